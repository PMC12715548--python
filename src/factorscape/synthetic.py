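"""Synthetic cohort generator with known ground truth.

Real morphometric/functional MRI cohorts are access-restricted, so every input
the pipeline consumes is emulated here with a ground truth the tests can score
against:

* signed symmetric "factor" matrices with sparse, mostly disjoint edge supports
  (patterns of hyper- and hypo-connectivity / -similarity);
* per-subject matrices as Dirichlet-weighted mixtures of those factors plus
  symmetric Gaussian noise;
* per-region vertex clouds drawn from region-specific multivariate Gaussians,
  together with the closed-form symmetrized-KL matrix between the true
  Gaussians (the recovery target for the MIND estimators);
* multivariate-Gaussian BOLD-like time series with a prescribed population
  correlation matrix;
* spatially autocorrelated receptor-density maps on a spherical parcellation;
* behavioral scores linearly coupled to the true factor loadings.

Every generator is deterministic given (parameters, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrices import lower_triangle, tril_indices
from .mind import VertexFeatureTable, gaussian_kl

#: Transmitter/receptor names matching the 19 PET-derived density maps commonly
#: used for cortical annotation (serotonin, dopamine, noradrenaline (NET),
#: endocannabinoid (CB1), GABA, glutamate, opioid, histamine, acetylcholine).
RECEPTOR_NAMES = [
    "5HT1a", "5HT1b", "5HT2a", "5HT4", "5HT6", "5HTT",
    "A4B2", "CB1", "D1", "D2", "DAT", "GABAa", "H3",
    "M1", "mGluR5", "MOR", "NET", "NMDA", "VAChT",
]


@dataclass
class SpherePoints:
    """Parcel centroid coordinates on the unit sphere with hemisphere labels."""

    coords: np.ndarray  # R x 3, unit rows
    hemisphere: np.ndarray  # R array of 'L'/'R'

    @property
    def n_regions(self) -> int:
        return self.coords.shape[0]

    def to_frame(self, labels: list[str] | None = None) -> pd.DataFrame:
        labels = labels or [f"region_{i:03d}" for i in range(self.n_regions)]
        return pd.DataFrame(
            {
                "region": labels,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "z": self.coords[:, 2],
                "hemisphere": self.hemisphere,
            }
        )


@dataclass
class ReceptorAtlas:
    """Per-parcel receptor/transporter density maps plus spherical coordinates."""

    densities: np.ndarray  # R x M, column-standardized
    names: list[str]
    sphere: SpherePoints

    @property
    def n_regions(self) -> int:
        return self.densities.shape[0]

    @property
    def n_maps(self) -> int:
        return self.densities.shape[1]


@dataclass
class GroundTruth:
    """Bundle of everything a synthetic cohort was generated from."""

    factor_matrices: list[np.ndarray] = field(default_factory=list)
    loadings: np.ndarray | None = None  # N x K, simplex rows
    behavior_effects: np.ndarray | None = None  # S x K
    region_gaussians: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    receptor_truth: np.ndarray | None = None
    sphere: SpherePoints | None = None


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _hemisphere_lattice(n: int, axis_sign: float) -> np.ndarray:
    """Quasi-uniform Fibonacci lattice over one half-sphere (x < 0 or x > 0)."""
    i = np.arange(n)
    c = 1.0 - (i + 0.5) / n  # cosine of angle from the hemisphere axis, in (0, 1)
    s = np.sqrt(1.0 - c**2)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    return np.column_stack([axis_sign * c, s * np.cos(phi), s * np.sin(phi)])


def gen_sphere_parcellation(n_regions: int, seed=0) -> SpherePoints:
    """Quasi-uniform parcel centroids on the unit sphere, half per hemisphere.

    Each hemisphere is a Fibonacci lattice over its half-sphere — parcel
    spacing is nearly even, as in real cortical parcellations, which is what
    makes rotation-and-reassign spin nulls faithful.  The first
    ``n_regions/2`` parcels occupy x < 0 and are labeled left ('L'), the rest
    x > 0 ('R'); each hemisphere is independently rotated about the x axis by
    a seeded random angle.
    """
    if n_regions < 4 or n_regions % 2 != 0:
        raise ValueError(f"n_regions must be even and >= 4, got {n_regions}")
    rng = _rng(seed)
    half = n_regions // 2
    hemis = []
    for sign in (-1.0, 1.0):
        pts = _hemisphere_lattice(half, sign)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        cos_t, sin_t = np.cos(theta), np.sin(theta)
        rot_x = np.array([[1.0, 0.0, 0.0], [0.0, cos_t, -sin_t], [0.0, sin_t, cos_t]])
        hemis.append(pts @ rot_x.T)
    coords = np.vstack(hemis)
    coords /= np.linalg.norm(coords, axis=1, keepdims=True)
    hemi = np.array(["L"] * half + ["R"] * half)
    return SpherePoints(coords=coords, hemisphere=hemi)


def gen_factor_truth(
    n_factors: int,
    n_regions: int,
    edge_density: float = 0.3,
    magnitude: float = 1.0,
    seed=0,
    max_tries: int = 50,
) -> list[np.ndarray]:
    """Signed symmetric ground-truth factor matrices with sparse supports.

    Each factor activates ~``edge_density`` of the lower-triangle edges with a
    mix of positive (hyper-) and negative (hypo-) weights.  Supports lean
    disjoint — each factor draws preferentially from its own exclusive edge
    pool — and draws are rejected until all pairwise lower-triangle
    correlations are below 0.5, so that the factors are identifiable.
    """
    if not (0 < edge_density <= 1):
        raise ValueError(f"edge_density must lie in (0, 1], got {edge_density}")
    if n_factors < 1:
        raise ValueError("n_factors must be >= 1")
    n_edges = n_regions * (n_regions - 1) // 2
    m = max(1, int(round(edge_density * n_edges)))
    rng = _rng(seed)
    rows, cols = tril_indices(n_regions)

    for _ in range(max_tries):
        order = rng.permutation(n_edges)
        pools = np.array_split(order, n_factors)
        factors = []
        for k in range(n_factors):
            pool = pools[k]
            if m <= len(pool):
                support = rng.choice(pool, size=m, replace=False)
            else:
                others = np.setdiff1d(order, pool, assume_unique=False)
                extra = rng.choice(others, size=m - len(pool), replace=False)
                support = np.concatenate([pool, extra])
            vals = np.zeros(n_edges)
            signs = rng.choice([-1.0, 1.0], size=len(support))
            vals[support] = signs * (0.2 + np.abs(rng.standard_normal(len(support)))) * magnitude
            mat = np.zeros((n_regions, n_regions))
            mat[rows, cols] = vals
            mat = mat + mat.T
            factors.append(mat)
        if n_factors == 1:
            return factors
        ok = True
        for a in range(n_factors):
            for b in range(a + 1, n_factors):
                r = np.corrcoef(lower_triangle(factors[a]), lower_triangle(factors[b]))[0, 1]
                if abs(r) >= 0.5:
                    ok = False
        if ok:
            return factors
    raise RuntimeError("could not generate well-separated factors; lower edge_density")


def gen_cohort_matrices(
    factor_matrices: list[np.ndarray],
    n_subjects: int,
    dirichlet_alpha=0.5,
    noise_sd: float = 0.05,
    seed=0,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-subject matrices as noisy Dirichlet mixtures of the true factors.

    subject_i = sum_k loading_ik * factor_k + symmetric N(0, noise_sd) noise.
    Returns (matrices, loadings); loadings rows lie on the simplex.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    k = len(factor_matrices)
    alpha = np.broadcast_to(np.atleast_1d(np.asarray(dirichlet_alpha, dtype=float)), (k,))
    if np.any(alpha <= 0):
        raise ValueError("dirichlet_alpha must be > 0")
    if n_subjects < k:
        warnings.warn(
            f"n_subjects={n_subjects} < n_factors={k}: factor recovery is not identifiable",
            UserWarning,
            stacklevel=2,
        )
    rng = _rng(seed)
    loadings = rng.dirichlet(alpha, size=n_subjects)
    stack = np.stack(factor_matrices)
    r = stack.shape[1]
    mats = []
    for i in range(n_subjects):
        m = np.tensordot(loadings[i], stack, axes=1)
        if noise_sd > 0:
            a = rng.normal(0.0, noise_sd, size=(r, r))
            m = m + (a + a.T) / np.sqrt(2.0)
        np.fill_diagonal(m, 0.0)
        m = (m + m.T) / 2.0  # exact symmetry against float asymmetry
        mats.append(m)
    return mats, loadings


def _random_spd_perturbation(rng: np.random.Generator, dim: int) -> np.ndarray:
    a = rng.standard_normal((dim, dim))
    return a @ a.T / (2.0 * dim)


def gen_vertex_features(
    n_regions: int,
    vertices_per_region: int = 500,
    n_features: int = 5,
    separation: float = 1.0,
    seed=0,
    region_labels: list[str] | None = None,
) -> tuple[VertexFeatureTable, np.ndarray]:
    """Per-region vertex clouds from region-specific Gaussians, plus truth.

    Region r's vertices are i.i.d. draws from N(mu_r, Sigma_r) with
    mu_r = separation * z_r and Sigma_r = I + separation * (A_r A_r^T / 2F);
    at ``separation=0`` all regions share the standard Gaussian and the true
    divergence matrix is identically zero.  The second return value is the
    closed-form symmetrized KL matrix between the true Gaussians — the target
    the MIND estimators are scored against.  Five features per vertex mirrors
    the usual morphometric set (thickness, volume, area, curvature, sulcal
    depth).
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if vertices_per_region < n_features + 2:
        raise ValueError(
            f"vertices_per_region must be >= n_features + 2 "
            f"({n_features + 2}), got {vertices_per_region}"
        )
    rng = _rng(seed)
    labels = region_labels or [f"region_{i:03d}" for i in range(n_regions)]
    means, covs, data = [], [], {}
    eye = np.eye(n_features)
    for r in range(n_regions):
        mu = separation * rng.standard_normal(n_features)
        cov = eye + separation * _random_spd_perturbation(rng, n_features)
        means.append(mu)
        covs.append(cov)
        chol = np.linalg.cholesky(cov)
        data[labels[r]] = mu + rng.standard_normal((vertices_per_region, n_features)) @ chol.T

    true_kl = np.zeros((n_regions, n_regions))
    for a in range(n_regions):
        for b in range(a + 1, n_regions):
            d = 0.5 * (
                gaussian_kl(means[a], covs[a], means[b], covs[b])
                + gaussian_kl(means[b], covs[b], means[a], covs[a])
            )
            true_kl[a, b] = true_kl[b, a] = d
    feature_names = ["thickness", "volume", "area", "curvature", "sulc"][:n_features]
    if len(feature_names) < n_features:
        feature_names += [f"feat_{i}" for i in range(len(feature_names), n_features)]
    table = VertexFeatureTable(regions=labels, features=feature_names, data=data)
    return table, true_kl


def gen_timeseries(
    n_regions: int,
    n_timepoints: int,
    target_fc: np.ndarray,
    seed=0,
) -> np.ndarray:
    """T x R multivariate-Gaussian series with population correlation target_fc.

    The target must be a symmetric PSD matrix with unit diagonal; the sample
    correlation converges to it as T grows.  T=2 is allowed but warned about
    (rank-deficient sample correlation).
    """
    target_fc = np.asarray(target_fc, dtype=float)
    if target_fc.shape != (n_regions, n_regions):
        raise ValueError(f"target_fc must be {n_regions}x{n_regions}")
    if not np.allclose(target_fc, target_fc.T, atol=1e-10):
        raise ValueError("target_fc must be symmetric")
    if not np.allclose(np.diag(target_fc), 1.0, atol=1e-10):
        raise ValueError("target_fc must have unit diagonal")
    eigvals = np.linalg.eigvalsh(target_fc)
    if eigvals[0] < -1e-10:
        raise ValueError(
            f"target_fc is not positive semi-definite: smallest eigenvalue {eigvals[0]:.3e}"
        )
    if n_timepoints < 3:
        warnings.warn(
            f"n_timepoints={n_timepoints} < 3: sample correlation is rank-deficient",
            UserWarning,
            stacklevel=2,
        )
    rng = _rng(seed)
    # eigen square root tolerates exact semidefiniteness where Cholesky fails
    w, v = np.linalg.eigh(target_fc)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    return rng.standard_normal((n_timepoints, n_regions)) @ root.T


def gen_receptor_maps(
    sphere: SpherePoints,
    n_maps: int = 19,
    smoothness: float = 1.0,
    seed=0,
    n_neighbors: int = 6,
) -> ReceptorAtlas:
    """Spatially autocorrelated receptor-density maps over a parcellation.

    Each map starts as i.i.d. parcel noise and is smoothed ``round(smoothness)``
    times over the k-nearest-neighbor graph of the spherical coordinates
    (including self), giving a tunable spatial autocorrelation length;
    ``smoothness=0`` leaves the maps spatially white.  Columns are standardized
    to zero mean, unit variance.
    """
    if smoothness < 0:
        raise ValueError("smoothness must be >= 0")
    rng = _rng(seed)
    r = sphere.n_regions
    maps = rng.standard_normal((r, n_maps))
    passes = int(round(smoothness))
    if passes > 0:
        d2 = ((sphere.coords[:, None, :] - sphere.coords[None, :, :]) ** 2).sum(axis=2)
        nn = np.argsort(d2, axis=1)[:, : min(n_neighbors + 1, r)]  # includes self
        w = np.zeros((r, r))
        row = np.repeat(np.arange(r), nn.shape[1])
        w[row, nn.ravel()] = 1.0
        w /= w.sum(axis=1, keepdims=True)
        for _ in range(passes):
            maps = w @ maps
    maps = maps - maps.mean(axis=0, keepdims=True)
    sd = maps.std(axis=0, ddof=0, keepdims=True)
    maps = maps / sd
    names = RECEPTOR_NAMES[:n_maps]
    if len(names) < n_maps:
        names = names + [f"map_{i}" for i in range(len(names), n_maps)]
    return ReceptorAtlas(densities=maps, names=names, sphere=sphere)


def gen_behavior(
    true_loadings: np.ndarray,
    effects: np.ndarray,
    noise_sd: float = 1.0,
    seed=0,
    scale_names: list[str] | None = None,
) -> pd.DataFrame:
    """Behavioral scores linearly coupled to true factor loadings.

    score_is = sum_k loadings_ik * effects_sk + N(0, noise_sd).  ``effects`` is
    S scales x K factors; a zero row makes that scale a true null.
    """
    true_loadings = np.asarray(true_loadings, dtype=float)
    effects = np.atleast_2d(np.asarray(effects, dtype=float))
    if effects.shape[1] != true_loadings.shape[1]:
        raise ValueError(
            f"effects has {effects.shape[1]} factor columns, loadings have "
            f"{true_loadings.shape[1]}"
        )
    rng = _rng(seed)
    scores = true_loadings @ effects.T
    if noise_sd > 0:
        scores = scores + rng.normal(0.0, noise_sd, size=scores.shape)
    names = scale_names or [f"scale_{s}" for s in range(effects.shape[0])]
    if len(names) != effects.shape[0]:
        raise ValueError("scale_names length must match number of effect rows")
    return pd.DataFrame(scores, columns=names)


def behavior_noise_for_target_r(
    loading_var: float, effect: float, target_r: float
) -> float:
    """Noise SD giving population correlation ``target_r`` for a single-factor effect.

    For score = effect * loading + eps, r = effect*sd(loading) /
    sqrt(effect^2 var(loading) + sd_eps^2); invert for sd_eps.
    """
    if not (0 < target_r < 1):
        raise ValueError("target_r must lie in (0, 1)")
    return float(np.sqrt(effect**2 * loading_var * (1.0 / target_r**2 - 1.0)))


def dirichlet_loading_variance(alpha, n_factors: int) -> float:
    """Marginal variance of one coordinate of a symmetric Dirichlet(alpha) draw."""
    alpha = float(np.atleast_1d(alpha)[0])
    a0 = alpha * n_factors
    return alpha * (a0 - alpha) / (a0**2 * (a0 + 1.0))
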