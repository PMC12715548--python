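"""Morphometric Inverse Divergence (MIND) similarity matrices.

Each cortical region is treated as a multivariate distribution over its
vertices' morphometric features (thickness, volume, area, curvature, sulcal
depth).  For every pair of regions a symmetrized Kullback-Leibler divergence
D is estimated — either in closed form under a Gaussian fit or nonparametrically
with a k-nearest-neighbor density-ratio estimator — and mapped to a similarity

    MIND(i, j) = 1 / (1 + D(i, j))  in (0, 1].

An optional z-normalization step standardizes the off-diagonal values over the
lower triangle, matching how the similarity matrices enter group analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial import cKDTree

from .matrices import SimilarityMatrix, tril_indices


@dataclass
class VertexFeatureTable:
    """Per-region arrays of vertex rows x feature columns for one subject."""

    regions: list[str]
    features: list[str]
    data: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        f = len(self.features)
        for region in self.regions:
            if region not in self.data:
                raise ValueError(f"region {region!r} missing from data")
            arr = np.asarray(self.data[region], dtype=float)
            if arr.ndim != 2 or arr.shape[1] != f:
                raise ValueError(
                    f"region {region!r}: expected vertices x {f} features, got {arr.shape}"
                )
            if arr.shape[0] < f + 2:
                raise ValueError(
                    f"region {region!r} has {arr.shape[0]} vertices; need >= {f + 2} "
                    "to estimate a covariance"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"region {region!r} contains non-finite values")
            self.data[region] = arr

    @property
    def n_features(self) -> int:
        return len(self.features)

    def pooled(self) -> np.ndarray:
        """All vertices of all regions stacked, in region order."""
        return np.vstack([self.data[r] for r in self.regions])


def zscore_features(table: VertexFeatureTable) -> VertexFeatureTable:
    """Standardize each feature to mean 0, variance 1 over the pooled vertices.

    Standardization is per subject, across the pooled vertex set of all
    regions; it makes features on incommensurate units (mm, mm^2, unitless
    curvature) comparable before divergence estimation.  A zero-variance
    feature is an error (it carries no distributional information and breaks
    covariance estimation).
    """
    pooled = table.pooled()
    mean = pooled.mean(axis=0)
    sd = pooled.std(axis=0, ddof=0)
    for name, s in zip(table.features, sd):
        if s == 0:
            raise ValueError(f"feature {name!r} has zero variance across pooled vertices")
    data = {r: (table.data[r] - mean) / sd for r in table.regions}
    return VertexFeatureTable(regions=list(table.regions), features=list(table.features), data=data)


def _check_spd(cov: np.ndarray, name: str):
    cov = np.asarray(cov, dtype=float)
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    try:
        return cho_factor(cov, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"{name} is not positive definite") from exc


def gaussian_kl(mean1, cov1, mean2, cov2) -> float:
    """Closed-form KL(P || Q) in nats between multivariate Gaussians.

    0.5 * [tr(S2^-1 S1) + (m2-m1)^T S2^-1 (m2-m1) - F + ln(det S2 / det S1)].
    """
    mean1 = np.atleast_1d(np.asarray(mean1, dtype=float))
    mean2 = np.atleast_1d(np.asarray(mean2, dtype=float))
    cov1 = np.atleast_2d(np.asarray(cov1, dtype=float))
    cov2 = np.atleast_2d(np.asarray(cov2, dtype=float))
    f = mean1.shape[0]
    c1 = _check_spd(cov1, "cov1")
    c2 = _check_spd(cov2, "cov2")
    logdet1 = 2.0 * np.sum(np.log(np.diag(c1[0])))
    logdet2 = 2.0 * np.sum(np.log(np.diag(c2[0])))
    trace_term = np.trace(cho_solve(c2, cov1))
    diff = mean2 - mean1
    maha = float(diff @ cho_solve(c2, diff))
    return float(0.5 * (trace_term + maha - f + logdet2 - logdet1))


def knn_kl_estimate(samples_p: np.ndarray, samples_q: np.ndarray, k: int = 3) -> float:
    """Nonparametric k-NN estimate of KL(P || Q) in nats, clamped at 0.

    Wang-Kulkarni-Verdu density-ratio form: with rho_k(i) the k-th NN distance
    of x_i within P (self excluded) and nu_k(i) the k-th NN distance from x_i
    into Q,

        KL ~= (F/n) * sum_i ln(nu_k(i) / rho_k(i)) + ln(m / (n - 1)).

    The estimator is consistent but can go slightly negative at finite n; the
    returned value is max(estimate, 0).  Zero distances from duplicate points
    are replaced by the smallest positive distance observed times 1e-6
    (deterministic jitter).
    """
    x = np.atleast_2d(np.asarray(samples_p, dtype=float))
    y = np.atleast_2d(np.asarray(samples_q, dtype=float))
    if x.shape[1] != y.shape[1]:
        raise ValueError("sample sets must share the feature dimension")
    n, f = x.shape
    m = y.shape[0]
    if k >= min(n, m):
        raise ValueError(f"k={k} must be < min(n, m) = {min(n, m)}")
    rho = cKDTree(x).query(x, k=k + 1)[0][:, -1]  # k-th neighbor, self excluded
    nu = cKDTree(y).query(x, k=k)[0]
    nu = nu[:, -1] if nu.ndim == 2 else nu
    positive = np.concatenate([rho[rho > 0], nu[nu > 0]])
    if positive.size == 0:
        return 0.0  # all points identical in both sets: distributions agree
    eps = positive.min() * 1e-6
    rho = np.where(rho > 0, rho, eps)
    nu = np.where(nu > 0, nu, eps)
    est = (f / n) * np.sum(np.log(nu / rho)) + np.log(m / (n - 1.0))
    return float(max(est, 0.0))


def _gaussian_fits(table: VertexFeatureTable) -> list[tuple[np.ndarray, np.ndarray]]:
    fits = []
    for region in table.regions:
        arr = table.data[region]
        fits.append((arr.mean(axis=0), np.cov(arr, rowvar=False, ddof=1)))
    return fits


def znormalize(sm: SimilarityMatrix) -> SimilarityMatrix:
    """Z-score the off-diagonal values over the lower triangle and mirror back.

    The diagonal is excluded from the statistics and set to the maximum z value
    for display only; downstream analyses use the lower triangle.
    """
    vals = sm.values
    i, j = tril_indices(vals.shape[0])
    tri = vals[i, j]
    sd = tri.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot z-normalize a constant matrix")
    z = (tri - tri.mean()) / sd
    out = np.zeros_like(vals)
    out[i, j] = z
    out[j, i] = z
    np.fill_diagonal(out, z.max())
    return SimilarityMatrix(out, "mind_znorm", list(sm.labels))


def mind_matrix(
    table: VertexFeatureTable,
    estimator: str = "knn",
    k: int = 3,
    znorm: bool = False,
    standardize: bool = True,
) -> SimilarityMatrix:
    """MIND similarity matrix from a subject's vertex features.

    For each region pair the symmetrized divergence
    D = (KL(P||Q) + KL(Q||P)) / 2 is estimated with the chosen estimator and
    mapped to MIND = 1/(1+D); the diagonal is 1.  ``estimator='gaussian'``
    fits each region with a multivariate Gaussian and uses the closed form
    (fast, exact under the model); ``'knn'`` is the nonparametric default.
    With ``znorm=True`` the result is lower-triangle z-scored
    (kind ``mind_znorm``).
    """
    if estimator not in ("gaussian", "knn"):
        raise ValueError(f"estimator must be 'gaussian' or 'knn', got {estimator!r}")
    if standardize:
        table = zscore_features(table)
    regions = table.regions
    r = len(regions)
    d = np.zeros((r, r))
    if estimator == "gaussian":
        fits = _gaussian_fits(table)
        for a in range(r):
            for b in range(a + 1, r):
                m1, c1 = fits[a]
                m2, c2 = fits[b]
                d[a, b] = d[b, a] = 0.5 * (
                    gaussian_kl(m1, c1, m2, c2) + gaussian_kl(m2, c2, m1, c1)
                )
    else:
        arrays = [table.data[name] for name in regions]
        for a in range(r):
            for b in range(a + 1, r):
                d[a, b] = d[b, a] = 0.5 * (
                    knn_kl_estimate(arrays[a], arrays[b], k=k)
                    + knn_kl_estimate(arrays[b], arrays[a], k=k)
                )
    mind = 1.0 / (1.0 + d)
    sm = SimilarityMatrix(mind, "mind_raw", list(regions))
    return znormalize(sm) if znorm else sm
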