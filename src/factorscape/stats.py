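"""Factor characterization statistics.

Covers four analyses applied to fitted factors:

* correspondence between factor sets (lower-triangle Pearson r), used both for
  patient-vs-control comparison and for structure-function coupling;
* Pearson correlations of subject loadings with behavioral scale scores
  (pairwise-complete, two-sided t-test p);
* reduction of a factor matrix to a single region-wise summary vector (first
  principal component, regions as observations);
* ordinary least squares of that summary vector on standardized receptor
  density maps, with spin-permutation p-values supplied by :mod:`.spin`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .matrices import SimilarityMatrix, lower_triangle


def _as_tri(obj) -> np.ndarray:
    if isinstance(obj, SimilarityMatrix):
        return obj.lower_triangle()
    return lower_triangle(np.asarray(obj))


def factor_correspondence(
    factors_a: list,
    factors_b: list,
    names_a: list[str] | None = None,
    names_b: list[str] | None = None,
) -> pd.DataFrame:
    """All-pairs Pearson correlation between lower-triangle factor vectors.

    Returns a tidy table (a, b, r, p) with two-sided p-values.
    """
    names_a = names_a or [f"A{i + 1}" for i in range(len(factors_a))]
    names_b = names_b or [f"B{i + 1}" for i in range(len(factors_b))]
    tris_a = [_as_tri(f) for f in factors_a]
    tris_b = [_as_tri(f) for f in factors_b]
    rows = []
    for na, ta in zip(names_a, tris_a):
        for nb, tb in zip(names_b, tris_b):
            r, p = sstats.pearsonr(ta, tb)
            rows.append({"a": na, "b": nb, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)


def loading_behavior_correlations(
    loadings: np.ndarray,
    behavior: pd.DataFrame,
    factor_names: list[str] | None = None,
) -> pd.DataFrame:
    """Pearson correlation of each factor loading with each behavioral scale.

    Missing behavior entries are handled by pairwise deletion; a cell with
    fewer than 3 complete pairs is flagged (r, p = NaN) rather than computed.
    Returns a tidy table (factor, scale, r, p, n).
    """
    loadings = np.asarray(loadings, dtype=float)
    n, k = loadings.shape
    if len(behavior) != n:
        raise ValueError(
            f"behavior table has {len(behavior)} rows, loadings have {n} subjects"
        )
    factor_names = factor_names or [f"factor_{i + 1}" for i in range(k)]
    rows = []
    for fi, fname in enumerate(factor_names):
        col = loadings[:, fi]
        for scale in behavior.columns:
            y = behavior[scale].to_numpy(dtype=float)
            mask = np.isfinite(y) & np.isfinite(col)
            n_ok = int(mask.sum())
            if n_ok < 3:
                rows.append(
                    {"factor": fname, "scale": scale, "r": np.nan, "p": np.nan, "n": n_ok}
                )
                continue
            r, p = sstats.pearsonr(col[mask], y[mask])
            rows.append(
                {"factor": fname, "scale": scale, "r": float(r), "p": float(p), "n": n_ok}
            )
    return pd.DataFrame(rows)


def pca_first_component(matrix: np.ndarray) -> np.ndarray:
    """First principal component scores of an R x R matrix, regions as rows.

    The matrix is treated as R observations (regions) x R variables,
    column-centered; the returned length-R score vector summarizes each
    region's connectivity profile.  Sign is fixed so the component correlates
    nonnegatively with the matrix row means.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got {m.shape}")
    centered = m - m.mean(axis=0, keepdims=True)
    if np.allclose(centered, 0.0):
        raise ValueError("matrix has no variance across regions (rank 0 after centering)")
    # SVD of the centered data: scores along the first right singular vector
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    scores = u[:, 0] * s[0]
    row_means = m.mean(axis=1)
    r = np.corrcoef(scores, row_means)[0, 1]
    if np.isfinite(r) and r < 0:
        scores = -scores
    return scores


def receptor_regression(pc: np.ndarray, atlas, joint: bool = True) -> pd.DataFrame:
    """OLS of a factor's summary vector on the receptor maps.

    With ``joint=True`` (default) all M maps enter one model and the
    coefficients are mutually adjusted; with ``joint=False`` each map is
    tested in a separate simple regression (the coefficient then equals the
    plain correlation of the standardized variables).  Response and
    predictors are z-scored, so coefficients are standardized betas.  Returns
    a table (transmitter, beta) plus rows ``_intercept`` and ``_r_squared``
    (for the joint model; NaN otherwise).  Raises on collinear maps
    (condition number > 1e8) in the joint model.
    """
    if not joint:
        z = _standardize(np.asarray(atlas.densities, dtype=float))
        y = _standardize(np.asarray(pc, dtype=float)[:, None])[:, 0]
        betas = z.T @ y / len(y)
        rows = [{"transmitter": n, "beta": float(b)} for n, b in zip(atlas.names, betas)]
        rows.append({"transmitter": "_intercept", "beta": 0.0})
        rows.append({"transmitter": "_r_squared", "beta": float("nan")})
        return pd.DataFrame(rows)
    betas, intercept, r2 = _regress(pc, atlas.densities)
    rows = [{"transmitter": n, "beta": float(b)} for n, b in zip(atlas.names, betas)]
    rows.append({"transmitter": "_intercept", "beta": float(intercept)})
    rows.append({"transmitter": "_r_squared", "beta": float(r2)})
    return pd.DataFrame(rows)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("constant column cannot be standardized")
    return (x - x.mean(axis=0)) / sd


def _design(maps: np.ndarray) -> np.ndarray:
    z = _standardize(np.asarray(maps, dtype=float))
    cond = np.linalg.cond(z)
    if cond > 1e8:
        corr = np.corrcoef(z, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"receptor maps are collinear (condition number {cond:.2e}); "
            f"worst pair: columns {i} and {j} (|r|={abs(corr[i, j]):.6f})"
        )
    return np.column_stack([np.ones(z.shape[0]), z])


def _regress(pc: np.ndarray, maps: np.ndarray):
    pc = np.asarray(pc, dtype=float)
    x = _design(maps)
    if pc.shape[0] != x.shape[0]:
        raise ValueError("summary vector and maps must share the region dimension")
    if x.shape[0] <= x.shape[1]:
        raise ValueError(
            f"need more regions ({x.shape[0]}) than predictors+1 ({x.shape[1]})"
        )
    y = _standardize(pc[:, None])[:, 0]
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    r2 = 1.0 - resid @ resid / (y @ y)
    return coef[1:], coef[0], r2
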