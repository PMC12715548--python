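"""Functional connectivity from parcellated BOLD time series.

FC is the Pearson correlation between pairs of regional time series.  For
multi-run acquisitions, per-run correlation matrices are Fisher r-to-z
transformed before averaging (averaging raw r is biased toward zero); healthy
control comparison patterns are plain element-wise group averages.
"""

from __future__ import annotations

import warnings

import numpy as np

from .matrices import SimilarityMatrix

_CLIP = 1.0 - 1e-7


def fc_from_timeseries(
    timeseries: np.ndarray, labels: list[str] | None = None
) -> SimilarityMatrix:
    """Pearson correlation matrix (kind ``fc_r``) from a T x R time series."""
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError(f"expected a T x R array, got shape {ts.shape}")
    t, r = ts.shape
    if t < 3:
        raise ValueError(f"need at least 3 timepoints, got {t}")
    sd = ts.std(axis=0, ddof=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [labels[i] if labels else f"region index {i}" for i in dead]
        raise ValueError(f"zero temporal variance in region(s): {', '.join(map(str, names))}")
    corr = np.corrcoef(ts, rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return SimilarityMatrix(corr, "fc_r", labels or [])


def fisher_z(r):
    """Fisher r-to-z transform, z = atanh(r).  Requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| must be < 1 for the Fisher transform")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def inverse_fisher(z):
    """Inverse Fisher transform, r = tanh(z)."""
    z = np.asarray(z, dtype=float)
    out = np.tanh(z)
    return float(out) if out.ndim == 0 else out


def _z_matrix(sm: SimilarityMatrix) -> np.ndarray:
    """Fisher-transform an fc_r matrix; diagonal excluded and set to 0."""
    vals = sm.values.copy()
    np.fill_diagonal(vals, 0.0)
    near_one = np.abs(vals) >= 1.0 - 1e-12
    if np.any(near_one):
        warnings.warn(
            f"{int(near_one.sum())} off-diagonal |r| values at 1 clipped to {_CLIP}",
            UserWarning,
            stacklevel=3,
        )
        vals = np.clip(vals, -_CLIP, _CLIP)
    z = np.arctanh(vals)
    np.fill_diagonal(z, 0.0)
    return z


def average_runs(matrices: list[SimilarityMatrix]) -> SimilarityMatrix:
    """Mean of Fisher-z transformed per-run FC matrices (kind ``fc_z``).

    The diagonal (r = 1, z = infinity) is excluded from the transform and set
    to 0 in the output; no downstream statistic uses it.
    """
    if not matrices:
        raise ValueError("need at least one run")
    labels = matrices[0].labels
    for m in matrices:
        if m.kind != "fc_r":
            raise ValueError(f"average_runs expects fc_r matrices, got {m.kind!r}")
        if m.labels != labels:
            raise ValueError("run matrices have mismatched region labels")
    z = np.mean([_z_matrix(m) for m in matrices], axis=0)
    z = (z + z.T) / 2.0
    return SimilarityMatrix(z, "fc_z", list(labels))


def group_average(matrices: list[SimilarityMatrix]) -> SimilarityMatrix:
    """Element-wise mean across subjects; the healthy-control comparison pattern."""
    if len(matrices) < 2:
        raise ValueError("need at least two subjects for a group average")
    kind = matrices[0].kind
    labels = matrices[0].labels
    for m in matrices:
        if m.kind != kind:
            raise ValueError(f"mixed matrix kinds: {kind!r} vs {m.kind!r}")
        if m.labels != labels:
            raise ValueError("subject matrices have mismatched region labels")
    mean = np.mean([m.values for m in matrices], axis=0)
    mean = (mean + mean.T) / 2.0
    if kind in ("fc_r", "mind_raw"):
        np.fill_diagonal(mean, 1.0)
    return SimilarityMatrix(mean, kind, list(labels))
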