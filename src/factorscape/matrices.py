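"""Region-by-region similarity matrices and their canonical vectorization.

The whole pipeline works on symmetric R x R matrices: functional connectivity
(Pearson r between regional BOLD time series), morphometric similarity (MIND,
an inverse KL-divergence between regional vertex-feature distributions) and the
signed latent-factor matrices recovered from them.  ``SimilarityMatrix`` is the
shared container; the canonical lower-triangle order (row-major, i > j) is the
edge vocabulary every downstream module agrees on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Recognised matrix kinds.  ``mind_raw`` lives in (0, 1]; ``mind_znorm`` is its
#: lower-triangle z-scored variant; ``fc_r`` is a Pearson correlation matrix;
#: ``fc_z`` is Fisher-z transformed (diagonal set to 0); ``signed`` is a generic
#: signed symmetric matrix (synthetic mixtures, factor patterns).
KINDS = ("mind_raw", "mind_znorm", "fc_r", "fc_z", "signed")

SYMMETRY_ATOL = 1e-10


def default_labels(n_regions: int) -> list[str]:
    """Region labels used when an input carries none."""
    return [f"region_{i:03d}" for i in range(n_regions)]


def tril_indices(n_regions: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical lower-triangle index pair (row-major, i > j, diagonal excluded)."""
    return np.tril_indices(n_regions, k=-1)


def lower_triangle(values: np.ndarray) -> np.ndarray:
    """Vectorize a square matrix's strict lower triangle in canonical order.

    Returns a length R(R-1)/2 vector.  Raises ``ValueError`` on non-square
    input.
    """
    values = np.asarray(values)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {values.shape}")
    i, j = tril_indices(values.shape[0])
    return values[i, j].copy()


def from_lower_triangle(vec: np.ndarray, diagonal: float = 0.0) -> np.ndarray:
    """Mirror a canonical lower-triangle vector back into a symmetric matrix."""
    vec = np.asarray(vec, dtype=float)
    e = vec.shape[0]
    r = int(round((1 + np.sqrt(1 + 8 * e)) / 2))
    if r * (r - 1) // 2 != e:
        raise ValueError(f"vector length {e} is not a triangular number")
    out = np.full((r, r), diagonal, dtype=float)
    i, j = tril_indices(r)
    out[i, j] = vec
    out[j, i] = vec
    return out


@dataclass
class SimilarityMatrix:
    """A symmetric R x R similarity/connectivity matrix with provenance tag.

    Parameters
    ----------
    values
        Symmetric array (checked to ``SYMMETRY_ATOL``).
    kind
        One of :data:`KINDS`.
    labels
        Region labels in parcellation order; generated if omitted.
    """

    values: np.ndarray
    kind: str
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"matrix must be square, got shape {self.values.shape}")
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}; expected one of {KINDS}")
        if not self.labels:
            self.labels = default_labels(self.values.shape[0])
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("label count does not match matrix size")
        if not np.allclose(self.values, self.values.T, atol=SYMMETRY_ATOL, rtol=0.0):
            raise ValueError("matrix is not symmetric within 1e-10")
        # kind-specific range checks
        if self.kind == "mind_raw":
            off = lower_triangle(self.values)
            if np.any(off <= 0) or np.any(off > 1 + 1e-12):
                raise ValueError("mind_raw values must lie in (0, 1]")
            if not np.allclose(np.diag(self.values), 1.0, atol=1e-10):
                raise ValueError("mind_raw diagonal must be 1")
        elif self.kind == "fc_r":
            if np.any(np.abs(self.values) > 1 + 1e-12):
                raise ValueError("fc_r values must lie in [-1, 1]")
            if not np.allclose(np.diag(self.values), 1.0, atol=1e-10):
                raise ValueError("fc_r diagonal must be 1")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def lower_triangle(self) -> np.ndarray:
        """Strict lower triangle in canonical row-major (i > j) order."""
        return lower_triangle(self.values)

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "SimilarityMatrix":
        return SimilarityMatrix(values, kind or self.kind, list(self.labels))
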