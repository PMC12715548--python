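"""Latent-factor decomposition of signed connectivity matrices via smoothed LDA.

The dimensional-subtyping model treats each subject's similarity/connectivity
matrix as a "document" over an edge vocabulary: every lower-triangle edge
contributes a positive-channel word (hyper-connectivity / hyper-similarity)
and a negative-channel word (hypo-), and the edge value is discretized into
word counts.  Smoothed latent Dirichlet allocation then decomposes the cohort
into K latent factors — probability distributions over the 2E words, rendered
as signed symmetric matrices — with a per-subject simplex loading vector
saying how strongly each factor expresses in that subject.

Inference is batch variational EM with Dirichlet priors on both the
document-factor proportions (alpha) and the factor-word distributions (eta).
The evidence lower bound (ELBO) is tracked every iteration and is
coordinate-ascent monotone; multiple random restarts are fitted and the best
bound wins.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln, logsumexp, psi

from .matrices import SimilarityMatrix, from_lower_triangle, lower_triangle


# ---------------------------------------------------------------------------
# Documents: matrices -> two-channel edge counts
# ---------------------------------------------------------------------------

def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Half-away-from-zero rounding for nonnegative values (platform-stable)."""
    return np.floor(x + 0.5)


def matrix_to_document(m: SimilarityMatrix | np.ndarray, scale: float = 10.0) -> np.ndarray:
    """Discretize one signed matrix into counts over the 2E edge vocabulary.

    For each lower-triangle edge value x (canonical i > j order):
    positive-channel count = round(scale * max(x, 0)), negative-channel count
    = round(scale * max(-x, 0)).  Word w < E is edge w's positive channel,
    word E + w its negative channel; at most one of the two is nonzero.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    tri = m.lower_triangle() if isinstance(m, SimilarityMatrix) else lower_triangle(m)
    pos = _round_half_away(scale * np.clip(tri, 0.0, None))
    neg = _round_half_away(scale * np.clip(-tri, 0.0, None))
    counts = np.concatenate([pos, neg]).astype(np.int64)
    if counts.sum() == 0:
        raise ValueError(
            "document has zero total count after rounding; increase scale"
        )
    return counts


def documents_from_matrices(
    matrices: list, scale: float = 10.0, center: str = "none"
) -> np.ndarray:
    """Stack a cohort of matrices into an N x 2E count array.

    ``center='edge_zscore'`` z-scores each edge across the cohort before
    discretization (parity option with HC-normalized variants of the
    framework); the default ``'none'`` feeds matrices in as-is, matching the
    use of unnormalized patient matrices.
    """
    if center not in ("none", "edge_zscore"):
        raise ValueError(f"unknown centering policy {center!r}")
    tris = np.stack(
        [m.lower_triangle() if isinstance(m, SimilarityMatrix) else lower_triangle(m)
         for m in matrices]
    )
    if center == "edge_zscore":
        sd = tris.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        tris = (tris - tris.mean(axis=0)) / sd
    docs = []
    for row in tris:
        pos = _round_half_away(scale * np.clip(row, 0.0, None))
        neg = _round_half_away(scale * np.clip(-row, 0.0, None))
        docs.append(np.concatenate([pos, neg]))
    counts = np.asarray(docs, dtype=np.int64)
    if np.any(counts.sum(axis=1) == 0):
        bad = np.flatnonzero(counts.sum(axis=1) == 0)
        raise ValueError(
            f"document(s) {bad.tolist()} have zero total count; increase scale"
        )
    return counts


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------

@dataclass
class FactorSet:
    """K latent factors over a 2E edge vocabulary.

    ``word_distributions`` rows are probability vectors over the vocabulary;
    ``signed_matrices`` renders each factor as P(pos | k) - P(neg | k) per
    edge, mirrored into a symmetric zero-diagonal R x R matrix.
    """

    word_distributions: np.ndarray  # K x 2E
    n_regions: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        wd = np.asarray(self.word_distributions, dtype=float)
        if np.any(wd < 0):
            raise ValueError("word distributions must be nonnegative")
        if not np.allclose(wd.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("each word distribution must sum to 1")
        e = self.n_regions * (self.n_regions - 1) // 2
        if wd.shape[1] != 2 * e:
            raise ValueError(
                f"vocabulary size {wd.shape[1]} does not match R={self.n_regions}"
            )
        self.word_distributions = wd

    @property
    def n_factors(self) -> int:
        return self.word_distributions.shape[0]

    @property
    def signed_matrices(self) -> list[np.ndarray]:
        return factors_to_matrices(self)

    def permuted(self, perm: np.ndarray) -> "FactorSet":
        return FactorSet(self.word_distributions[perm], self.n_regions, dict(self.meta))


def factors_to_matrices(fs: FactorSet) -> list[np.ndarray]:
    """Signed symmetric matrix per factor: P(pos word) - P(neg word) per edge."""
    e = fs.n_regions * (fs.n_regions - 1) // 2
    out = []
    for row in fs.word_distributions:
        out.append(from_lower_triangle(row[:e] - row[e:], diagonal=0.0))
    return out


# ---------------------------------------------------------------------------
# Variational EM
# ---------------------------------------------------------------------------

def _dirichlet_expectation(arr: np.ndarray) -> np.ndarray:
    """E[log X] for rows of Dirichlet-distributed X with parameter rows arr."""
    return psi(arr) - psi(arr.sum(axis=1, keepdims=True))


def _elbo(
    counts: np.ndarray,
    gamma: np.ndarray,
    lam: np.ndarray,
    alpha: float,
    eta: float,
) -> float:
    """Evidence lower bound with the word-assignment term at its optimum.

    Because the per-word variational assignment given (gamma, lambda) is a
    softmax, its contribution collapses to sum_dw n_dw * logsumexp_k
    (Elog theta_dk + Elog beta_kw); the remaining terms are the standard
    Dirichlet prior/entropy terms for gamma and lambda.
    """
    n_docs, n_topics = gamma.shape
    n_words = lam.shape[1]
    elog_theta = _dirichlet_expectation(gamma)
    elog_beta = _dirichlet_expectation(lam)
    # (N, V, K) tensor is affordable at the cohort sizes this model targets
    combo = elog_theta[:, None, :] + elog_beta.T[None, :, :]
    score = float(np.sum(counts * logsumexp(combo, axis=2)))
    # theta prior and entropy
    score += float(
        np.sum((alpha - gamma) * elog_theta)
        + np.sum(gammaln(gamma))
        - np.sum(gammaln(gamma.sum(axis=1)))
        + n_docs * (gammaln(n_topics * alpha) - n_topics * gammaln(alpha))
    )
    # beta prior and entropy
    score += float(
        np.sum((eta - lam) * elog_beta)
        + np.sum(gammaln(lam))
        - np.sum(gammaln(lam.sum(axis=1)))
        + n_topics * (gammaln(n_words * eta) - n_words * gammaln(eta))
    )
    return score


def _e_step(
    counts: np.ndarray,
    gamma: np.ndarray,
    elog_beta: np.ndarray,
    alpha: float,
    inner_iter: int = 100,
    mean_change_tol: float = 1e-8,
):
    """Update per-document Dirichlet parameters; return (gamma, suff stats).

    Sufficient statistics are recomputed from the final gamma (one extra
    implicit phi update), which keeps the outer coordinate ascent monotone.
    """
    exp_elog_beta = np.exp(elog_beta)
    exp_elog_theta = np.exp(_dirichlet_expectation(gamma))
    eps = 1e-100
    for _ in range(inner_iter):
        phi_norm = exp_elog_theta @ exp_elog_beta + eps  # N x V
        new_gamma = alpha + exp_elog_theta * ((counts / phi_norm) @ exp_elog_beta.T)
        change = np.abs(new_gamma - gamma).mean()
        gamma = new_gamma
        exp_elog_theta = np.exp(_dirichlet_expectation(gamma))
        if change < mean_change_tol:
            break
    phi_norm = exp_elog_theta @ exp_elog_beta + eps
    sstats = exp_elog_beta * (exp_elog_theta.T @ (counts / phi_norm))  # K x V
    return gamma, sstats


def _fit_single(
    counts: np.ndarray,
    n_factors: int,
    alpha: float,
    eta: float,
    max_iter: int,
    tol: float,
    rng: np.random.Generator,
):
    n_docs, n_words = counts.shape
    lam = rng.gamma(100.0, 1.0 / 100.0, size=(n_factors, n_words))
    gamma = np.full((n_docs, n_factors), alpha + counts.sum(axis=1, keepdims=True) / n_factors)
    counts_f = counts.astype(float)
    bounds: list[float] = []
    converged = False
    for _ in range(max_iter):
        elog_beta = _dirichlet_expectation(lam)
        gamma, sstats = _e_step(counts_f, gamma, elog_beta, alpha)
        lam = eta + sstats
        bound = _elbo(counts_f, gamma, lam, alpha, eta)
        bounds.append(bound)
        if len(bounds) > 1:
            prev = bounds[-2]
            if abs(bound - prev) <= tol * abs(prev):
                converged = True
                break
    return gamma, lam, bounds, converged


def fit_lda(
    documents: np.ndarray,
    n_factors: int,
    alpha: float | None = None,
    eta: float = 0.01,
    n_restarts: int = 5,
    max_iter: int = 200,
    tol: float = 1e-5,
    seed=0,
    n_regions: int | None = None,
):
    """Fit smoothed LDA to an N x 2E count array by variational EM.

    Parameters
    ----------
    documents
        Count array from :func:`documents_from_matrices`.
    n_factors
        K, the number of latent factors.
    alpha
        Symmetric Dirichlet prior on document-factor proportions; default
        50/K (standard topic-model practice).
    eta
        Symmetric Dirichlet smoothing on factor-word distributions.
    n_restarts
        Independent random initializations; the fit with the best final ELBO
        is returned.
    tol
        Relative ELBO change declaring convergence.

    Returns
    -------
    (FactorSet, loadings)
        ``loadings`` is N x K, rows on the simplex (normalized variational
        Dirichlet parameters).  Fit metadata (ELBO trace per restart, chosen
        restart, convergence flag, seed) lives in ``FactorSet.meta``.
    """
    documents = np.asarray(documents)
    if documents.ndim != 2:
        raise ValueError("documents must be an N x V count array")
    n_docs, n_words = documents.shape
    if n_factors < 1:
        raise ValueError("n_factors must be >= 1")
    if n_docs < n_factors:
        raise ValueError(f"need at least K={n_factors} documents, got {n_docs}")
    if n_words % 2 != 0:
        raise ValueError("vocabulary size must be even (pos/neg channel per edge)")
    if n_regions is None:
        e = n_words // 2
        n_regions = int(round((1 + np.sqrt(1 + 8 * e)) / 2))
    if alpha is None:
        alpha = 50.0 / n_factors

    seeds = np.random.SeedSequence(seed).spawn(n_restarts)
    best = None
    traces = []
    for idx, child in enumerate(seeds):
        rng = np.random.default_rng(child)
        gamma, lam, bounds, converged = _fit_single(
            documents, n_factors, alpha, eta, max_iter, tol, rng
        )
        traces.append(bounds)
        if best is None or bounds[-1] > best[3][-1]:
            best = (idx, gamma, lam, bounds, converged)

    idx, gamma, lam, bounds, converged = best
    if not converged:
        import warnings

        warnings.warn(
            f"LDA restart {idx} did not converge in {max_iter} iterations",
            UserWarning,
            stacklevel=2,
        )
    word_dist = lam / lam.sum(axis=1, keepdims=True)
    loadings = gamma / gamma.sum(axis=1, keepdims=True)
    meta = {
        "alpha": alpha,
        "eta": eta,
        "seed": seed,
        "restart": idx,
        "converged": bool(converged),
        "n_iterations": len(bounds),
        "bound_trace": [float(b) for b in bounds],
        "all_final_bounds": [float(t[-1]) for t in traces],
    }
    return FactorSet(word_dist, n_regions, meta), loadings


# ---------------------------------------------------------------------------
# Factor alignment (label switching)
# ---------------------------------------------------------------------------

def align_factors(reference: FactorSet, candidate: FactorSet):
    """Permute candidate factors to best match the reference.

    Solves the assignment maximizing the total lower-triangle Pearson
    correlation between matched signed matrices (Hungarian algorithm, which is
    exact for this objective).  Returns ``(permuted_candidate, permutation,
    match_correlations)`` where ``permutation[i]`` is the candidate index
    matched to reference factor i.
    """
    if reference.n_factors != candidate.n_factors:
        raise ValueError(
            f"factor count mismatch: {reference.n_factors} vs {candidate.n_factors}"
        )
    if reference.word_distributions.shape[1] != candidate.word_distributions.shape[1]:
        raise ValueError("vocabulary size mismatch")
    ref_tris = [lower_triangle(m) for m in reference.signed_matrices]
    cand_tris = [lower_triangle(m) for m in candidate.signed_matrices]
    k = reference.n_factors
    corr = np.zeros((k, k))
    for a in range(k):
        for b in range(k):
            corr[a, b] = np.corrcoef(ref_tris[a], cand_tris[b])[0, 1]
    rows, cols = linear_sum_assignment(-corr)
    perm = cols[np.argsort(rows)]
    match = corr[np.arange(k), perm]
    return candidate.permuted(perm), perm, match


def align_matrices(reference: list[np.ndarray], candidate: list[np.ndarray]):
    """Assignment between two lists of signed matrices (same objective as above)."""
    k = len(reference)
    if len(candidate) != k:
        raise ValueError("matrix list length mismatch")
    corr = np.zeros((k, k))
    for a in range(k):
        for b in range(k):
            corr[a, b] = np.corrcoef(lower_triangle(reference[a]), lower_triangle(candidate[b]))[0, 1]
    rows, cols = linear_sum_assignment(-corr)
    perm = cols[np.argsort(rows)]
    return perm, corr[np.arange(k), perm]
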