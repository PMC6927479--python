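"""Between-participant connectivity variability and its principal components.

Variability is the across-participant standard deviation of Fisher-z values
at each edge, summarized regionally by averaging over a parcel's incident
edges.  Connectome-wide patterns of individual differences come from a PCA
(by SVD) of the participants-by-edges matrix, with the number of retained
components decided by Horn's parallel analysis: observed eigenvalues are
kept while they exceed those of column-permuted (structure-free) resamples.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .core import stack_edges, devectorize

__all__ = [
    "VariabilityResult",
    "PCAResult",
    "edgewise_sd",
    "variability_group_contrast",
    "connectome_pca",
    "parallel_analysis",
    "component_behavior_corr",
]


@dataclass
class VariabilityResult:
    edge_sd: np.ndarray       # P x P matrix of across-participant SDs
    regional_sd: np.ndarray   # per-parcel mean of incident edge SDs
    n_participants: int


@dataclass
class PCAResult:
    loadings: np.ndarray        # edges x k
    scores: np.ndarray          # participants x k
    explained_frac: np.ndarray  # k fractions of total variance
    singular_values: np.ndarray
    retained_k: int | None = None


def edgewise_sd(connectomes) -> VariabilityResult:
    """Sample SD (ddof=1) of z values at each edge, with regional means."""
    edges = stack_edges(connectomes)
    n = edges.shape[0]
    if n < 3:
        raise ValueError("need at least 3 participants for edgewise SD")
    sd = edges.std(axis=0, ddof=1)
    p = _infer_p(edges.shape[1])
    sd_mat = devectorize(sd, p)
    regional = sd_mat.sum(axis=0) / (p - 1)
    return VariabilityResult(edge_sd=sd_mat, regional_sd=regional, n_participants=n)


def _infer_p(n_edges: int) -> int:
    p = int((1 + np.sqrt(1 + 8 * n_edges)) / 2)
    if p * (p - 1) // 2 != n_edges:
        raise ValueError(f"{n_edges} is not a triangular number")
    return p


def variability_group_contrast(connectomes, factor) -> dict:
    """Cohen's d of the edgewise-SD distributions between factor levels.

    For each level pair the SDs are computed within level and d is taken
    over the edge distribution (pooled SD denominator).
    """
    edges = stack_edges(connectomes)
    factor = np.asarray(factor)
    levels = np.unique(factor)
    sds = {}
    for g in levels:
        idx = np.flatnonzero(factor == g)
        if idx.size < 3:
            raise ValueError(f"level {g!r} has fewer than 3 participants")
        sds[g] = edges[idx].std(axis=0, ddof=1)
    out = {}
    for a, b in combinations(levels, 2):
        va, vb = sds[a], sds[b]
        pooled = np.sqrt((va.var(ddof=1) + vb.var(ddof=1)) / 2)
        d = (va.mean() - vb.mean()) / pooled if pooled > 0 else 0.0
        out[(a, b)] = float(d)
    return out


def connectome_pca(connectomes) -> PCAResult:
    """PCA of the participants x edges matrix via singular values.

    Columns (edges) are mean-centered; scores are the left singular vectors
    scaled by singular values; explained fractions come from the squared
    singular values.
    """
    edges = stack_edges(connectomes)
    if edges.shape[0] < 3:
        raise ValueError("need at least 3 participants for PCA")
    x = edges - edges.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    if not np.any(s > 1e-12):
        raise ValueError("data matrix has rank 0 after centering")
    total = (s**2).sum()
    return PCAResult(loadings=vt.T, scores=u * s,
                     explained_frac=s**2 / total, singular_values=s)


def _eigenvalues(x: np.ndarray) -> np.ndarray:
    """Covariance eigenvalues of a column-centered matrix, descending, via
    the Gram matrix (cheap when edges >> participants)."""
    n = x.shape[0]
    g = x @ x.T / (n - 1)
    w = np.linalg.eigvalsh(g)[::-1]
    return np.clip(w, 0.0, None)


def parallel_analysis(data: np.ndarray, n_iter: int = 5000,
                      criterion: str = "mean", seed: int = 0) -> int:
    """Horn's parallel analysis: number of components whose eigenvalues
    exceed those of resampled data.

    Each iteration independently permutes every column across rows
    (preserving column marginals while destroying correlation structure)
    and records the covariance eigenvalues.  The observed eigenvalues are
    compared rank-by-rank against the null criterion (mean by default,
    ``"p95"`` for the 95th percentile); components are retained while they
    exceed it, stopping at the first failure.
    """
    if n_iter < 100:
        raise ValueError("parallel analysis needs n_iter >= 100")
    if criterion not in ("mean", "p95"):
        raise ValueError("criterion must be 'mean' or 'p95'")
    data = np.asarray(data, dtype=float)
    n, m = data.shape
    x = data - data.mean(axis=0)
    obs = _eigenvalues(x)
    rng = np.random.default_rng(seed)
    null = np.empty((n_iter, obs.shape[0]))
    for it in range(n_iter):
        # independent column permutations via argsorted random keys
        order = np.argsort(rng.random((n, m)), axis=0)
        perm = np.take_along_axis(x, order, axis=0)
        null[it] = _eigenvalues(perm - perm.mean(axis=0))
    thresh = null.mean(axis=0) if criterion == "mean" else np.percentile(null, 95, axis=0)
    retained = 0
    for k in range(obs.shape[0]):
        if obs[k] > thresh[k]:
            retained += 1
        else:
            break
    return retained


def component_behavior_corr(scores: np.ndarray, behavior) -> list[dict]:
    """Pearson r (and two-sided p) of each component score with behavior,
    complete cases only."""
    behavior = np.asarray(behavior, dtype=float)
    ok = np.isfinite(behavior)
    if ok.sum() < 10:
        raise ValueError("need at least 10 complete behavior observations")
    out = []
    for k in range(scores.shape[1]):
        r, p = stats.pearsonr(scores[ok, k], behavior[ok])
        out.append({"component": k + 1, "r": float(r), "p": float(p),
                    "n": int(ok.sum())})
    return out
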