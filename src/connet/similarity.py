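"""Participant-by-participant connectome similarity and classical MDS.

Each participant's edge vector is correlated with every other participant's,
giving an N x N similarity matrix (stored Fisher-z transformed, as group
differences are reported on the z scale).  Group contrasts compare the
distributions of within-group pairwise similarities; classical (Torgerson)
MDS embeds participants from Euclidean distances between edge vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import stack_edges

__all__ = [
    "similarity_matrix",
    "mean_similarity",
    "group_similarity_contrast",
    "classical_mds",
    "group_centroids",
    "GroupContrast",
]

Z_CLIP = 7.0


def similarity_matrix(connectomes, clip_perfect: bool = False) -> np.ndarray:
    """N x N matrix of Fisher-z-transformed Pearson correlations between
    participants' edge vectors.  Diagonal is set to NaN (excluded from all
    statistics).  Off-diagonal |r| = 1 raises unless ``clip_perfect``, in
    which case z is capped at +/-7.
    """
    edges = stack_edges(connectomes)
    if edges.shape[0] < 2:
        raise ValueError("need at least 2 participants")
    sd = edges.std(axis=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"zero-variance edge vector for participant(s) {bad.tolist()}")
    r = np.corrcoef(edges)
    np.fill_diagonal(r, 0.0)
    r = np.clip(r, -1.0, 1.0)
    off = ~np.eye(r.shape[0], dtype=bool)
    perfect = np.abs(r) >= 1.0 - 1e-15
    if np.any(perfect & off):
        if not clip_perfect:
            i, j = np.where(perfect & off)
            raise ValueError(
                f"participants {i[0]} and {j[0]} have identical edge vectors "
                f"(|r| = 1); pass clip_perfect=True to cap at z = {Z_CLIP}")
        z = np.where(perfect, np.sign(r) * Z_CLIP, np.arctanh(np.where(perfect, 0, r)))
    else:
        z = np.arctanh(r)
    np.fill_diagonal(z, np.nan)
    return z


def _within_values(s: np.ndarray, members: np.ndarray) -> np.ndarray:
    sub = s[np.ix_(members, members)]
    iu = np.triu_indices(len(members), k=1)
    return sub[iu]


def mean_similarity(s: np.ndarray) -> float:
    """Mean off-diagonal similarity, z scale."""
    iu = np.triu_indices(s.shape[0], k=1)
    return float(np.nanmean(s[iu]))


@dataclass
class GroupContrast:
    delta: float       # difference of mean within-group similarity, z scale
    cohens_d: float    # pooled-SD effect size over pairwise values
    perm_p: float      # two-sided label-permutation p


def group_similarity_contrast(s: np.ndarray, labels, group_a, group_b,
                              n_perm: int = 1000, seed: int = 0) -> GroupContrast:
    """Contrast within-group pairwise similarity between two groups.

    The pairwise similarity values are not independent, so the Cohen's d is
    descriptive; the permutation test (reshuffling group labels over the
    pooled membership and recomputing the contrast) supplies the p-value.
    """
    labels = np.asarray(labels)
    mem_a = np.flatnonzero(labels == group_a)
    mem_b = np.flatnonzero(labels == group_b)
    if mem_a.size < 2 or mem_b.size < 2:
        raise ValueError("each group needs at least 2 members")
    if np.intersect1d(mem_a, mem_b).size:
        raise ValueError("groups overlap")

    def contrast(a_idx, b_idx):
        va, vb = _within_values(s, a_idx), _within_values(s, b_idx)
        delta = va.mean() - vb.mean()
        ss = ((va - va.mean()) ** 2).sum() + ((vb - vb.mean()) ** 2).sum()
        dof = va.size + vb.size - 2
        pooled = np.sqrt(ss / dof) if dof > 0 else 0.0
        d = delta / pooled if pooled > 0 else 0.0
        return delta, d

    delta_obs, d_obs = contrast(mem_a, mem_b)
    pool = np.concatenate([mem_a, mem_b])
    na = mem_a.size
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        dlt, _ = contrast(perm[:na], perm[na:])
        if abs(dlt) >= abs(delta_obs) - 1e-15:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return GroupContrast(delta=float(delta_obs), cohens_d=float(d_obs), perm_p=float(p))


def classical_mds(connectomes, k: int = 2) -> np.ndarray:
    """Torgerson classical MDS of participants from Euclidean distances
    between their edge vectors.

    Double-centers the squared distance matrix, takes the top-k eigenpairs,
    and scales eigenvectors by sqrt(eigenvalue).  Axis signs are fixed so
    the first participant has non-negative coordinates.
    """
    edges = stack_edges(connectomes)
    n = edges.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} participants")
    sq = ((edges[:, None, :] - edges[None, :, :]) ** 2).sum(axis=2) if edges.shape[1] < 2000 \
        else _sq_dists(edges)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ sq @ j
    w, v = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    if np.all(np.abs(w[:k]) < 1e-12):
        return np.zeros((n, k))  # all points identical
    if np.sum(w > 1e-12) < k:
        raise ValueError(f"fewer than k={k} positive eigenvalues")
    coords = v[:, :k] * np.sqrt(w[:k])
    for axis in range(k):
        if coords[0, axis] < 0:
            coords[:, axis] *= -1
    return coords


def _sq_dists(edges: np.ndarray) -> np.ndarray:
    g = edges @ edges.T
    sq = np.diag(g)[:, None] + np.diag(g)[None, :] - 2 * g
    return np.maximum(sq, 0.0)


def group_centroids(coords: np.ndarray, labels) -> dict:
    """Per-group mean coordinate and per-axis standard error of the mean."""
    labels = np.asarray(labels)
    out = {}
    for g in np.unique(labels):
        members = np.flatnonzero(labels == g)
        if members.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
        pts = coords[members]
        out[g] = {
            "mean": pts.mean(axis=0),
            "sem": pts.std(axis=0, ddof=1) / np.sqrt(members.size),
            "n": int(members.size),
        }
    return out
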