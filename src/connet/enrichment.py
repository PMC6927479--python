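"""Edgewise brain-behavior association and network-pair enrichment.

Associations are computed two ways, mirroring the two roles they play:
(1) a per-edge linear model of the behavior score on the edge z value with
manufacturer and sex covariates, whose edge-coefficient t-statistics form
the association matrix used for split-half reliability; and (2) plain
edgewise Pearson correlations, binarized at an uncorrected p < alpha, which
feed the network-pair enrichment.  Enrichment of suprathreshold edges
within each network pair is tested hypergeometrically, calibrated against
a pooled permutation null (behavior labels shuffled across participants,
null hypergeometric p-values pooled over all pairs), and corrected across
pairs by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import stack_edges, edge_index_pairs

logger = logging.getLogger(__name__)

__all__ = [
    "edgewise_behavior_glm",
    "split_half_reliability",
    "edgewise_behavior_r",
    "binarize_associations",
    "network_pair_index",
    "hypergeometric_enrichment",
    "permutation_null",
    "fdr_bh",
    "enrichment_table",
    "manufacturer_interaction_check",
]


def _dummy_code(values, name: str) -> np.ndarray:
    values = np.asarray(values).astype(str)
    levels = sorted(pd.unique(values))
    if len(levels) < 2:
        raise ValueError(f"covariate '{name}' has a single level; design is rank-deficient")
    return np.column_stack([(values == l).astype(float) for l in levels[1:]])


def _complete_cases(behavior, *covariate_arrays):
    behavior = np.asarray(behavior, dtype=float)
    ok = np.isfinite(behavior)
    n_drop = int((~ok).sum())
    if n_drop:
        logger.info("dropping %d participants with missing behavior", n_drop)
    return ok


def edgewise_behavior_glm(connectomes, behavior, manufacturer=None, sex=None) -> dict:
    """Per-edge linear model of behavior on {edge z, manufacturer, sex}.

    Returns the t-statistic of the edge coefficient per edge (plus the
    coefficients and two-sided p).  Computed by Frisch-Waugh-Lovell
    residualization: behavior and every edge are residualized on the shared
    covariate design, after which the per-edge simple regression t equals
    the multiple-regression t of the edge term exactly.
    Complete behavior cases only; dropped rows are logged.
    """
    edges = stack_edges(connectomes)
    ok = _complete_cases(behavior)
    y = np.asarray(behavior, dtype=float)[ok]
    edges = edges[ok]
    n = y.shape[0]
    design = [np.ones((n, 1))]
    if manufacturer is not None:
        design.append(_dummy_code(np.asarray(manufacturer)[ok], "manufacturer"))
    if sex is not None:
        design.append(_dummy_code(np.asarray(sex)[ok], "sex"))
    z = np.column_stack(design)
    n_cov = z.shape[1]
    if n <= n_cov + 1:
        raise ValueError("too few complete cases for the covariate design")
    if np.linalg.matrix_rank(z) < n_cov:
        raise ValueError("covariate design is rank-deficient")
    # residualize on covariates
    zt_z_inv = np.linalg.inv(z.T @ z)
    hat = z @ zt_z_inv
    y_res = y - hat @ (z.T @ y)
    e_res = edges - hat @ (z.T @ edges)
    xx = (e_res**2).sum(axis=0)
    xy = y_res @ e_res
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = xy / xx
    beta = np.nan_to_num(beta, nan=0.0)
    df = n - n_cov - 1
    rss = (y_res**2).sum() - beta * xy
    rss = np.maximum(rss, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / df / xx)
        t = beta / se
    t = np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)
    p = 2 * stats.t.sf(np.abs(t), df)
    return {"t": t, "beta": beta, "p": p, "df": int(df), "n": int(n)}


def split_half_reliability(t_a: np.ndarray, t_b: np.ndarray) -> float:
    """Pearson r between two halves' edgewise association statistics."""
    a, b = np.asarray(t_a, float).ravel(), np.asarray(t_b, float).ravel()
    if a.shape != b.shape:
        raise ValueError("association matrices have different sizes")
    return float(np.corrcoef(a, b)[0, 1])


def edgewise_behavior_r(connectomes, behavior) -> tuple[np.ndarray, int]:
    """Plain edgewise Pearson correlation with behavior, complete cases."""
    edges = stack_edges(connectomes)
    ok = _complete_cases(behavior)
    y = np.asarray(behavior, dtype=float)[ok]
    return _corr_with(edges[ok], y), int(ok.sum())


def _corr_with(edges: np.ndarray, y: np.ndarray) -> np.ndarray:
    yc = y - y.mean()
    ec = edges - edges.mean(axis=0)
    den = np.sqrt((yc @ yc) * (ec**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (yc @ ec) / den
    return np.nan_to_num(r, nan=0.0)


def binarize_associations(r_values: np.ndarray, n: int, alpha: float = 0.05) -> np.ndarray:
    """1 where the two-sided p of an edgewise Pearson r is below alpha."""
    if n < 10:
        raise ValueError("need at least 10 observations to binarize")
    r = np.clip(np.asarray(r_values, float), -0.9999999, 0.9999999)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    return (p < alpha).astype(int)


def network_pair_index(parcels_or_labels) -> tuple[list, np.ndarray, np.ndarray]:
    """Map each edge to its (network A, network B) pair.

    Returns the ordered pair list, the per-edge pair index (-1 for edges
    touching an unassigned parcel), and the per-pair edge counts.
    """
    if isinstance(parcels_or_labels, pd.DataFrame):
        labels = parcels_or_labels["template_network"].to_numpy()
    else:
        labels = np.asarray(parcels_or_labels)
    p = labels.shape[0]
    i, j = edge_index_pairs(p)
    nets = sorted({str(l) for l in labels if l != -1})
    pairs = list(combinations_with_replacement(nets, 2))
    pair_pos = {frozenset((a, b)) if a != b else frozenset((a,)): k
                for k, (a, b) in enumerate(pairs)}
    idx = np.full(i.shape[0], -1, dtype=int)
    for e in range(i.shape[0]):
        la, lb = labels[i[e]], labels[j[e]]
        if la == -1 or lb == -1:
            continue
        key = frozenset((str(la),)) if la == lb else frozenset((str(la), str(lb)))
        idx[e] = pair_pos[key]
    counts = np.bincount(idx[idx >= 0], minlength=len(pairs))
    return pairs, idx, counts


def hypergeometric_enrichment(binary_edges: np.ndarray, pair_idx: np.ndarray,
                              pair_counts: np.ndarray) -> np.ndarray:
    """One-sided hypergeometric enrichment p per network pair.

    For a pair with n_pair edges and k hits, against K total hits among the
    N scored edges: p = P(X >= k), X ~ Hypergeometric(N, K, n_pair).
    Pairs with no edges get NaN.
    """
    hits = np.asarray(binary_edges).astype(int)
    scored = pair_idx >= 0
    n_total = int(scored.sum())
    k_total = int(hits[scored].sum())
    k_pair = np.bincount(pair_idx[scored], weights=hits[scored],
                         minlength=pair_counts.shape[0]).astype(int)
    p = np.full(pair_counts.shape[0], np.nan)
    nz = pair_counts > 0
    p[nz] = stats.hypergeom.sf(k_pair[nz] - 1, n_total, k_total, pair_counts[nz])
    return p


def permutation_null(connectomes, behavior, pair_idx: np.ndarray,
                     pair_counts: np.ndarray, observed_p: np.ndarray,
                     n_perm: int = 10000, alpha: float = 0.05,
                     seed: int = 0) -> np.ndarray:
    """Pooled-null empirical p per network pair.

    Behavior labels are permuted across participants ``n_perm`` times; each
    permutation yields a full set of per-pair hypergeometric p-values, all
    of which are pooled into one null distribution.  Each pair's empirical
    p is (1 + #{pooled null <= observed}) / (1 + n_pooled) — smaller
    hypergeometric p means more enriched.
    """
    if n_perm < 100:
        raise ValueError("permutation null needs n_perm >= 100")
    edges = stack_edges(connectomes)
    ok = np.isfinite(np.asarray(behavior, dtype=float))
    y = np.asarray(behavior, dtype=float)[ok]
    edges = edges[ok]
    n = y.shape[0]
    rng = np.random.default_rng(seed)
    # |r| cutoff equivalent to the two-sided p < alpha threshold
    t_crit = stats.t.isf(alpha / 2, n - 2)
    r_crit = t_crit / np.sqrt(n - 2 + t_crit**2)
    ec = edges - edges.mean(axis=0)
    edge_norm = np.sqrt((ec**2).sum(axis=0))
    edge_norm[edge_norm == 0] = np.inf
    y_norm = np.linalg.norm(y - y.mean())
    pooled = []
    for _ in range(n_perm):
        yc = rng.permutation(y)
        yc = yc - yc.mean()
        r = (yc @ ec) / (y_norm * edge_norm)
        hits = (np.abs(r) > r_crit).astype(int)
        pooled.append(hypergeometric_enrichment(hits, pair_idx, pair_counts))
    pooled = np.concatenate(pooled)
    pooled = pooled[np.isfinite(pooled)]
    pooled.sort()
    out = np.full(observed_p.shape[0], np.nan)
    fin = np.isfinite(observed_p)
    ranks = np.searchsorted(pooled, observed_p[fin], side="right")
    out[fin] = (1 + ranks) / (1 + pooled.size)
    return out


def fdr_bh(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up FDR: significance flags and q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=bool), np.array([])
    fin = np.isfinite(p)
    reject = np.zeros(p.shape, dtype=bool)
    qvals = np.full(p.shape, np.nan)
    if fin.any():
        rej, qv, *_ = multipletests(p[fin], alpha=q, method="fdr_bh")
        reject[fin] = rej
        qvals[fin] = qv
    return reject, qvals


def enrichment_table(connectomes, behavior, labels, n_perm: int = 10000,
                     alpha: float = 0.05, q: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Full network-pair enrichment: counts, hypergeometric p, pooled
    permutation p, BH-FDR q, and the mean sign of suprathreshold r values."""
    pairs, pair_idx, pair_counts = network_pair_index(labels)
    r, n = edgewise_behavior_r(connectomes, behavior)
    hits = binarize_associations(r, n, alpha)
    hyper_p = hypergeometric_enrichment(hits, pair_idx, pair_counts)
    perm_p = permutation_null(connectomes, behavior, pair_idx, pair_counts,
                              hyper_p, n_perm=n_perm, alpha=alpha, seed=seed)
    reject, qvals = fdr_bh(perm_p, q=q)
    scored = pair_idx >= 0
    k_total = int(hits[scored].sum())
    n_total = int(scored.sum())
    rows = []
    for k, (a, b) in enumerate(pairs):
        in_pair = pair_idx == k
        k_hits = int(hits[in_pair].sum())
        supra = in_pair & (hits == 1)
        mean_sign = float(np.sign(r[supra]).mean()) if supra.any() else 0.0
        rows.append({
            "network_a": a, "network_b": b,
            "n_pair_edges": int(pair_counts[k]), "k_hits": k_hits,
            "K_total_hits": k_total, "N_total_edges": n_total,
            "hyper_p": hyper_p[k], "perm_p": perm_p[k],
            "fdr_q": qvals[k], "significant": bool(reject[k]),
            "mean_sign": mean_sign,
        })
    return pd.DataFrame(rows)


def manufacturer_interaction_check(connectomes, behavior, manufacturer,
                                   sex=None) -> dict:
    """Mean R-squared gain from adding edge-by-manufacturer interactions.

    For every edge, fits the behavior model with and without interaction
    terms between the edge value and the manufacturer dummies; reports the
    mean R-squared difference over edges (small values argue the
    brain-behavior association is not manufacturer-driven).
    """
    edges = stack_edges(connectomes)
    ok = _complete_cases(behavior)
    y = np.asarray(behavior, dtype=float)[ok]
    edges = edges[ok]
    n = y.shape[0]
    manu = _dummy_code(np.asarray(manufacturer)[ok], "manufacturer")
    base_cols = [np.ones((n, 1)), manu]
    if sex is not None:
        base_cols.append(_dummy_code(np.asarray(sex)[ok], "sex"))
    zbase = np.column_stack(base_cols)
    n_inter = manu.shape[1]
    if n <= zbase.shape[1] + 1 + n_inter:
        raise ValueError("too few participants for the interaction design")
    tss = ((y - y.mean())**2).sum()
    dr2 = np.empty(edges.shape[1])
    for e in range(edges.shape[1]):
        x = edges[:, e:e + 1]
        x_main = np.column_stack([zbase, x])
        x_int = np.column_stack([x_main, manu * x])
        r2_main = 1 - _rss(x_main, y) / tss
        r2_int = 1 - _rss(x_int, y) / tss
        dr2[e] = r2_int - r2_main
    null_expect = n_inter / (n - 1)   # expected inflation from added terms
    return {"mean_delta_r2": float(dr2.mean()), "delta_r2": dr2,
            "null_expectation": float(null_expect), "n": int(n)}


def _rss(x: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid)
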