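"""Edgewise scanner/batch-effect quantification and distance dependence.

Scanner-manufacturer effects on connectivity are measured three ways: a
one-way ANOVA per edge (with the fraction of significant edges and a
per-parcel average of incident F-statistics), point-biserial correlations
per edge for two-level contrasts, and the correlation of those edgewise
point-biserial values with inter-parcel Euclidean distance — the
"short-to-long" gradient.  Participant-level covariates (mean FD, site
altitude) are partialed out of the edgewise profile by residualizing on
their own edgewise correlation profiles before the distance regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .core import stack_edges, centroid_distances, devectorize, edge_index_pairs

__all__ = [
    "BatchEffectResult",
    "edgewise_anova",
    "edgewise_point_biserial",
    "distance_dependence",
    "pairwise_manufacturer_contrasts",
]


@dataclass
class BatchEffectResult:
    f_edges: np.ndarray                  # per-edge one-way F
    p_edges: np.ndarray
    frac_significant: float
    alpha: float
    regional_f: np.ndarray               # per-parcel mean incident F
    df_between: int
    df_within: int
    r_pb: np.ndarray | None = None       # per-edge point-biserial (2 levels)
    distance_r: float | None = None
    covariates_partialed: list = field(default_factory=list)


def _edge_matrix(connectomes) -> np.ndarray:
    return stack_edges(connectomes)


def edgewise_anova(connectomes, factor, alpha: float = 0.001) -> BatchEffectResult:
    """Classical one-way ANOVA of a categorical factor at every edge.

    The significant-edge fraction defaults to p < 0.001, matching the
    convention used when reporting manufacturer effects; the per-parcel
    summary averages F over all edges incident to each parcel.
    """
    edges = _edge_matrix(connectomes)
    factor = np.asarray(factor)
    levels = np.unique(factor)
    if levels.size < 2:
        raise ValueError("factor needs at least 2 levels")
    n = edges.shape[0]
    group_idx = [np.flatnonzero(factor == g) for g in levels]
    for g, idx in zip(levels, group_idx):
        if idx.size < 2:
            raise ValueError(f"factor level {g!r} has fewer than 2 participants")

    grand = edges.mean(axis=0)
    ssb = np.zeros(edges.shape[1])
    ssw = np.zeros(edges.shape[1])
    for idx in group_idx:
        gm = edges[idx].mean(axis=0)
        ssb += idx.size * (gm - grand) ** 2
        ssw += ((edges[idx] - gm) ** 2).sum(axis=0)
    dfb = levels.size - 1
    dfw = n - levels.size
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / dfb) / (ssw / dfw)
    f = np.where(ssw == 0, np.where(ssb <= 1e-300, 0.0, np.inf), f)
    f = np.nan_to_num(f, nan=0.0)
    p = stats.f.sf(f, dfb, dfw)

    n_parcels = _infer_p(edges.shape[1])
    f_mat = devectorize(f, n_parcels)
    regional = f_mat.sum(axis=0) / (n_parcels - 1)
    return BatchEffectResult(
        f_edges=f, p_edges=p, frac_significant=float(np.mean(p < alpha)),
        alpha=alpha, regional_f=regional, df_between=dfb, df_within=dfw)


def _infer_p(n_edges: int) -> int:
    p = int((1 + np.sqrt(1 + 8 * n_edges)) / 2)
    if p * (p - 1) // 2 != n_edges:
        raise ValueError(f"{n_edges} is not a triangular number")
    return p


def edgewise_point_biserial(connectomes, binary_factor) -> np.ndarray:
    """Point-biserial correlation (Pearson r with 0/1 coding) per edge."""
    edges = _edge_matrix(connectomes)
    factor = np.asarray(binary_factor)
    levels = np.unique(factor)
    if levels.size != 2:
        raise ValueError(f"binary factor must have exactly 2 levels, got {levels.size}")
    dummy = (factor == levels[1]).astype(float)
    return _pearson_profile(edges, dummy)


def _pearson_profile(edges: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Pearson r of a participant-level variable with every edge."""
    xc = x - x.mean()
    ec = edges - edges.mean(axis=0)
    num = xc @ ec
    den = np.sqrt((xc @ xc) * (ec**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / den
    return np.nan_to_num(r, nan=0.0)


def distance_dependence(r_pb: np.ndarray, parcels: pd.DataFrame,
                        covariate_profiles: dict[str, np.ndarray] | None = None):
    """Correlate an edgewise profile with inter-parcel Euclidean distance.

    ``covariate_profiles`` maps covariate names to their own edgewise
    correlation profiles; these are regressed out of ``r_pb`` (ordinary
    least squares across edges) before correlating the residual with
    distance, yielding a covariate-adjusted distance dependence.
    """
    dist = centroid_distances(parcels)
    if np.std(dist) == 0:
        raise ValueError("inter-parcel distances are constant")
    y = np.asarray(r_pb, dtype=float)
    if y.shape != dist.shape:
        raise ValueError("edgewise profile length does not match parcel count")
    partialed = []
    if covariate_profiles:
        x = np.column_stack([np.ones_like(y)] +
                            [np.asarray(v, float) for v in covariate_profiles.values()])
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        y = y - x @ beta
        partialed = list(covariate_profiles)
    r = float(np.corrcoef(y, dist)[0, 1])
    n = y.size
    t = r * np.sqrt((n - 2) / max(1e-300, 1 - r * r))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return {"distance_r": r, "p": float(p), "n_edges": int(n),
            "covariates_partialed": partialed}


def pairwise_manufacturer_contrasts(connectomes, manufacturer, parcels,
                                    fd=None, extra_covariates: dict | None = None,
                                    collapse: tuple | None = None) -> pd.DataFrame:
    """Distance-dependence analysis for every unordered manufacturer pair.

    For each pair, participants from the two manufacturers are pooled, the
    edgewise point-biserial profile of the manufacturer contrast is
    computed, participant-level covariates (mean FD by default; e.g. site
    altitude via ``extra_covariates``) are partialed out as edgewise
    profiles, and the residual profile is correlated with distance.
    ``collapse`` merges the named manufacturers into one level first.
    """
    edges = _edge_matrix(connectomes)
    manufacturer = np.asarray(manufacturer, dtype=object).copy()
    if collapse:
        merged = "/".join(str(c) for c in collapse)
        manufacturer[np.isin(manufacturer, list(collapse))] = merged
    levels = [g for g in pd.unique(manufacturer)]
    if len(levels) < 2:
        raise ValueError("need at least 2 manufacturer levels")
    fd = None if fd is None else np.asarray(fd, dtype=float)
    extra = {k: np.asarray(v, float) for k, v in (extra_covariates or {}).items()}

    rows = []
    for a, b in combinations(sorted(map(str, levels)), 2):
        sel = np.flatnonzero(np.isin(manufacturer, [a, b]))
        if (manufacturer[sel] == a).sum() == 0 or (manufacturer[sel] == b).sum() == 0:
            warnings.warn(f"manufacturer pair ({a}, {b}) has an empty level; skipped")
            continue
        sub = edges[sel]
        dummy = (manufacturer[sel] == b).astype(float)
        r_pb = _pearson_profile(sub, dummy)
        profiles = {}
        if fd is not None:
            profiles["fd_mean"] = _pearson_profile(sub, fd[sel])
        for name, vals in extra.items():
            profiles[name] = _pearson_profile(sub, vals[sel])
        res = distance_dependence(r_pb, parcels, profiles or None)
        rows.append({"level_a": a, "level_b": b, "distance_r": res["distance_r"],
                     "p": res["p"], "n_participants": int(sel.size),
                     "covariates": ",".join(res["covariates_partialed"])})
    return pd.DataFrame(rows)
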