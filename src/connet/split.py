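"""Demographically matched, family-preserving discovery/replication split.

Family units are never divided across arms; singleton and multi-member unit
counts per arm differ by at most one; a randomized greedy swap search then
minimizes the worst absolute standardized mean difference across the
matching variables (continuous variables directly, categorical variables
through their one-hot indicator levels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SplitResult", "matched_split", "balance_report"]

DISCOVERY = "discovery"
REPLICATION = "replication"


@dataclass
class SplitResult:
    assignment: pd.Series            # participant_id -> arm
    balance: pd.DataFrame            # per-variable balance statistics
    objective: float                 # final max |standardized mean difference|
    seed: int

    def arm_ids(self, arm: str) -> np.ndarray:
        return self.assignment.index[self.assignment == arm].to_numpy()


def _design_columns(table: pd.DataFrame, variables) -> pd.DataFrame:
    """Numeric matrix: continuous variables as-is, categoricals one-hot."""
    cols = {}
    for v in variables:
        if v not in table.columns:
            raise ValueError(f"matching variable '{v}' not in participant table")
        s = table[v]
        if s.isna().all():
            raise ValueError(f"matching variable '{v}' is entirely missing")
        if pd.api.types.is_numeric_dtype(s):
            cols[v] = s.astype(float).fillna(s.astype(float).mean())
        else:
            for level, ind in pd.get_dummies(s).items():
                cols[f"{v}={level}"] = ind.astype(float)
    return pd.DataFrame(cols, index=table.index)


def _max_abs_smd(sum_a, sum_b, sumsq, n_a, n_b, n_total):
    """Max absolute standardized mean difference given arm sums."""
    mean_a = sum_a / n_a
    mean_b = sum_b / n_b
    total_mean = (sum_a + sum_b) / n_total
    var = sumsq / n_total - total_mean**2
    sd = np.sqrt(np.maximum(var, 1e-12))
    return float(np.max(np.abs(mean_a - mean_b) / sd))


def matched_split(table: pd.DataFrame, variables, seed: int = 0,
                  n_sweeps: int = 20) -> SplitResult:
    """Assign family units to two matched arms.

    Parameters
    ----------
    table : participant table with family_id and the matching variables.
    variables : names of the matching variables (e.g. site, age_months, sex,
        ethnicity, grade, parental_education, handedness, income, anesthesia).
    seed : RNG seed for the initial assignment, sweep order and tie-breaks.
    n_sweeps : passes of the greedy swap search over all unit pairs.
    """
    if "family_id" not in table.columns:
        raise ValueError("participant table needs a family_id column")
    design = _design_columns(table, variables)
    x = design.to_numpy()
    n_total = len(table)

    fam = table["family_id"].to_numpy()
    units = []
    for fid in pd.unique(fam):
        idx = np.flatnonzero(fam == fid)
        units.append(idx)
    sizes = np.array([len(u) for u in units])
    if len(units) < 2:
        raise ValueError("need at least 2 family units to split")
    if sizes.max() > n_total / 2:
        raise ValueError("a single family exceeds half the cohort; cannot balance arms")

    unit_sums = np.stack([x[u].sum(axis=0) for u in units])  # units x vars
    sumsq = (x**2).sum(axis=0)

    rng = np.random.default_rng(seed)
    arm = np.zeros(len(units), dtype=int)  # 0 = discovery, 1 = replication
    # balanced initial assignment within each unit-size category
    for size in np.unique(sizes):
        members = np.flatnonzero(sizes == size)
        members = rng.permutation(members)
        arm[members[: len(members) // 2]] = 1

    def objective(arm_vec):
        in_b = arm_vec == 1
        n_b = int(sizes[in_b].sum())
        n_a = n_total - n_b
        if n_a == 0 or n_b == 0:
            return np.inf
        sum_b = unit_sums[in_b].sum(axis=0)
        sum_a = unit_sums.sum(axis=0) - sum_b
        return _max_abs_smd(sum_a, sum_b, sumsq, n_a, n_b, n_total)

    best = objective(arm)
    # greedy swap search: exchange two units of equal size between arms;
    # accept only strict improvements (monotone)
    for _ in range(n_sweeps):
        improved = False
        order = rng.permutation(len(units))
        for ui in order:
            partners = np.flatnonzero((arm != arm[ui]) & (sizes == sizes[ui]))
            if partners.size == 0:
                continue
            partners = rng.permutation(partners)
            for uj in partners[: min(40, partners.size)]:
                arm[ui], arm[uj] = arm[uj], arm[ui]
                cand = objective(arm)
                if cand < best - 1e-12:
                    best = cand
                    improved = True
                    break
                arm[ui], arm[uj] = arm[uj], arm[ui]
        if not improved:
            break

    arm_of_participant = np.empty(n_total, dtype=object)
    for u, a in zip(units, arm):
        arm_of_participant[u] = DISCOVERY if a == 0 else REPLICATION
    pid = table["participant_id"] if "participant_id" in table.columns else table.index
    assignment = pd.Series(arm_of_participant, index=pd.Index(pid, name="participant_id"),
                           name="arm")
    balance = balance_frame(assignment, table, variables)
    return SplitResult(assignment=assignment, balance=balance,
                       objective=best, seed=seed)


def balance_frame(assignment: pd.Series, table: pd.DataFrame, variables) -> pd.DataFrame:
    """Per-variable balance: standardized mean difference for continuous
    variables, chi-square statistic for categoricals."""
    arm = assignment.to_numpy()
    in_a, in_b = arm == DISCOVERY, arm == REPLICATION
    rows = []
    for v in variables:
        s = table[v].reset_index(drop=True)
        if pd.api.types.is_numeric_dtype(s):
            a, b = s[in_a].astype(float), s[in_b].astype(float)
            sd = s.astype(float).std(ddof=0)
            smd = (a.mean() - b.mean()) / sd if sd > 0 else 0.0
            rows.append((v, "continuous", float(smd), np.nan))
        else:
            ct = pd.crosstab(s, pd.Series(arm, name="arm"))
            chi2 = stats.chi2_contingency(ct)[0] if ct.shape[0] > 1 else 0.0
            rows.append((v, "categorical", np.nan, float(chi2)))
    return pd.DataFrame(rows, columns=["variable", "kind", "smd", "chi2"])


def balance_report(split: SplitResult, table: pd.DataFrame, variables) -> pd.DataFrame:
    """Arm-comparison tests: Welch t (continuous) and chi-square
    (categorical) per matching variable, with p-values."""
    arm = split.assignment.to_numpy()
    in_a, in_b = arm == DISCOVERY, arm == REPLICATION
    if in_a.sum() < 2 or in_b.sum() < 2:
        raise ValueError("each arm needs at least 2 members")
    rows = []
    for v in variables:
        s = table[v].reset_index(drop=True)
        if pd.api.types.is_numeric_dtype(s):
            a, b = s[in_a].astype(float).dropna(), s[in_b].astype(float).dropna()
            t, p = stats.ttest_ind(a, b, equal_var=False)
            sd = s.astype(float).std(ddof=0)
            smd = (a.mean() - b.mean()) / sd if sd > 0 else 0.0
            rows.append((v, "welch_t", float(t), float(p), float(smd)))
        else:
            ct = pd.crosstab(s, pd.Series(arm, name="arm"))
            if ct.shape[0] > 1:
                chi2, p = stats.chi2_contingency(ct)[:2]
            else:
                chi2, p = 0.0, 1.0
            rows.append((v, "chi2", float(chi2), float(p), np.nan))
    return pd.DataFrame(rows, columns=["variable", "test", "statistic", "p", "smd"])
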