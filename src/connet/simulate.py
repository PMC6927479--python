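"""Synthetic multi-site resting-state cohort generator.

Emulates the statistical structure of a large multi-site pediatric
resting-state study: block-structured group connectivity over a cortical
parcellation, participant-level edge variability with family sharing
(singletons / siblings / twins), additive scanner-manufacturer bias with a
"short-to-long" distance dependence, head-motion summaries, and a
cognition-like composite score with planted network-pair associations.

All randomness derives from named substreams of a single master seed, so a
cohort is byte-identical across runs and adding participants does not
perturb the parcel geometry.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Connectome, fisher_z

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "simulate_cohort",
    "simulate_timeseries",
    "flag_frames",
    "motion_inclusion",
    "frames_duration_minutes",
    "write_cohort",
]

# A 333-parcel cortical parcellation grouped into the canonical large-scale
# functional networks (sizes sum to 333).
DEFAULT_NETWORK_SIZES: dict[str, int] = {
    "Default": 41,
    "SomatomotorHand": 38,
    "SomatomotorMouth": 8,
    "Visual": 39,
    "FrontoParietal": 24,
    "Auditory": 24,
    "CinguloParietal": 5,
    "RetrosplenialTemporal": 8,
    "CinguloOperc": 40,
    "VentralAttn": 23,
    "Salience": 4,
    "DorsalAttn": 32,
    "None": 47,
}

# Within-network correlation (r) of the group template, per network.
DEFAULT_WITHIN: dict[str, float] = {
    "Default": 0.50,
    "SomatomotorHand": 0.65,
    "SomatomotorMouth": 0.65,
    "Visual": 0.60,
    "FrontoParietal": 0.40,
    "Auditory": 0.55,
    "CinguloParietal": 0.45,
    "RetrosplenialTemporal": 0.45,
    "CinguloOperc": 0.45,
    "VentralAttn": 0.40,
    "Salience": 0.40,
    "DorsalAttn": 0.45,
    "None": 0.20,
}

# Between-network correlations deviating from the generic background,
# including the task-negative/task-positive anticorrelation.
DEFAULT_BETWEEN_SPECIAL: dict[tuple[str, str], float] = {
    ("Default", "DorsalAttn"): -0.15,
    ("Default", "VentralAttn"): -0.08,
    ("Default", "FrontoParietal"): 0.12,
    ("Visual", "SomatomotorHand"): 0.12,
    ("Visual", "DorsalAttn"): 0.15,
    ("SomatomotorHand", "SomatomotorMouth"): 0.25,
    ("CinguloOperc", "Salience"): 0.15,
}

# Planted brain-behavior effects: (network A, network B, correlation of the
# behavior score with mean connectivity over the pair's edges).  Negative for
# the anticorrelated pair: stronger anticorrelation <-> higher score.
DEFAULT_PLANTED_PAIRS: list[tuple[str, str, float]] = [
    ("Default", "DorsalAttn", -0.12),
    ("Default", "Default", 0.10),
    ("Visual", "Visual", 0.10),
    ("FrontoParietal", "SomatomotorHand", 0.10),
]


def _default_manufacturers(n_sites: int) -> dict[int, str]:
    """Roughly 5:2:1 split of sites across manufacturers A, B, C."""
    out = {}
    for s in range(n_sites):
        frac = s / n_sites
        out[s] = "A" if frac < 0.625 else ("B" if frac < 0.875 else "C")
    return out


@dataclass
class SimConfig:
    """Conditions for one synthetic cohort.

    Block means are given as correlations in (-1, 1); participant deviations
    and manufacturer bias act additively in Fisher-z space.  Manufacturer A
    is the reference (zero bias); bias for the others is ``a + b * d_ij`` in
    z units with ``d_ij`` the inter-centroid Euclidean distance in mm.
    """

    n_parcels: int = 333
    network_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_NETWORK_SIZES))
    within_block_mean: dict[str, float] | float = field(
        default_factory=lambda: dict(DEFAULT_WITHIN))
    between_block_mean: float = 0.05
    between_block_special: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_BETWEEN_SPECIAL))
    participant_sd: float = 0.23
    # fraction of participant edge variance shared within each network-pair
    # block (a per-participant latent factor per block); keeps the marginal
    # edge SD at participant_sd while giving individual differences the
    # low-rank block structure real connectomes show
    edge_block_rho: float = 0.3
    n_participants: int = 400
    n_sites: int = 8
    manufacturer_of_site: dict[int, str] | None = None
    # per non-reference manufacturer; scalars broadcast to every non-A level
    manufacturer_bias_intercept: dict[str, float] | float = field(
        default_factory=lambda: {"B": -0.010, "C": -0.020})
    manufacturer_bias_slope: dict[str, float] | float = field(
        default_factory=lambda: {"B": 0.00013, "C": 0.00026})
    # extra participant-level noise for non-reference scanners (lower
    # within-manufacturer similarity, as observed for Philips/GE)
    manufacturer_noise_scale: dict[str, float] = field(
        default_factory=lambda: {"B": 1.12, "C": 1.10})
    fd_mean: float = 0.11
    fd_sd: float = 0.04
    fd_range: tuple[float, float] = (0.03, 0.30)
    frames_total: int = 1500
    behavior_mean: float = 88.52
    behavior_sd: float = 8.23
    missing_behavior_fraction: float = 0.02
    planted_pairs: list[tuple[str, str, float]] = field(
        default_factory=lambda: list(DEFAULT_PLANTED_PAIRS))
    # unit fractions: (singleton, sibling pair, twin pair)
    family_fractions: tuple[float, float, float] = (0.80, 0.08, 0.12)
    family_weights: dict[str, float] = field(
        default_factory=lambda: {"single": 0.0, "sibling": 0.3, "twin": 0.5})
    master_seed: int = 0

    @property
    def n_networks(self) -> int:
        return len(self.network_sizes)

    def validate(self) -> None:
        if self.n_parcels <= 0 or self.n_participants <= 0 or self.n_sites <= 0:
            raise ValueError("n_parcels, n_participants, n_sites must be positive")
        if sum(self.network_sizes.values()) != self.n_parcels:
            raise ValueError(
                f"network sizes sum to {sum(self.network_sizes.values())}, "
                f"expected n_parcels={self.n_parcels}")
        if self.participant_sd < 0:
            raise ValueError("participant_sd must be non-negative")
        if abs(sum(self.family_fractions) - 1.0) > 1e-9:
            raise ValueError("family_fractions must sum to 1")
        if self.fd_sd <= 0 or self.fd_mean <= 0:
            raise ValueError("fd_mean and fd_sd must be positive")
        if self.frames_total <= 0:
            raise ValueError("frames_total must be positive")
        nets = set(self.network_sizes)
        for a, b, r in self.planted_pairs:
            if a not in nets or b not in nets:
                raise ValueError(f"planted pair ({a}, {b}) names an unknown network")
            if not -1 < r < 1:
                raise ValueError("planted effect sizes must be correlations in (-1,1)")

    def manufacturers(self) -> dict[int, str]:
        if self.manufacturer_of_site is not None:
            return dict(self.manufacturer_of_site)
        return _default_manufacturers(self.n_sites)


def _rng(master_seed: int, *key: int) -> np.random.Generator:
    """Named substream of the master seed."""
    return np.random.default_rng([int(master_seed)] + [int(k) for k in key])


_STREAM_GEOMETRY = 1
_STREAM_PARTICIPANTS = 2
_STREAM_DEVIATIONS = 3
_STREAM_BEHAVIOR = 4


# ---------------------------------------------------------------------------
# parcel geometry

def _make_parcels(config: SimConfig) -> pd.DataFrame:
    """Place parcels on two hemispheric spherical caps, networks spatially
    clustered and mirrored across the midline."""
    rng = _rng(config.master_seed, _STREAM_GEOMETRY)
    radius = 70.0
    rows = []
    pid = 0
    for net, size in config.network_sizes.items():
        # a seed direction on the left cap (x < 0)
        u = rng.normal(size=3)
        u[0] = -abs(u[0]) - 0.3
        u /= np.linalg.norm(u)
        n_left = (size + 1) // 2
        for k in range(size):
            hemi = "L" if k < n_left else "R"
            v = u + 0.45 * rng.normal(size=3)
            v[0] = -abs(v[0]) - 0.05  # stay on the left cap
            v = v / np.linalg.norm(v) * radius
            if hemi == "R":
                v = v.copy()
                v[0] = -v[0]
                # homotopic jitter so mirrored parcels are not exact images
                v += rng.normal(scale=2.0, size=3)
                v = v / np.linalg.norm(v) * radius
                v[0] = abs(v[0])
            rows.append((pid, hemi, v[0], v[1], v[2], net))
            pid += 1
    return pd.DataFrame(rows, columns=["parcel_id", "hemisphere", "x", "y", "z",
                                       "template_network"])


# ---------------------------------------------------------------------------
# template matrix

def _template_correlation(config: SimConfig, parcels: pd.DataFrame) -> np.ndarray:
    nets = list(config.network_sizes)
    labels = parcels["template_network"].to_numpy()
    within = config.within_block_mean
    if not isinstance(within, dict):
        within = {n: float(within) for n in nets}
    special = {frozenset(k): v for k, v in config.between_block_special.items()}
    p = config.n_parcels
    block = np.full((len(nets), len(nets)), float(config.between_block_mean))
    for i, a in enumerate(nets):
        block[i, i] = within[a]
        for j in range(i + 1, len(nets)):
            key = frozenset((a, nets[j]))
            if key in special:
                block[i, j] = block[j, i] = special[key]
    net_idx = {n: i for i, n in enumerate(nets)}
    lab_idx = np.array([net_idx[l] for l in labels])
    r = block[np.ix_(lab_idx, lab_idx)].copy()
    np.fill_diagonal(r, 1.0)
    return _psd_repair(r)


def _psd_repair(r: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues at 0, reconstruct, renormalize to unit
    diagonal.  The simplest repair preserving block structure."""
    w, v = np.linalg.eigh((r + r.T) / 2.0)
    if np.all(w <= 1e-12):
        raise ValueError("template matrix is not PSD-repairable (all eigenvalues clipped)")
    w = np.clip(w, 0.0, None)
    m = (v * w) @ v.T
    d = np.sqrt(np.diag(m))
    if np.any(d <= 0):
        raise ValueError("template matrix is not PSD-repairable (zero diagonal)")
    m = m / np.outer(d, d)
    np.fill_diagonal(m, 1.0)
    return m


# ---------------------------------------------------------------------------
# participants

def _truncnorm(rng, mean, sd, lo, hi, size):
    out = np.empty(size)
    n = 0
    while n < size:
        draw = rng.normal(mean, sd, size=size)
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(size - n, keep.size)
        out[n:n + take] = keep[:take]
        n += take
    return out


def _make_participants(config: SimConfig) -> pd.DataFrame:
    rng = _rng(config.master_seed, _STREAM_PARTICIPANTS)
    manu = config.manufacturers()
    n = config.n_participants

    # family units until the cohort is full
    rows = []
    fam_id = 0
    unit_kinds = ["single", "sibling", "twin"]
    probs = np.asarray(config.family_fractions, dtype=float)
    pid = 0
    while pid < n:
        kind = unit_kinds[rng.choice(3, p=probs)]
        size = 1 if kind == "single" else 2
        size = min(size, n - pid)
        if size == 1 and kind != "single":
            kind = "single"  # truncated tail unit
        site = int(rng.integers(config.n_sites))
        base_age = rng.normal(120.5, 7.5)
        for k in range(size):
            age = base_age if kind == "twin" else base_age + (0 if k == 0 else rng.normal(0, 14))
            rows.append({
                "participant_id": pid,
                "family_id": fam_id,
                "relationship": kind,
                "site": site,
                "manufacturer": manu[site],
                "sex": "F" if rng.random() < 0.5 else "M",
                "age_months": age,
            })
            pid += 1
        fam_id += 1
    df = pd.DataFrame(rows)

    # site-level attributes: coil fixed within site, altitude per site
    site_coil, site_alt = {}, {}
    site_rng = _rng(config.master_seed, _STREAM_PARTICIPANTS, 1)
    for s in range(config.n_sites):
        is_a = manu[s] == "A"
        site_coil[s] = 64 if (is_a and site_rng.random() < 0.3) else 32
        site_alt[s] = float(site_rng.uniform(50, 500))
    if config.n_sites >= 3:  # one genuinely high-altitude site
        site_alt[config.n_sites - 1] = 1900.0 + float(site_rng.uniform(0, 300))
    df["coil_channels"] = df["site"].map(site_coil)
    df["site_altitude"] = df["site"].map(site_alt)

    # motion summaries
    m = len(df)
    lo, hi = config.fd_range
    df["fd_mean"] = _truncnorm(rng, config.fd_mean, config.fd_sd, lo, hi, m)
    frac_low = np.clip(1.05 - 1.8 * df["fd_mean"].to_numpy()
                       + rng.normal(0, 0.08, size=m), 0.0, 1.0)
    df["n_low_motion_frames"] = np.round(frac_low * config.frames_total).astype(int)

    # matching covariates
    df["ethnicity"] = rng.choice(
        ["white", "black", "hispanic", "asian", "other"],
        p=[0.52, 0.15, 0.20, 0.06, 0.07], size=m)
    df["grade"] = rng.choice([3, 4, 5], p=[0.3, 0.5, 0.2], size=m)
    df["parental_education"] = rng.choice(
        ["<HS", "HS", "some_college", "bachelor", "postgrad"],
        p=[0.05, 0.12, 0.28, 0.30, 0.25], size=m)
    df["income"] = rng.choice(["<50k", "50-100k", ">100k"], p=[0.3, 0.3, 0.4], size=m)
    df["handedness"] = rng.choice(["R", "L"], p=[0.9, 0.1], size=m)
    df["anesthesia"] = rng.choice(["no", "yes"], p=[0.85, 0.15], size=m)
    return df


# ---------------------------------------------------------------------------
# cohort

def _pair_edge_mask(labels: np.ndarray, net_a: str, net_b: str,
                    iu: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    la, lb = labels[iu[0]], labels[iu[1]]
    return ((la == net_a) & (lb == net_b)) | ((la == net_b) & (lb == net_a))


def simulate_cohort(config: SimConfig):
    """Generate a full synthetic cohort.

    Returns
    -------
    parcels : DataFrame
        parcel_id, hemisphere, x, y, z, template_network.
    participants : DataFrame
        Demographics, acquisition factors, motion summaries, behavior.
    connectomes : (n_participants, P, P) ndarray
        One symmetric Fisher-z matrix per participant (zero diagonal).
    """
    config.validate()
    parcels = _make_parcels(config)
    participants = _make_participants(config)
    p = config.n_parcels
    n = len(participants)

    template_r = _template_correlation(config, parcels)
    off = ~np.eye(p, dtype=bool)
    template_z = np.zeros_like(template_r)
    template_z[off] = np.arctanh(np.clip(template_r[off], -0.999999, 0.999999))

    xyz = parcels[["x", "y", "z"]].to_numpy()
    dist = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=2)

    def _bias_param(par, m):
        return float(par[m]) if isinstance(par, dict) else float(par)

    manu = participants["manufacturer"].to_numpy()
    bias_by_manu = {}
    for m in sorted(set(manu)):
        if m == "A":
            continue
        a = _bias_param(config.manufacturer_bias_intercept, m)
        b = _bias_param(config.manufacturer_bias_slope, m)
        bm = a + b * dist
        np.fill_diagonal(bm, 0.0)
        bias_by_manu[m] = bm

    iu = np.triu_indices(p, k=1)
    fam_ids = participants["family_id"].to_numpy()
    rel = participants["relationship"].to_numpy()
    weights = config.family_weights

    # network-pair block index per edge (for the shared latent factors)
    labels_arr = parcels["template_network"].to_numpy()
    nets_sorted = sorted(config.network_sizes)
    net_pos = {nm: k for k, nm in enumerate(nets_sorted)}
    li, lj = labels_arr[iu[0]], labels_arr[iu[1]]
    a = np.minimum([net_pos[x] for x in li], [net_pos[x] for x in lj])
    b = np.maximum([net_pos[x] for x in li], [net_pos[x] for x in lj])
    block_of_edge = (a * len(nets_sorted) + b).astype(int)
    _, block_of_edge = np.unique(block_of_edge, return_inverse=True)
    n_blocks = int(block_of_edge.max()) + 1
    rho = float(config.edge_block_rho)
    if not 0 <= rho < 1:
        raise ValueError("edge_block_rho must lie in [0, 1)")

    def _structured_deviation(rng_local):
        # unit-variance per edge: sqrt(rho) * block factor + sqrt(1-rho) * iid
        u = rng_local.normal(0.0, 1.0, size=n_blocks)
        eps = rng_local.normal(0.0, 1.0, size=iu[0].shape[0])
        return np.sqrt(rho) * u[block_of_edge] + np.sqrt(1.0 - rho) * eps

    # shared family deviation per family unit (substream keyed on family id)
    shared = {}
    connectomes = np.empty((n, p, p))
    for i in range(n):
        rng_i = _rng(config.master_seed, _STREAM_DEVIATIONS, i)
        scale = config.manufacturer_noise_scale.get(manu[i], 1.0) if manu[i] != "A" else 1.0
        sd = config.participant_sd * scale
        w = float(weights.get(rel[i], 0.0))
        own = _structured_deviation(rng_i)
        if w > 0:
            fid = fam_ids[i]
            if fid not in shared:
                fam_rng = _rng(config.master_seed, _STREAM_DEVIATIONS, 10_000_000 + int(fid))
                shared[fid] = _structured_deviation(fam_rng)
            dev = (w * shared[fid] + np.sqrt(1.0 - w * w) * own) * sd
        else:
            dev = own * sd
        z = template_z.copy()
        z[iu] += dev
        if manu[i] in bias_by_manu:
            z[iu] += bias_by_manu[manu[i]][iu]
        zl = z.T.copy()
        z[np.tril_indices(p, k=-1)] = zl[np.tril_indices(p, k=-1)]
        np.fill_diagonal(z, 0.0)
        connectomes[i] = z

    # behavior: planted network-pair effects + calibrated noise
    rng_b = _rng(config.master_seed, _STREAM_BEHAVIOR)
    labels = parcels["template_network"].to_numpy()
    edges = connectomes[:, iu[0], iu[1]]
    total_r2 = 0.0
    signal = np.zeros(n)
    for net_a, net_b, r_eff in config.planted_pairs:
        mask = _pair_edge_mask(labels, net_a, net_b, iu)
        if not mask.any():
            raise ValueError(f"planted pair ({net_a}, {net_b}) has no edges")
        x = edges[:, mask].mean(axis=1)
        xs = x.std()
        x_std = (x - x.mean()) / (xs if xs > 0 else 1.0)
        signal += r_eff * x_std
        total_r2 += r_eff * r_eff
    if total_r2 >= 1.0:
        raise ValueError("planted effect sizes imply more than 100% of behavior variance")
    behavior = (config.behavior_mean
                + config.behavior_sd * signal
                + config.behavior_sd * np.sqrt(1.0 - total_r2) * rng_b.normal(size=n))
    if config.missing_behavior_fraction > 0:
        n_miss = int(round(config.missing_behavior_fraction * n))
        if n_miss:
            miss = rng_b.choice(n, size=n_miss, replace=False)
            behavior[miss] = np.nan
    participants = participants.copy()
    participants["behavior"] = behavior
    return parcels, participants, connectomes


# ---------------------------------------------------------------------------
# timeseries

def simulate_timeseries(connectome, n_frames: int, seed: int) -> np.ndarray:
    """Draw multivariate-normal frames whose population correlation matches
    the participant's (inverse-Fisher) correlation matrix."""
    if n_frames < 2:
        raise ValueError("n_frames must be at least 2 (correlation undefined for 1 frame)")
    z = connectome.values if isinstance(connectome, Connectome) else np.asarray(connectome, float)
    r = np.tanh(z)
    np.fill_diagonal(r, 1.0)
    w, v = np.linalg.eigh((r + r.T) / 2.0)
    if w[0] < -1e-8:
        raise ValueError(
            f"correlation matrix is not positive semi-definite "
            f"(smallest eigenvalue {w[0]:.3e})")
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n_frames, r.shape[0])) @ factor.T


# ---------------------------------------------------------------------------
# motion bookkeeping

def flag_frames(fd_series, threshold: float = 0.20) -> np.ndarray:
    """Flag motion-contaminated frames: FD strictly above threshold (mm)."""
    fd = np.asarray(fd_series, dtype=float)
    if fd.size and np.any(fd < 0):
        raise ValueError("framewise displacement must be non-negative")
    return fd > threshold


def motion_inclusion(table: pd.DataFrame, fd_max: float = 0.20,
                     min_frames: int = 600) -> pd.DataFrame:
    """Retain participants with mean FD strictly below ``fd_max`` and at
    least ``min_frames`` low-motion frames."""
    for col in ("fd_mean", "n_low_motion_frames"):
        if col not in table.columns:
            raise ValueError(f"participant table is missing '{col}'")
        bad = table.index[table[col].isna()]
        if len(bad):
            ids = table.loc[bad, "participant_id"].tolist() if "participant_id" in table else list(bad)
            raise ValueError(f"missing {col} for participants {ids}")
    fd_ok = table["fd_mean"] < fd_max
    frames_ok = table["n_low_motion_frames"] >= min_frames
    logger.info("motion inclusion: %d removed for fd_mean >= %.2f, %d for frames < %d, %d retained",
                int((~fd_ok).sum()), fd_max, int((fd_ok & ~frames_ok).sum()),
                min_frames, int((fd_ok & frames_ok).sum()))
    return table[fd_ok & frames_ok].copy()


def frames_duration_minutes(n_frames: int, tr_ms: float = 800.0) -> float:
    """Scan time in minutes for a frame count at a given TR (ms)."""
    return n_frames * tr_ms / 1000.0 / 60.0


# ---------------------------------------------------------------------------
# writers

def write_cohort(out_dir: str, parcels: pd.DataFrame, participants: pd.DataFrame,
                 connectomes: np.ndarray, config: SimConfig) -> None:
    """Write parcels.tsv, participants.tsv, per-participant connectome TSVs
    and a manifest.json recording the configuration and seed."""
    os.makedirs(out_dir, exist_ok=True)
    parcels.to_csv(os.path.join(out_dir, "parcels.tsv"), sep="\t", index=False,
                   float_format="%.6f")
    participants.to_csv(os.path.join(out_dir, "participants.tsv"), sep="\t",
                        index=False, float_format="%.6f")
    for i in range(connectomes.shape[0]):
        np.savetxt(os.path.join(out_dir, f"sub-{i:04d}_connectome.tsv"),
                   connectomes[i], fmt="%.6f", delimiter="\t")
    manifest = {
        "master_seed": config.master_seed,
        "n_parcels": config.n_parcels,
        "n_participants": config.n_participants,
        "n_sites": config.n_sites,
        "participant_sd": config.participant_sd,
        "fd_mean": config.fd_mean,
        "fd_sd": config.fd_sd,
        "behavior_mean": config.behavior_mean,
        "behavior_sd": config.behavior_sd,
        "planted_pairs": [list(p) for p in config.planted_pairs],
        "family_fractions": list(config.family_fractions),
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
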