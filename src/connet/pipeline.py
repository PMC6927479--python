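"""End-to-end orchestration: filter, split, per-arm analyses, cross-arm
reproducibility, and a machine-readable report.

Every stage is deterministic given the configuration and seeds; the report
embeds the configuration verbatim so any number it contains can be
recomputed from the inputs alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import batch, enrichment, networks, similarity, split as split_mod, variability
from .core import Connectome, group_average, matrix_similarity, stack_edges
from .simulate import motion_inclusion

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "report", "write_report"]

DEFAULT_MATCH_VARS = ["site", "age_months", "sex", "ethnicity", "grade",
                      "parental_education", "handedness", "income", "anesthesia"]


@dataclass
class PipelineConfig:
    fd_max: float = 0.20
    min_frames: int = 600
    densities: tuple = tuple(np.geomspace(0.001, 0.05, 10).tolist())
    exclusion_mm: float = 30.0
    min_community_size: int | None = None
    alpha: float = 0.05
    anova_alpha: float = 0.001
    n_perm: int = 10000
    pa_iterations: int = 5000
    seed: int = 0
    match_vars: tuple = tuple(DEFAULT_MATCH_VARS)
    collapse_manufacturers: tuple | None = None

    def validate(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.anova_alpha < 1:
            raise ValueError("alpha thresholds must lie in (0,1)")
        if self.fd_max <= 0 or self.min_frames < 0:
            raise ValueError("motion thresholds out of domain")
        if self.n_perm < 100 or self.pa_iterations < 100:
            raise ValueError("n_perm and pa_iterations must be >= 100")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _arm_analyses(connectomes: np.ndarray, table: pd.DataFrame,
                  parcels: pd.DataFrame, config: PipelineConfig,
                  arm_seed: int) -> dict:
    out: dict = {}
    out["group_average"] = group_average(connectomes)

    net_cfg = networks.NetworkConfig(
        densities=config.densities, exclusion_mm=config.exclusion_mm,
        min_community_size=config.min_community_size,
        infomap_seed=arm_seed)
    out["networks"] = networks.detect_networks(out["group_average"], parcels, net_cfg)

    manu = table["manufacturer"].to_numpy()
    s = similarity.similarity_matrix(connectomes)
    out["mean_similarity_z"] = similarity.mean_similarity(s)
    out["shared_variance_frac"] = float(np.tanh(out["mean_similarity_z"]) )
    contrasts = {}
    for a, b in [("A", "B"), ("A", "C"), ("B", "C")]:
        if (manu == a).sum() >= 2 and (manu == b).sum() >= 2:
            contrasts[f"{a}_vs_{b}"] = similarity.group_similarity_contrast(
                s, manu, a, b, n_perm=min(config.n_perm, 1000), seed=arm_seed)
    out["similarity_contrasts"] = contrasts

    out["anova"] = batch.edgewise_anova(connectomes, manu, alpha=config.anova_alpha)
    collapse = config.collapse_manufacturers or ("B", "C")
    out["manufacturer_pairs"] = batch.pairwise_manufacturer_contrasts(
        connectomes, manu, parcels, fd=table["fd_mean"].to_numpy())
    manu_collapsed = np.where(np.isin(manu, list(collapse)), "/".join(collapse), manu)
    if len(np.unique(manu_collapsed)) == 2:
        r_pb = batch.edgewise_point_biserial(connectomes, manu_collapsed)
        out["distance_dependence"] = batch.distance_dependence(r_pb, parcels)

    out["variability"] = variability.edgewise_sd(connectomes)
    pca = variability.connectome_pca(connectomes)
    edges = stack_edges(connectomes)
    pca.retained_k = variability.parallel_analysis(
        edges, n_iter=config.pa_iterations, seed=arm_seed)
    out["pca"] = pca

    behavior = table["behavior"].to_numpy()
    glm = enrichment.edgewise_behavior_glm(
        connectomes, behavior, manufacturer=manu, sex=table["sex"].to_numpy())
    out["glm"] = glm
    out["enrichment"] = enrichment.enrichment_table(
        connectomes, behavior, parcels["template_network"].to_numpy(),
        n_perm=config.n_perm, alpha=config.alpha, seed=arm_seed)
    return out


def run_pipeline(parcels: pd.DataFrame, participants: pd.DataFrame,
                 connectomes: np.ndarray, config: PipelineConfig | None = None) -> dict:
    """Filter -> split -> per-arm analyses -> cross-arm reproducibility."""
    config = config or PipelineConfig()
    config.validate()

    kept = motion_inclusion(participants, fd_max=config.fd_max,
                            min_frames=config.min_frames)
    logger.info("motion filter: %d of %d participants retained",
                len(kept), len(participants))
    idx = kept.index.to_numpy()
    connectomes = connectomes[idx]
    kept = kept.reset_index(drop=True)

    sp = split_mod.matched_split(kept, list(config.match_vars), seed=config.seed)
    arm = sp.assignment.to_numpy()
    bundle: dict = {"config": config, "split": sp,
                    "n_input": len(participants), "n_retained": len(kept)}
    for arm_name, arm_seed in ((split_mod.DISCOVERY, config.seed * 2 + 1),
                               (split_mod.REPLICATION, config.seed * 2 + 2)):
        members = np.flatnonzero(arm == arm_name)
        logger.info("running %s arm (n=%d)", arm_name, members.size)
        bundle[arm_name] = _arm_analyses(
            connectomes[members], kept.iloc[members].reset_index(drop=True),
            parcels, config, arm_seed)
        bundle[arm_name]["n"] = int(members.size)

    d, r = bundle[split_mod.DISCOVERY], bundle[split_mod.REPLICATION]
    bundle["cross_arm"] = {
        "group_matrix_r": matrix_similarity(d["group_average"], r["group_average"]),
        "network_nmi": networks.nmi(d["networks"]["consensus"],
                                    r["networks"]["consensus"]),
        "split_half_reliability_t": enrichment.split_half_reliability(
            d["glm"]["t"], r["glm"]["t"]),
    }
    return bundle


def report(bundle: dict) -> dict:
    """Headline statistics of a pipeline bundle as one JSON-able dict."""
    config: PipelineConfig = bundle["config"]
    out = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_input": bundle.get("n_input"),
        "n_retained": bundle.get("n_retained"),
        "cross_arm": {k: float(v) for k, v in bundle.get("cross_arm", {}).items()},
        "arms": {},
    }
    for arm_name in (split_mod.DISCOVERY, split_mod.REPLICATION):
        arm = bundle.get(arm_name)
        if arm is None:
            logger.warning("missing stage output for arm %s", arm_name)
            out["arms"][arm_name] = None
            continue
        contrasts = {k: {"delta_z": c.delta, "cohens_d": c.cohens_d, "perm_p": c.perm_p}
                     for k, c in arm["similarity_contrasts"].items()}
        pairs = arm["manufacturer_pairs"]
        enr = arm["enrichment"]
        out["arms"][arm_name] = {
            "n": arm["n"],
            "mean_similarity_z": float(arm["mean_similarity_z"]),
            "shared_variance_frac": float(arm["shared_variance_frac"]),
            "similarity_contrasts": contrasts,
            "anova_frac_significant": float(arm["anova"].frac_significant),
            "distance_r": (float(arm["distance_dependence"]["distance_r"])
                           if "distance_dependence" in arm else None),
            "manufacturer_pair_distance_r": {
                f"{row.level_a}_vs_{row.level_b}": float(row.distance_r)
                for row in pairs.itertuples()},
            "mean_edge_sd": float(np.mean(
                arm["variability"].edge_sd[np.triu_indices_from(
                    arm["variability"].edge_sd, k=1)])),
            "pca_retained_k": int(arm["pca"].retained_k),
            "pca_explained_top10": [float(x) for x in arm["pca"].explained_frac[:10]],
            "n_significant_pairs": int(enr["significant"].sum()),
            "enrichment": enr.drop(columns=["significant"]).to_dict("records"),
            "percent_differing_from_template": float(
                arm["networks"]["percent_differing"]),
        }
    return out


def write_report(bundle: dict, out_dir: str) -> str:
    """Write the JSON report and headline TSVs into ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    rep = report(bundle)
    path = os.path.join(out_dir, "report.json")
    with open(path, "w") as fh:
        json.dump(rep, fh, indent=2, default=_json_default)
    bundle["split"].assignment.to_frame().to_csv(
        os.path.join(out_dir, "split.tsv"), sep="\t")
    for arm_name in (split_mod.DISCOVERY, split_mod.REPLICATION):
        arm = bundle.get(arm_name)
        if arm is None:
            continue
        arm["enrichment"].to_csv(
            os.path.join(out_dir, f"enrichment_{arm_name}.tsv"),
            sep="\t", index=False, float_format="%.6f")
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
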