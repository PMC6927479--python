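"""Community detection on group-average connectomes via the map equation.

The pipeline mirrors the standard resting-state network-detection recipe:
short-range within-hemisphere edges are zeroed (Euclidean stand-in for the
geodesic exclusion), the matrix is thresholded at a range of edge densities,
each thresholded graph is partitioned by minimizing the two-level map
equation (an Infomap-style greedy optimizer with node moves, module
aggregation and seeded restarts), small communities are marked unassigned,
communities are named by best Dice overlap with a template, a consensus is
taken across densities, and reproducibility is quantified with normalized
mutual information.

The map-equation codelength for a partition M of an undirected weighted
graph with node visit rates p_a (strength over total strength) and module
exit rates q_m (boundary weight over total strength) is

    L(M) = plogp(q) - 2*sum_m plogp(q_m) - sum_a plogp(p_a)
           + sum_m plogp(q_m + sum_{a in m} p_a),        plogp(x) = x log2 x

which reduces to the entropy of the visit rates when all nodes share one
module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import normalized_mutual_info_score

__all__ = [
    "UNASSIGNED",
    "NetworkConfig",
    "Graph",
    "exclusion_mask",
    "threshold_by_density",
    "map_equation",
    "infomap_partition",
    "size_filter",
    "match_to_template",
    "multi_density_consensus",
    "nmi",
    "detect_networks",
]

UNASSIGNED = -1

VERTEX_SCALE_MIN_SIZE = 400   # "400 or fewer" at full cortical vertex scale
VERTEX_COUNT = 59412


def default_min_community_size(n_parcels: int) -> int:
    """Scale the vertex-level 400-node filter to parcel-scale inputs."""
    return max(2, round(VERTEX_SCALE_MIN_SIZE * n_parcels / VERTEX_COUNT))


@dataclass
class NetworkConfig:
    densities: tuple = tuple(np.geomspace(0.001, 0.05, 10).tolist())
    exclusion_mm: float = 30.0
    min_community_size: int | None = None   # None -> scaled default
    infomap_seed: int = 0
    n_outer_loops: int = 10

    def validate(self) -> None:
        d = np.asarray(self.densities, dtype=float)
        if np.any(d <= 0) or np.any(d > 1):
            raise ValueError("densities must lie in (0, 1]")
        if np.any(np.diff(d) < 0):
            raise ValueError("densities must be sorted ascending")
        if self.exclusion_mm < 0:
            raise ValueError("exclusion_mm must be non-negative")


# ---------------------------------------------------------------------------
# graph container

class Graph:
    """Undirected weighted graph on nodes 0..n-1 with optional self-loops."""

    def __init__(self, n_nodes: int, edges):
        self.n_nodes = int(n_nodes)
        self.neighbors: list[list[tuple[int, float]]] = [[] for _ in range(n_nodes)]
        self.self_weight = np.zeros(n_nodes)
        self.strength = np.zeros(n_nodes)
        self.n_edges = 0
        for i, j, w in edges:
            i, j, w = int(i), int(j), float(w)
            if i == j:
                self.self_weight[i] += w
                self.strength[i] += 2 * w
            else:
                self.neighbors[i].append((j, w))
                self.neighbors[j].append((i, w))
                self.strength[i] += w
                self.strength[j] += w
                self.n_edges += 1
        self.total_strength = float(self.strength.sum())

    def components(self) -> list[np.ndarray]:
        seen = np.zeros(self.n_nodes, dtype=bool)
        comps = []
        for start in range(self.n_nodes):
            if seen[start]:
                continue
            stack, comp = [start], []
            seen[start] = True
            while stack:
                v = stack.pop()
                comp.append(v)
                for u, _ in self.neighbors[v]:
                    if not seen[u]:
                        seen[u] = True
                        stack.append(u)
            comps.append(np.array(sorted(comp)))
        return comps

    def subgraph(self, nodes: np.ndarray) -> tuple["Graph", np.ndarray]:
        index = {int(v): k for k, v in enumerate(nodes)}
        edges = []
        for v in nodes:
            iv = index[int(v)]
            if self.self_weight[v]:
                edges.append((iv, iv, self.self_weight[v]))
            for u, w in self.neighbors[v]:
                if u in index and u > v:
                    edges.append((iv, index[u], w))
        return Graph(len(nodes), edges), nodes


# ---------------------------------------------------------------------------
# masking and thresholding

def exclusion_mask(parcels: pd.DataFrame, exclusion_mm: float) -> np.ndarray:
    """Boolean P x P mask, True where the edge is zeroed: same-hemisphere
    pairs strictly closer than ``exclusion_mm``.  Cross-hemisphere edges are
    never masked (no smoothing crosses the midline)."""
    xyz = parcels[["x", "y", "z"]].to_numpy(dtype=float)
    hemi = parcels["hemisphere"].to_numpy()
    dist = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=2)
    same_hemi = hemi[:, None] == hemi[None, :]
    mask = same_hemi & (dist < exclusion_mm)
    np.fill_diagonal(mask, True)
    return mask


def threshold_by_density(matrix: np.ndarray, density: float,
                         mask: np.ndarray | None = None) -> Graph:
    """Keep the top ``round(density * n_unmasked_edges)`` edges by value.

    Ties at the cutoff are broken deterministically: larger value first,
    then lower (i, j) index.
    """
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    m = np.asarray(matrix, dtype=float)
    p = m.shape[0]
    iu = np.triu_indices(p, k=1)
    values = m[iu]
    if mask is not None:
        keep = ~mask[iu]
    else:
        keep = np.ones(values.shape[0], dtype=bool)
    idx = np.flatnonzero(keep)
    n_keep = int(round(density * idx.size))
    if n_keep < 1:
        raise ValueError(f"density {density} keeps no edges "
                         f"({idx.size} unmasked edges available)")
    vals = values[idx]
    order = np.lexsort((iu[1][idx], iu[0][idx], -vals))
    chosen = idx[order[:n_keep]]
    edges = [(int(iu[0][e]), int(iu[1][e]), float(values[e])) for e in chosen]
    return Graph(p, edges)


# ---------------------------------------------------------------------------
# map equation

def _plogp(x: float) -> float:
    return x * np.log2(x) if x > 0 else 0.0


def _codelength_terms(graph: Graph, modules: np.ndarray):
    s = graph.total_strength
    if s <= 0:
        raise ValueError("graph has no edge weight")
    p_node = graph.strength / s
    uniq = np.unique(modules)
    p_mod = np.zeros(uniq.size)
    cut = np.zeros(uniq.size)
    pos = {int(m): k for k, m in enumerate(uniq)}
    for v in range(graph.n_nodes):
        k = pos[int(modules[v])]
        p_mod[k] += p_node[v]
        for u, w in graph.neighbors[v]:
            if modules[u] != modules[v]:
                cut[k] += w / s
    return p_node, p_mod, cut


def map_equation(graph: Graph, modules) -> float:
    """Two-level map-equation codelength (bits) of a partition.

    Raises on disconnected graphs: visit rates of an undirected random walk
    are only defined per connected component, so process components
    independently instead.
    """
    modules = np.asarray(modules)
    if modules.shape[0] != graph.n_nodes:
        raise ValueError("partition must cover every node")
    if len(graph.components()) > 1:
        raise ValueError("graph is disconnected; evaluate the map equation "
                         "per connected component")
    p_node, p_mod, cut = _codelength_terms(graph, modules)
    q = float(cut.sum())
    node_term = sum(_plogp(x) for x in p_node)
    mod_term = sum(-2 * _plogp(qm) + _plogp(qm + pm) for qm, pm in zip(cut, p_mod))
    return _plogp(q) + mod_term - node_term


# ---------------------------------------------------------------------------
# greedy optimizer

def _optimize_component(graph: Graph, rng: np.random.Generator,
                        n_outer_loops: int) -> tuple[np.ndarray, float]:
    """Seeded greedy minimization of the map equation on a connected graph:
    repeated local node moves, module aggregation, and restarts; the
    one-module partition is always considered as a candidate."""
    n = graph.n_nodes
    single = np.zeros(n, dtype=int)
    best_modules = single
    best_l = map_equation(graph, single)
    for _ in range(max(1, n_outer_loops)):
        modules = _two_level_search(graph, rng)
        l = map_equation(graph, modules)
        if l < best_l - 1e-12:
            best_l, best_modules = l, modules
    return _compact_labels(best_modules), best_l


def _two_level_search(graph: Graph, rng: np.random.Generator) -> np.ndarray:
    modules = _local_moves(graph, np.arange(graph.n_nodes), rng)
    # aggregate and re-optimize until the module structure stops changing
    while True:
        modules = _compact_labels(modules)
        n_mod = modules.max() + 1
        if n_mod == graph.n_nodes or n_mod == 1:
            break
        agg = _aggregate(graph, modules, n_mod)
        super_modules = _local_moves(agg, np.arange(n_mod), rng)
        if np.unique(super_modules).size == n_mod:
            break
        modules = super_modules[modules]
    return modules


def _aggregate(graph: Graph, modules: np.ndarray, n_mod: int) -> Graph:
    acc: dict[tuple[int, int], float] = {}
    for v in range(graph.n_nodes):
        mv = int(modules[v])
        if graph.self_weight[v]:
            acc[(mv, mv)] = acc.get((mv, mv), 0.0) + graph.self_weight[v]
        for u, w in graph.neighbors[v]:
            if u > v:
                a, b = sorted((mv, int(modules[u])))
                acc[(a, b)] = acc.get((a, b), 0.0) + w
    return Graph(n_mod, [(i, j, w) for (i, j), w in acc.items()])


def _local_moves(graph: Graph, init: np.ndarray, rng: np.random.Generator,
                 max_passes: int = 50) -> np.ndarray:
    """Greedy node-move passes; accepts only strict codelength decreases."""
    s = graph.total_strength
    modules = init.copy()
    p_node = graph.strength / s
    ext = (graph.strength - 2 * graph.self_weight) / s   # non-self weight
    n_mod = modules.max() + 1
    p_mod = np.zeros(n_mod)
    cut = np.zeros(n_mod)
    for v in range(graph.n_nodes):
        p_mod[modules[v]] += p_node[v]
    for v in range(graph.n_nodes):
        for u, w in graph.neighbors[v]:
            if modules[u] != modules[v]:
                cut[modules[v]] += w / s
    q = float(cut.sum())

    def mod_term(qm, pm):
        return -2 * _plogp(qm) + _plogp(qm + pm)

    for _ in range(max_passes):
        improved = False
        for v in rng.permutation(graph.n_nodes):
            mv = int(modules[v])
            # weight from v to each neighboring module
            w_to: dict[int, float] = {}
            for u, w in graph.neighbors[v]:
                mu = int(modules[u])
                w_to[mu] = w_to.get(mu, 0.0) + w / s
            w_own = w_to.get(mv, 0.0)
            cut_a_new = cut[mv] - (ext[v] - w_own) + w_own
            pa_new = p_mod[mv] - p_node[v]
            base_old = mod_term(cut[mv], p_mod[mv])
            best_gain, best_target = -1e-12, None
            for mb, w_b in w_to.items():
                if mb == mv:
                    continue
                cut_b_new = cut[mb] + (ext[v] - w_b) - w_b
                q_new = q - cut[mv] - cut[mb] + cut_a_new + cut_b_new
                delta = (_plogp(q_new) - _plogp(q)
                         + mod_term(cut_a_new, pa_new) - base_old
                         + mod_term(cut_b_new, p_mod[mb] + p_node[v])
                         - mod_term(cut[mb], p_mod[mb]))
                if delta < best_gain:
                    best_gain, best_target = delta, mb
            if best_target is not None:
                mb = best_target
                w_b = w_to[mb]
                q = q - cut[mv] - cut[mb] + cut_a_new + (cut[mb] + ext[v] - 2 * w_b)
                cut[mb] += ext[v] - 2 * w_b
                cut[mv] = cut_a_new
                p_mod[mv] = pa_new
                p_mod[mb] += p_node[v]
                modules[v] = mb
                improved = True
        if not improved:
            break
    return modules


def _compact_labels(modules: np.ndarray) -> np.ndarray:
    uniq, inv = np.unique(modules, return_inverse=True)
    return inv.astype(int)


def infomap_partition(graph: Graph, seed: int = 0, n_outer_loops: int = 10) -> np.ndarray:
    """Partition a graph by greedy map-equation minimization.

    Disconnected components are processed independently and receive
    disjoint community ids.
    """
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    rng = np.random.default_rng(seed)
    modules = np.full(graph.n_nodes, UNASSIGNED, dtype=int)
    offset = 0
    for comp in graph.components():
        if comp.size == 1:
            modules[comp[0]] = offset
            offset += 1
            continue
        sub, nodes = graph.subgraph(comp)
        sub_modules, _ = _optimize_component(sub, rng, n_outer_loops)
        modules[nodes] = sub_modules + offset
        offset += sub_modules.max() + 1
    return modules


# ---------------------------------------------------------------------------
# post-processing

def size_filter(partition, min_community_size: int):
    """Mark communities with ``min_community_size`` or fewer nodes as
    unassigned (the size rule is inclusive)."""
    part = np.asarray(partition).copy()
    assigned = part != UNASSIGNED
    out = part.copy()
    for c in np.unique(part[assigned]):
        members = part == c
        if members.sum() <= min_community_size:
            out[members] = UNASSIGNED
    if not np.any(out != UNASSIGNED):
        warnings.warn("size filter removed every community; partition is all-unassigned")
    return out


def match_to_template(partition, template_labels, parcels: pd.DataFrame | None = None,
                      border_mm: float | None = None):
    """Assign each detected community the template network label with the
    best Dice overlap (largest overlap assigned first; a template label may
    serve several communities).

    Returns the relabeled partition (template labels; unassigned nodes keep
    ``UNASSIGNED``) and the fraction of assigned nodes whose label differs
    from the template.  With ``border_mm`` and parcel geometry, nodes within
    that distance of a template label change are excluded from the percent
    before it is recomputed.
    """
    part = np.asarray(partition)
    template = np.asarray(template_labels)
    if part.shape != template.shape:
        raise ValueError("partition and template cover different node sets")
    communities = [c for c in np.unique(part) if c != UNASSIGNED]
    t_labels = np.unique(template)
    pairs = []
    for c in communities:
        cm = part == c
        for t in t_labels:
            tm = template == t
            inter = int(np.sum(cm & tm))
            dice = 2 * inter / (cm.sum() + tm.sum())
            pairs.append((dice, inter, c, t))
    pairs.sort(key=lambda x: (-x[0], -x[1], str(x[3])))
    label_of: dict = {}
    for dice, inter, c, t in pairs:
        if c not in label_of and inter > 0:
            label_of[c] = t
    relabeled = np.array([label_of.get(c, UNASSIGNED) if c != UNASSIGNED else UNASSIGNED
                          for c in part], dtype=object)
    assigned = np.array([x != UNASSIGNED for x in relabeled])
    differ = assigned & (relabeled != template)
    percent = float(differ.sum() / assigned.sum()) if assigned.any() else 0.0
    result = {"labels": relabeled, "percent_differing": percent}
    if border_mm is not None and parcels is not None:
        xyz = parcels[["x", "y", "z"]].to_numpy(dtype=float)
        dist = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=2)
        near = (dist > 0) & (dist <= border_mm)
        border = np.array([np.any(template[near[v]] != template[v])
                           for v in range(len(template))])
        keep = assigned & ~border
        result["percent_differing_no_border"] = (
            float((differ & ~border).sum() / keep.sum()) if keep.any() else 0.0)
    return result


def multi_density_consensus(labels_by_density: dict[float, np.ndarray]) -> np.ndarray:
    """Modal template label per node across densities.

    Ties resolve toward the highest density; nodes unassigned at a majority
    of densities stay unassigned.
    """
    if not labels_by_density:
        raise ValueError("need at least one partition")
    densities = sorted(labels_by_density)
    stacked = [np.asarray(labels_by_density[d], dtype=object) for d in densities]
    n = stacked[0].shape[0]
    out = np.empty(n, dtype=object)
    n_dens = len(densities)
    for v in range(n):
        votes = [lab[v] for lab in stacked]
        unassigned = sum(1 for x in votes if x == UNASSIGNED)
        if unassigned * 2 > n_dens:
            out[v] = UNASSIGNED
            continue
        counts: dict = {}
        for k, x in enumerate(votes):
            if x == UNASSIGNED:
                continue
            cnt, last = counts.get(x, (0, -1))
            counts[x] = (cnt + 1, k)   # k tracks highest density voting for x
        if not counts:
            out[v] = UNASSIGNED
            continue
        out[v] = max(counts.items(), key=lambda kv: (kv[1][0], kv[1][1]))[0]
    return out


def nmi(p1, p2) -> float:
    """Normalized mutual information I(p1;p2) / mean(H(p1), H(p2)).

    Nodes unassigned in either partition are excluded pairwise.  When both
    partitions have a single community the value is 1 if they are identical
    (which, over the same nodes, they always are) — the 0/0 convention.
    """
    a = np.asarray(p1, dtype=object)
    b = np.asarray(p2, dtype=object)
    if a.shape != b.shape:
        raise ValueError("partitions cover different node sets")
    keep = np.array([(x != UNASSIGNED) and (y != UNASSIGNED) for x, y in zip(a, b)])
    if not keep.any():
        raise ValueError("no nodes assigned in both partitions")
    la = pd.factorize(a[keep])[0]
    lb = pd.factorize(b[keep])[0]
    return float(normalized_mutual_info_score(la, lb, average_method="arithmetic"))


# ---------------------------------------------------------------------------
# full detection pipeline

def detect_networks(group_connectome, parcels: pd.DataFrame,
                    config: NetworkConfig | None = None) -> dict:
    """Mask, threshold at each density, partition, size-filter, match to the
    template labels, and form the cross-density consensus."""
    config = config or NetworkConfig()
    config.validate()
    from .core import Connectome
    m = group_connectome.values if isinstance(group_connectome, Connectome) \
        else np.asarray(group_connectome, dtype=float)
    p = m.shape[0]
    min_size = (config.min_community_size if config.min_community_size is not None
                else default_min_community_size(p))
    mask = exclusion_mask(parcels, config.exclusion_mm)
    template = parcels["template_network"].to_numpy()
    by_density: dict[float, np.ndarray] = {}
    raw_partitions: dict[float, np.ndarray] = {}
    for density in config.densities:
        graph = threshold_by_density(m, float(density), mask)
        part = infomap_partition(graph, seed=config.infomap_seed,
                                 n_outer_loops=config.n_outer_loops)
        part = size_filter(part, min_size)
        matched = match_to_template(part, template)
        raw_partitions[float(density)] = part
        by_density[float(density)] = matched["labels"]
    consensus = multi_density_consensus(by_density)
    assigned = np.array([x != UNASSIGNED for x in consensus])
    percent = (float(np.sum(assigned & (consensus != template)) / assigned.sum())
               if assigned.any() else 0.0)
    return {"consensus": consensus, "by_density": by_density,
            "raw_partitions": raw_partitions, "min_community_size": min_size,
            "percent_differing": percent}
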