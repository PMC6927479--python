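import numpy as np
import pandas as pd
import pytest

from connet import networks
from connet.networks import (Graph, UNASSIGNED, exclusion_mask, infomap_partition,
                             map_equation, match_to_template, multi_density_consensus,
                             nmi, size_filter, threshold_by_density)


def _parcels(coords, hemis, labels=None):
    coords = np.asarray(coords, float)
    return pd.DataFrame({
        "parcel_id": range(len(coords)), "hemisphere": hemis,
        "x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2],
        "template_network": labels if labels is not None else ["n"] * len(coords)})


def _clique_pair_graph():
    edges = ([(i, j, 1.0) for i in range(4) for j in range(i + 1, 4)]
             + [(i, j, 1.0) for i in range(4, 8) for j in range(i + 1, 8)]
             + [(3, 4, 1.0)])
    return Graph(8, edges)


class TestExclusionMask:
    def test_zero_radius_masks_nothing(self):
        p = _parcels([[0, 0, 0], [1, 0, 0]], ["L", "L"])
        mask = exclusion_mask(p, 0.0)
        assert not mask[0, 1]

    def test_boundary_is_strict(self):
        p = _parcels([[0, 0, 0], [29.9, 0, 0], [30.0, 0, 0]], ["L", "L", "L"])
        mask = exclusion_mask(p, 30.0)
        assert mask[0, 1] and not mask[0, 2]

    def test_cross_hemisphere_never_masked(self):
        p = _parcels([[-5, 0, 0], [5, 0, 0]], ["L", "R"])
        mask = exclusion_mask(p, 30.0)
        assert not mask[0, 1]


class TestThresholdByDensity:
    def test_full_density_keeps_everything(self, rng):
        m = rng.normal(size=(10, 10))
        m = (m + m.T) / 2
        g = threshold_by_density(m, 1.0)
        assert g.n_edges == 45

    def test_parcellation_density_edge_count(self, rng):
        m = rng.normal(size=(333, 333))
        m = (m + m.T) / 2
        g = threshold_by_density(m, 0.05)
        assert g.n_edges == 2764  # round(0.05 * 55278)

    def test_equal_weights_deterministic_tiebreak(self):
        m = np.ones((5, 5))
        g1 = threshold_by_density(m, 0.3)
        g2 = threshold_by_density(m, 0.3)
        e1 = sorted((min(i, j), max(i, j)) for i in range(5)
                    for j, _ in g1.neighbors[i] if j > i)
        e2 = sorted((min(i, j), max(i, j)) for i in range(5)
                    for j, _ in g2.neighbors[i] if j > i)
        assert e1 == e2 == [(0, 1), (0, 2), (0, 3)]  # lowest (i, j) first

    def test_empty_graph_error(self):
        m = np.ones((30, 30))
        with pytest.raises(ValueError, match="keeps no edges"):
            threshold_by_density(m, 0.001)


class TestMapEquation:
    def test_single_module_is_visit_rate_entropy(self):
        g = _clique_pair_graph()
        p = g.strength / g.total_strength
        entropy = -np.sum(p * np.log2(p))
        assert map_equation(g, np.zeros(8, int)) == pytest.approx(entropy, abs=1e-12)

    def test_clique_split_beats_merged(self):
        g = _clique_pair_graph()
        two = map_equation(g, np.array([0, 0, 0, 0, 1, 1, 1, 1]))
        one = map_equation(g, np.zeros(8, int))
        assert two < one

    def test_disconnected_graph_rejected(self):
        g = Graph(4, [(0, 1, 1.0), (2, 3, 1.0)])
        with pytest.raises(ValueError, match="disconnected"):
            map_equation(g, np.zeros(4, int))


class TestInfomapPartition:
    def test_disjoint_cliques_found_per_component(self):
        edges = ([(i, j, 1.0) for i in range(4) for j in range(i + 1, 4)]
                 + [(i, j, 1.0) for i in range(4, 8) for j in range(i + 1, 8)])
        part = infomap_partition(Graph(8, edges), seed=0)
        assert len(set(part[:4])) == 1 and len(set(part[4:])) == 1
        assert part[0] != part[4]

    def test_planted_partition_recovery(self, rng):
        # 4 blocks of 30 nodes, p_in=0.3, p_out=0.01
        truth = np.repeat(np.arange(4), 30)
        nmis = []
        for seed in range(10):
            g_rng = np.random.default_rng(100 + seed)
            edges = []
            for i in range(120):
                for j in range(i + 1, 120):
                    p = 0.3 if truth[i] == truth[j] else 0.01
                    if g_rng.random() < p:
                        edges.append((i, j, 1.0))
            g = Graph(120, edges)
            part = infomap_partition(g, seed=seed, n_outer_loops=5)
            nmis.append(nmi(part, truth))
        assert min(nmis) >= 0.95

    def test_codelength_not_worse_than_singletons_or_merged(self, rng):
        m = rng.normal(size=(20, 20))
        m = np.abs((m + m.T) / 2)
        g = threshold_by_density(m, 0.4)
        if len(g.components()) == 1:
            part = infomap_partition(g, seed=3)
            l_opt = map_equation(g, part)
            assert l_opt <= map_equation(g, np.zeros(20, int)) + 1e-9
            assert l_opt <= map_equation(g, np.arange(20)) + 1e-9

    def test_empty_graph_error(self):
        with pytest.raises(ValueError, match="empty"):
            infomap_partition(Graph(0, []), seed=0)


class TestSizeFilter:
    def test_inclusive_boundary(self):
        part = np.array([0, 0, 0, 1, 1])
        out = size_filter(part, 2)
        assert out.tolist() == [0, 0, 0, UNASSIGNED, UNASSIGNED]

    def test_above_boundary_unchanged(self):
        part = np.array([0, 0, 0, 1, 1, 1])
        assert size_filter(part, 2).tolist() == part.tolist()

    def test_everything_filtered_warns(self):
        with pytest.warns(UserWarning, match="all-unassigned"):
            out = size_filter(np.array([0, 1, 2]), 5)
        assert all(x == UNASSIGNED for x in out)

    def test_vertex_scale_default_translates(self):
        assert networks.default_min_community_size(59412) == 400
        assert networks.default_min_community_size(333) == max(2, round(400 * 333 / 59412))


class TestMatchToTemplate:
    def test_identical_partition_zero_percent(self):
        template = np.array(["a"] * 5 + ["b"] * 5)
        part = np.array([0] * 5 + [1] * 5)
        res = match_to_template(part, template)
        assert res["percent_differing"] == 0.0
        assert list(res["labels"]) == list(template)

    def test_split_community_same_label(self):
        template = np.array(["a"] * 6 + ["b"] * 4)
        part = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2, 2])  # "a" split into two
        res = match_to_template(part, template)
        assert res["percent_differing"] == 0.0

    def test_random_relabeling_fraction_recovered(self, rng):
        template = np.repeat([f"n{k}" for k in range(5)], 40)
        part = np.repeat(np.arange(5), 40)
        flip = rng.choice(200, size=20, replace=False)
        for f in flip:
            part[f] = (part[f] + 1 + rng.integers(4)) % 5
        res = match_to_template(part, template)
        assert res["percent_differing"] == pytest.approx(0.10, abs=0.02)


class TestConsensus:
    def test_identical_everywhere(self):
        labels = np.array(["a", "a", "b"], dtype=object)
        out = multi_density_consensus({0.01: labels, 0.02: labels.copy()})
        assert list(out) == list(labels)

    def test_outlier_density_outvoted(self):
        good = np.array(["a", "b"], dtype=object)
        bad = np.array(["b", "b"], dtype=object)
        out = multi_density_consensus({0.01: good, 0.02: good, 0.05: bad})
        assert list(out) == ["a", "b"]

    def test_majority_unassigned_stays_unassigned(self):
        a = np.array([UNASSIGNED, "a"], dtype=object)
        out = multi_density_consensus({0.01: a, 0.02: a,
                                       0.05: np.array(["b", "a"], dtype=object)})
        assert out[0] == UNASSIGNED and out[1] == "a"


class TestNMI:
    def test_self_identity(self, rng):
        part = rng.integers(0, 6, size=200)
        assert nmi(part, part) == pytest.approx(1.0)

    def test_label_permutation_invariance(self, rng):
        part = rng.integers(0, 5, size=100)
        relabeled = (part + 2) % 5
        assert nmi(part, relabeled) == pytest.approx(1.0)

    def test_independent_partitions_near_zero(self, rng):
        a = rng.integers(0, 10, size=10_000)
        b = rng.integers(0, 10, size=10_000)
        assert nmi(a, b) < 0.01

    def test_unassigned_excluded_pairwise(self):
        a = np.array([0, 0, 1, 1, UNASSIGNED])
        b = np.array([5, 5, 9, UNASSIGNED, 9])
        # overlap restricted to the first three nodes: identical there
        assert nmi(a, b) == pytest.approx(1.0)

    def test_single_community_convention(self):
        assert nmi(np.zeros(5, int), np.ones(5, int) * 7) == 1.0


class TestDetectNetworks:
    def test_recovers_planted_block_structure(self, cohort400):
        parcels, _, conn = cohort400
        from connet.core import group_average
        cfg = networks.NetworkConfig(densities=tuple(np.geomspace(0.05, 0.5, 6)),
                                     infomap_seed=2)
        res = networks.detect_networks(group_average(conn[:100]), parcels, cfg)
        truth = parcels["template_network"].to_numpy()
        assert nmi(res["consensus"], truth) >= 0.95
        assert res["percent_differing"] <= 0.05

    def test_deterministic_given_seed(self, cohort400):
        parcels, _, conn = cohort400
        from connet.core import group_average
        ga = group_average(conn[:60])
        cfg = networks.NetworkConfig(densities=(0.1, 0.2, 0.3), infomap_seed=5)
        a = networks.detect_networks(ga, parcels, cfg)
        b = networks.detect_networks(ga, parcels, cfg)
        assert list(a["consensus"]) == list(b["consensus"])
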