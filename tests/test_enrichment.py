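import math

import numpy as np
import pytest
from scipy import stats

from connet import enrichment, simulate
from conftest import small_config


def hypergeom_tail_oracle(n_total, k_total, n_pair, k):
    """P(X >= k) by direct enumeration over draw counts."""
    total = math.comb(n_total, n_pair)
    acc = 0
    for x in range(k, min(n_pair, k_total) + 1):
        acc += math.comb(k_total, x) * math.comb(n_total - k_total, n_pair - x)
    return acc / total


def _sym_stack(rng, n, p, scale=1.0):
    m = rng.normal(scale=scale, size=(n, p, p))
    m = (m + m.transpose(0, 2, 1)) / 2
    m[:, np.arange(p), np.arange(p)] = 0.0
    return m


class TestBehaviorGLM:
    def test_null_behavior_calibrated(self, rng):
        conn = _sym_stack(rng, 120, 12)
        manu = rng.choice(["A", "B"], size=120)
        sex = rng.choice(["F", "M"], size=120)
        fracs = []
        for _ in range(30):
            res = enrichment.edgewise_behavior_glm(
                conn, rng.normal(size=120), manufacturer=manu, sex=sex)
            fracs.append(np.mean(res["p"] < 0.05))
        assert np.mean(fracs) == pytest.approx(0.05, abs=0.015)

    def test_behavior_equal_to_edge(self, rng):
        conn = _sym_stack(rng, 50, 4)
        behavior = conn[:, 0, 1]
        res = enrichment.edgewise_behavior_glm(conn, behavior)
        assert res["beta"][0] == pytest.approx(1.0, abs=1e-10)
        assert res["t"][0] > 1e6 or np.isinf(res["t"][0])

    def test_matches_statsmodels_multiple_regression(self, rng):
        import statsmodels.api as sm
        conn = _sym_stack(rng, 80, 5)
        manu = rng.choice(["A", "B", "C"], size=80)
        sex = rng.choice(["F", "M"], size=80)
        behavior = rng.normal(size=80) + 0.5 * conn[:, 0, 1]
        res = enrichment.edgewise_behavior_glm(conn, behavior,
                                               manufacturer=manu, sex=sex)
        from connet.core import stack_edges
        edges = stack_edges(conn)
        for e in [0, 3, 7]:
            x = np.column_stack([
                edges[:, e],
                (manu == "B").astype(float), (manu == "C").astype(float),
                (sex == "M").astype(float)])
            fit = sm.OLS(behavior, sm.add_constant(x)).fit()
            assert res["t"][e] == pytest.approx(fit.tvalues[1], abs=1e-8)

    def test_planted_pair_t_magnitude(self, rng):
        n = 1000
        conn = _sym_stack(rng, n, 6, scale=1.0)
        r_planted = 0.15
        edge = conn[:, 0, 1] / conn[:, 0, 1].std()
        behavior = r_planted * edge + np.sqrt(1 - r_planted**2) * rng.normal(size=n)
        res = enrichment.edgewise_behavior_glm(conn, behavior)
        expected_t = r_planted / np.sqrt(1 - r_planted**2) * np.sqrt(n - 2)
        assert res["t"][0] == pytest.approx(expected_t, abs=1.5)

    def test_single_level_covariate_error(self, rng):
        conn = _sym_stack(rng, 30, 4)
        with pytest.raises(ValueError, match="single level"):
            enrichment.edgewise_behavior_glm(conn, rng.normal(size=30),
                                             manufacturer=["A"] * 30)

    def test_missing_behavior_dropped(self, rng):
        conn = _sym_stack(rng, 40, 4)
        behavior = rng.normal(size=40)
        behavior[:5] = np.nan
        res = enrichment.edgewise_behavior_glm(conn, behavior)
        assert res["n"] == 35


class TestSplitHalfReliability:
    def test_identity_and_mismatch(self, rng):
        t = rng.normal(size=100)
        assert enrichment.split_half_reliability(t, t) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            enrichment.split_half_reliability(t, t[:50])

    def test_independent_null_halves(self, rng):
        e = 333 * 332 // 2
        r = enrichment.split_half_reliability(rng.normal(size=e), rng.normal(size=e))
        assert abs(r) < 0.02


class TestBinarize:
    def test_zero_r_all_zero(self):
        assert enrichment.binarize_associations(np.zeros(10), 100).sum() == 0

    def test_null_hit_rate(self, rng):
        n = 200
        fracs = []
        for _ in range(50):
            x = rng.normal(size=(n, 300))
            y = rng.normal(size=n)
            r = (y - y.mean()) @ (x - x.mean(0)) / (
                np.sqrt(((y - y.mean())**2).sum() * ((x - x.mean(0))**2).sum(0)))
            fracs.append(enrichment.binarize_associations(r, n).mean())
        assert np.mean(fracs) == pytest.approx(0.05, abs=0.01)

    def test_known_r_suprathreshold(self):
        out = enrichment.binarize_associations(np.array([0.10, 0.01]), 1000)
        assert out.tolist() == [1, 0]  # p(r=0.10, n=1000) ~ 0.0016


class TestHypergeometric:
    def test_small_case_enumeration(self):
        labels = np.array(["a"] * 3 + ["b"] * 2)  # N=10 edges total
        pairs, idx, counts = enrichment.network_pair_index(labels)
        hits = np.zeros(10, int)
        # place 5 hits, 4 of them among the 4 (a,b)-pair edges... use direct call
        p = stats.hypergeom.sf(4 - 1, 10, 5, 4)
        assert p == pytest.approx(5 / 210, rel=1e-9)
        assert p == pytest.approx(hypergeom_tail_oracle(10, 5, 4, 4), rel=1e-9)

    @pytest.mark.parametrize("n_total,k_total,n_pair,k", [
        (10, 5, 4, 4), (20, 8, 6, 3), (30, 15, 10, 5), (25, 3, 7, 0), (12, 12, 5, 5),
    ])
    def test_matches_enumeration(self, n_total, k_total, n_pair, k):
        p_scipy = stats.hypergeom.sf(k - 1, n_total, k_total, n_pair)
        assert p_scipy == pytest.approx(
            hypergeom_tail_oracle(n_total, k_total, n_pair, k), rel=1e-12)

    def test_everything_suprathreshold_gives_one(self):
        labels = np.array(["a"] * 4 + ["b"] * 4)
        pairs, idx, counts = enrichment.network_pair_index(labels)
        hits = np.ones(idx.shape[0], int)
        p = enrichment.hypergeometric_enrichment(hits, idx, counts)
        assert np.allclose(p[np.isfinite(p)], 1.0)

    def test_expected_count_not_enriched(self):
        labels = np.array(["a"] * 10 + ["b"] * 10)
        pairs, idx, counts = enrichment.network_pair_index(labels)
        rng = np.random.default_rng(0)
        hits = np.zeros(idx.shape[0], int)
        hits[rng.choice(idx.shape[0], size=idx.shape[0] // 2, replace=False)] = 1
        p = enrichment.hypergeometric_enrichment(hits, idx, counts)
        assert np.all(p[np.isfinite(p)] > 0.2)


class TestFDR:
    def test_step_up_by_hand(self):
        p = [0.01, 0.02, 0.03, 0.04, 0.05]
        reject, q = enrichment.fdr_bh(p, q=0.05)
        assert reject.all()  # p_(k) <= k q / m for k = m

    def test_all_ones_none_significant(self):
        reject, _ = enrichment.fdr_bh([1.0, 1.0, 1.0])
        assert not reject.any()

    def test_single_small_p(self):
        reject, q = enrichment.fdr_bh([0.04], q=0.05)
        assert reject[0] and q[0] == pytest.approx(0.04)

    def test_empty_input(self):
        reject, q = enrichment.fdr_bh([])
        assert reject.size == 0 and q.size == 0

    def test_matches_manual_step_up(self, rng):
        p = rng.uniform(size=25)
        reject, _ = enrichment.fdr_bh(p, q=0.1)
        order = np.argsort(p)
        thresh = 0
        for k, idx in enumerate(order, start=1):
            if p[idx] <= k * 0.1 / 25:
                thresh = k
        manual = np.zeros(25, bool)
        manual[order[:thresh]] = True
        assert np.array_equal(reject, manual)


class TestPermutationNull:
    def test_planted_pair_detected_others_null(self):
        cfg = small_config(n_participants=800, seed=41,
                           planted_pairs=[("Default", "DorsalAttn", -0.2)],
                           missing_behavior_fraction=0.0)
        parcels, participants, conn = simulate.simulate_cohort(cfg)
        table = enrichment.enrichment_table(
            conn, participants["behavior"].to_numpy(),
            parcels["template_network"].to_numpy(), n_perm=1000, seed=1)
        planted = table[(table.network_a == "Default") & (table.network_b == "DorsalAttn")]
        assert planted["perm_p"].iloc[0] < 0.01
        assert planted["mean_sign"].iloc[0] < 0
        others = table[~((table.network_a == "Default") & (table.network_b == "DorsalAttn"))]
        assert others["perm_p"].median() > 0.2

    def test_minimum_permutations_enforced(self, rng):
        conn = _sym_stack(rng, 30, 6)
        labels = np.array(["a"] * 3 + ["b"] * 3)
        pairs, idx, counts = enrichment.network_pair_index(labels)
        with pytest.raises(ValueError, match="n_perm"):
            enrichment.permutation_null(conn, rng.normal(size=30), idx, counts,
                                        np.ones(len(pairs)), n_perm=10)

    def test_participant_order_invariance(self, rng):
        cfg = small_config(n_participants=100, seed=43, missing_behavior_fraction=0.0)
        parcels, participants, conn = simulate.simulate_cohort(cfg)
        beh = participants["behavior"].to_numpy()
        labels = parcels["template_network"].to_numpy()
        perm = rng.permutation(100)
        a = enrichment.enrichment_table(conn, beh, labels, n_perm=200, seed=9)
        b = enrichment.enrichment_table(conn[perm], beh[perm], labels, n_perm=200, seed=9)
        assert np.allclose(a["hyper_p"], b["hyper_p"], equal_nan=True)


class TestInteractionCheck:
    def test_null_interaction_near_expected_inflation(self, rng):
        n = 300
        conn = _sym_stack(rng, n, 8)
        manu = rng.choice(["A", "B", "C"], size=n)
        behavior = rng.normal(size=n)
        res = enrichment.manufacturer_interaction_check(conn, behavior, manu)
        assert res["mean_delta_r2"] == pytest.approx(res["null_expectation"], abs=0.01)
        assert res["mean_delta_r2"] < 0.03

    def test_planted_interaction_detected(self, rng):
        n = 300
        conn = _sym_stack(rng, n, 4)
        manu = np.array(["A", "B"])[rng.integers(0, 2, n)]
        slope = np.where(manu == "A", 0.8, -0.8)
        behavior = slope * conn[:, 0, 1] + rng.normal(size=n)
        res = enrichment.manufacturer_interaction_check(conn, behavior, manu)
        null = res["null_expectation"]
        assert res["delta_r2"][0] > null + 0.05

    def test_rank_deficiency_error(self, rng):
        conn = _sym_stack(rng, 6, 4)
        manu = ["A", "B", "C", "A", "B", "C"]
        with pytest.raises(ValueError, match="too few"):
            enrichment.manufacturer_interaction_check(conn, rng.normal(size=6), manu)
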