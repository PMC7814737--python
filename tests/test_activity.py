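"""Activity calling, differential statistics, usage, and evaluation metrics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from promact.activity import (
    bh_adjust,
    call_activity,
    differential_activity,
    evaluate_regression,
    expression_consistency,
    feature_response_screen,
    promoter_usage,
    ranksum_pvalue,
    sample_specific_fraction,
)


def bimodal(rng, n=2000, means=(-2.0, 3.0), sd=0.5, p_active=0.4):
    labels = rng.random(n) < p_active
    x = np.where(labels, rng.normal(means[1], sd, n), rng.normal(means[0], sd, n))
    return x, labels


class TestActivityCalling:
    def test_recovers_planted_bimodal_labels(self, rng):
        x, labels = bimodal(rng)
        calls = call_activity(x)
        agreement = ((calls["state"] == "active") == labels).mean()
        assert agreement >= 0.99

    def test_posterior_in_valid_range(self, rng):
        x, _ = bimodal(rng, n=500)
        calls = call_activity(x)
        assert (calls["posterior"] >= 0.5).all()
        assert (calls["posterior"] <= 1.0).all()

    def test_labels_invariant_to_seed_relabeling(self, rng):
        """Which component index the GMM assigns must not change the calls."""
        x, _ = bimodal(rng, n=1000)
        c1 = call_activity(x, random_state=0)
        c2 = call_activity(x, random_state=17)
        assert (c1["state"] == c2["state"]).mean() > 0.995

    def test_affine_invariance(self, rng):
        x, _ = bimodal(rng, n=1000)
        c1 = call_activity(x)
        c2 = call_activity(3.0 * x + 7.0)
        assert (c1["state"] == c2["state"]).all()

    def test_degenerate_unimodal_input(self, rng):
        x = np.full(100, 1.0) + rng.normal(0, 1e-6, 100)
        calls = call_activity(x)
        assert calls["state"].nunique() <= 2  # converges without error

    def test_needs_two_distinct_values(self):
        with pytest.raises(ValueError, match="distinct"):
            call_activity(np.ones(10))


class TestSampleSpecificFraction:
    def _calls(self, active_ids, universe):
        return pd.DataFrame({
            "transcript_id": universe,
            "state": ["active" if t in active_ids else "inactive" for t in universe],
            "posterior": 1.0,
        })

    def test_identical_sets_zero(self):
        u = list("ABCDE")
        res = sample_specific_fraction({"s1": self._calls({"A", "B"}, u),
                                        "s2": self._calls({"A", "B"}, u)})
        assert res["fraction"].iloc[0] == 0.0

    def test_disjoint_sets_one(self):
        u = list("ABCDE")
        res = sample_specific_fraction({"s1": self._calls({"A"}, u),
                                        "s2": self._calls({"B", "C"}, u)})
        assert res["fraction"].iloc[0] == 1.0

    def test_hand_counted_example(self):
        u = ["1", "2", "3", "4", "5"]
        res = sample_specific_fraction({"A": self._calls({"1", "2", "3"}, u),
                                        "B": self._calls({"3", "4"}, u)})
        assert res["fraction"].iloc[0] == pytest.approx(3 / 4)

    def test_symmetric_and_bounded(self, rng):
        u = [str(i) for i in range(30)]
        calls = {
            s: self._calls(set(rng.choice(u, size=rng.integers(1, 20), replace=False)), u)
            for s in ["a", "b", "c"]
        }
        res = sample_specific_fraction(calls)
        assert ((res["fraction"] >= 0) & (res["fraction"] <= 1)).all()
        rev = sample_specific_fraction({"b": calls["b"], "a": calls["a"]})
        pair = res[(res["sample_a"] == "a") & (res["sample_b"] == "b")]["fraction"].iloc[0]
        assert rev["fraction"].iloc[0] == pair

    def test_empty_union_is_missing(self):
        u = list("AB")
        res = sample_specific_fraction({"s1": self._calls(set(), u), "s2": self._calls(set(), u)})
        assert np.isnan(res["fraction"].iloc[0])


def exact_ranksum_oracle(a, b):
    """Enumerate every group-label assignment; two-sided tail probability."""
    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n_a = len(a)
    mu = n_a * (len(pooled) + 1) / 2
    obs = abs(ranks[:n_a].sum() - mu)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        total += 1
        if abs(ranks[list(combo)].sum() - mu) >= obs - 1e-9:
            count += 1
    return count / total


class TestRankSum:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exact_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_a, n_b = rng.integers(2, 7, size=2)
        a = rng.normal(0, 1, n_a).round(1)  # rounding induces ties
        b = rng.normal(0.5, 1, n_b).round(1)
        _, p = ranksum_pvalue(a, b)
        assert p == pytest.approx(exact_ranksum_oracle(a, b), abs=1e-12)

    def test_all_tied_gives_p_one(self):
        _, p = ranksum_pvalue(np.ones(4), np.ones(5))
        assert p == 1.0

    def test_large_groups_use_normal_approximation(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(2, 1, 30)
        _, p = ranksum_pvalue(a, b)
        assert p < 1e-6


class TestBH:
    def test_printed_toy_pvalues(self):
        # hand step-up: q_i = min over j>=i of p_(j) * m / j
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.5]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_matches_brute_force_step_up(self, rng):
        p = rng.random(15)
        q = bh_adjust(p)
        m = len(p)
        order = np.argsort(p)
        expected = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, p[i] * m / (rank_idx + 1))
            expected[i] = running
        np.testing.assert_allclose(q, expected)
        # q monotone in p-rank
        assert (np.diff(q[order]) >= -1e-12).all()


class TestDifferentialActivity:
    def test_identical_groups_nothing_significant(self, rng):
        g = rng.normal(0, 1, size=(50, 4))
        res = differential_activity(g, g.copy())
        assert res["significant"].sum() == 0
        assert (res["q"] >= res["p"] - 1e-12).all()

    def test_planted_shift_dominates_significant_set(self, rng):
        n = 200
        a = rng.normal(0, 1, size=(n, 8))
        b = rng.normal(0, 1, size=(n, 8))
        shifted = np.arange(n) < 20
        b[shifted] += 2.0
        res = differential_activity(a, b)
        sig = res["significant"].to_numpy()
        assert sig[shifted].sum() >= 0.5 * shifted.sum()
        # most of the significant set is planted
        assert (sig & shifted).sum() >= 0.8 * max(sig.sum(), 1)

    def test_requires_two_samples_per_group(self, rng):
        with pytest.raises(ValueError, match="2 samples"):
            differential_activity(rng.normal(size=(10, 1)), rng.normal(size=(10, 4)))


class TestPromoterUsage:
    def _toy(self):
        # gene G with 2 promoters; groups cleanly swap the primary promoter
        samples = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        act = pd.DataFrame(
            {s: ([3.0, 0.0] if s.startswith("a") else [0.0, 3.0]) for s in samples},
            index=["T1", "T2"],
        )
        groups = {s: ("g1" if s.startswith("a") else "g2") for s in samples}
        gene_map = {"T1": "G", "T2": "G"}
        return act, groups, gene_map

    def test_clean_switch_detected(self):
        act, groups, gene_map = self._toy()
        res = promoter_usage(act, groups, gene_map, activity_delta=1.0)
        assert len(res) == 1
        row = res.iloc[0]
        assert row["primary_group1"] == "T1" and row["primary_group2"] == "T2"
        assert row["significant"]

    def test_same_primary_not_a_candidate(self):
        act, groups, gene_map = self._toy()
        act.loc["T2"] = 0.0  # T1 primary everywhere
        act.loc["T1"] = 3.0
        res = promoter_usage(act, groups, gene_map)
        assert len(res) == 0

    def test_gene_inactive_in_one_group_excluded(self):
        act, groups, gene_map = self._toy()
        for s in act.columns:
            if s.startswith("b"):
                act[s] = [0.5, 0.2]  # below the activity threshold in group 2
        res = promoter_usage(act, groups, gene_map)
        assert len(res) == 0

    def test_single_promoter_gene_skipped(self):
        act, groups, gene_map = self._toy()
        gene_map = {"T1": "G1", "T2": "G2"}  # each gene has one promoter
        res = promoter_usage(act, groups, gene_map)
        assert len(res) == 0


class TestEvaluateRegression:
    def test_identity(self, rng):
        x = rng.normal(0, 1, 50)
        res = evaluate_regression(x, x)
        assert res["r2"] == pytest.approx(1.0)
        assert res["rmse"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset(self, rng):
        x = rng.normal(0, 1, 50)
        res = evaluate_regression(x + 1.5, x)
        assert res["r2"] == pytest.approx(1.0)
        assert res["rmse"] == pytest.approx(1.5)

    def test_sign_flip_keeps_r2(self, rng):
        x = rng.normal(0, 1, 50)
        res = evaluate_regression(-x, x)
        assert res["r2"] == pytest.approx(1.0)
        assert res["rmse"] > 1.0

    def test_mappability_filter(self, rng):
        x = rng.normal(0, 1, 50)
        y = x.copy()
        y[:10] += 10  # corrupted low-mappability promoters
        mapp = np.ones(50)
        mapp[:10] = 0.5
        res = evaluate_regression(y, x, mappability=mapp, threshold=0.75)
        assert res["n"] == 40
        assert res["rmse"] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_promoters(self):
        with pytest.raises(ValueError, match="promoters"):
            evaluate_regression(np.ones(2), np.ones(2))


class TestExpressionConsistency:
    def test_perfect_consistency(self):
        n = 100
        act = np.linspace(-2, 5, n)
        fpkm = 2.0 ** act - 2.0 ** -2
        expr = pd.DataFrame({"gene_id": [f"G{i}" for i in range(n)], "fpkm": np.maximum(fpkm, 0)})
        from promact.response import EnrichmentVector

        vec = EnrichmentVector(values=act, transcript_ids=np.array([f"T{i}" for i in range(n)]))
        gmap = {f"T{i}": f"G{i}" for i in range(n)}
        res = expression_consistency(vec, expr, gmap)
        assert res["auroc"] == 1.0
        assert res["r2"] > 0.9

    def test_independent_activity_auroc_half(self, rng):
        n = 4000
        act = rng.normal(0, 1, n)
        expr = pd.DataFrame({"gene_id": [f"G{i}" for i in range(n)],
                             "fpkm": rng.gamma(1, 3, n)})
        from promact.response import EnrichmentVector

        vec = EnrichmentVector(values=act, transcript_ids=np.array([f"T{i}" for i in range(n)]))
        res = expression_consistency(vec, expr, {f"T{i}": f"G{i}" for i in range(n)})
        assert abs(res["auroc"] - 0.5) < 0.05

    def test_max_promoter_aggregation(self):
        from promact.response import EnrichmentVector

        vec = EnrichmentVector(values=np.array([1.0, 5.0, 2.0]),
                               transcript_ids=np.array(["T1", "T2", "T3"]))
        gmap = {"T1": "G1", "T2": "G1", "T3": "G2"}
        expr = pd.DataFrame({"gene_id": ["G1", "G2"], "fpkm": [10.0, 0.0]})
        res = expression_consistency(vec, expr, gmap)
        assert res["n_genes"] == 2
        assert res["auroc"] == 1.0  # G1 scored by its max promoter (5.0) beats G2 (2.0)

    def test_single_class_labels_undefined(self):
        from promact.response import EnrichmentVector

        vec = EnrichmentVector(values=np.array([1.0, 2.0, 3.0]),
                               transcript_ids=np.array(["T1", "T2", "T3"]))
        expr = pd.DataFrame({"gene_id": ["G1", "G2", "G3"], "fpkm": [5.0, 6.0, 7.0]})
        res = expression_consistency(vec, expr, {f"T{i}": f"G{i}" for i in (1, 2, 3)})
        assert res["auroc"] is None


class TestFeatureScreen:
    def test_planted_and_noise_columns(self, rng):
        n = 500
        raw = rng.normal(0, 1, (n, 2, 20, 3))
        y = raw[:, 0, 9, 0] * 2.0
        res = feature_response_screen(raw, y)
        planted = res[(res["scale"] == 0) & (res["window"] == 9) & (res["channel"] == 0)]
        assert planted["r2"].iloc[0] == pytest.approx(1.0)
        assert planted["best"].iloc[0]
        noise = res[(res["scale"] == 1)]
        assert noise["r2"].max() < 0.1

    def test_constant_column_flagged(self, rng):
        raw = rng.normal(0, 1, (50, 2, 20, 3))
        raw[:, 0, 0, 0] = 4.2
        res = feature_response_screen(raw, rng.normal(0, 1, 50))
        row = res[(res["scale"] == 0) & (res["window"] == 0) & (res["channel"] == 0)]
        assert row["constant"].iloc[0]
        assert row["r2"].iloc[0] == 0.0
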