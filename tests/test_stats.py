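"""Hypothesis testing, FDR control, enrichment and survival analysis.

Independent oracles: hand step-up for BH, hypergeometric enumeration for
the Fisher test, scipy's pooled t for the moderated statistic at s0 = 0,
a from-scratch observed-minus-expected log-rank computation, and the
repeated-measures F checked against pingouin.
"""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from protokg.prep import ExperimentMatrix
from protokg.stats import (SignificanceThresholds, bh_fdr, detect_design,
                           differential_regulation, fisher_enrichment,
                           km_logrank, pca, permutation_fdr, sam_statistic,
                           summarize_matrix)


def make_matrix(values, groups, subjects=None, features=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"f{j}" for j in range(values.shape[1])]
    samples = [f"s{i}" for i in range(values.shape[0])]
    meta = {"group": groups}
    if subjects is not None:
        meta["subject"] = subjects
    return ExperimentMatrix(
        values=pd.DataFrame(values, index=samples, columns=features),
        sample_meta=pd.DataFrame(meta, index=samples),
    )


class TestSummarize:
    def test_constant_feature_has_zero_cv(self):
        m = make_matrix([[3, 4], [3, 5], [3, 6]], ["a", "a", "b"])
        out = summarize_matrix(m)
        assert out["cv"].loc["f0", "cv_percent"] == 0.0

    def test_dynamic_range_ranks_linear_means(self):
        # log2 means chosen so linear means are 100 and 10
        m = make_matrix([[np.log2(100), np.log2(10)]] * 3, ["a", "a", "a"])
        out = summarize_matrix(m)
        assert out["dynamic_range"].loc["f0", "rank"] == 1
        assert out["dynamic_range"].loc["f1", "rank"] == 2

    def test_empty_group_level_does_not_crash(self):
        m = make_matrix([[1, 2], [3, 4]], ["a", "a"])
        m.sample_meta["group"] = pd.Categorical(["a", "a"], categories=["a", "b"])
        out = summarize_matrix(m)
        assert out["group_counts"].loc["a", "n_samples"] == 2


class TestPCA:
    def test_two_samples_put_all_variance_on_pc1(self):
        m = make_matrix([[1, 2, 3], [4, 5, 6]], ["a", "b"])
        result = pca(m, n_components=2)
        assert result.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_scores_preserve_pairwise_distances_in_full_rank(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(5, 4))
        m = make_matrix(x, ["a"] * 5)
        result = pca(m, n_components=4)
        d_orig = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        s = result.scores.to_numpy()
        d_pca = np.linalg.norm(s[:, None] - s[None, :], axis=-1)
        np.testing.assert_allclose(d_orig, d_pca, atol=1e-8)

    def test_duplicated_samples_add_no_variance_directions(self):
        x = np.array([[1.0, 2.0], [3.0, 1.0]])
        m = make_matrix(np.vstack([x, x]), ["a"] * 4)
        result = pca(m, n_components=2)
        assert result.explained_variance_ratio[1] == pytest.approx(0.0, abs=1e-12)

    def test_incomplete_matrix_directs_to_impute(self):
        m = make_matrix([[1, np.nan], [2, 3]], ["a", "b"])
        with pytest.raises(ValueError, match="impute"):
            pca(m)


class TestSamStatistic:
    def test_zero_pooled_se_with_s0_two_gives_half_diff(self):
        a = np.array([[5.0], [5.0]])
        b = np.array([[3.0], [3.0]])
        assert sam_statistic(a, b, s0=2.0)[0] == pytest.approx(1.0)

    def test_s0_zero_equals_pooled_t(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(6, 40))
        b = rng.normal(0.5, 1.2, size=(8, 40))
        d = sam_statistic(a, b, s0=0.0)
        t, _ = sps.ttest_ind(a, b, axis=0, equal_var=True)
        np.testing.assert_allclose(d, t, rtol=1e-10)

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=(5, 10)), rng.normal(size=(5, 10))
        np.testing.assert_allclose(sam_statistic(a, b, s0=1.0),
                                   -sam_statistic(b, a, s0=1.0))

    def test_zero_variance_and_zero_s0_is_undefined(self):
        with pytest.raises(ZeroDivisionError):
            sam_statistic([[1.0], [1.0]], [[2.0], [2.0]], s0=0.0)


class TestBhFdr:
    def test_hand_step_up_on_four_pvalues(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_all_ones_stay_one(self):
        assert (bh_fdr([1.0, 1.0, 1.0]) == 1.0).all()

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(1)
        p = rng.random(50)
        assert (bh_fdr(p) >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20), st.randoms())
    def test_invariant_under_input_permutation(self, pvals, rnd):
        shuffled = list(pvals)
        rnd.shuffle(shuffled)
        assert sorted(bh_fdr(pvals)) == pytest.approx(sorted(bh_fdr(shuffled)))


class TestDifferentialRegulation:
    def test_identical_groups_are_ns_with_zero_statistic(self):
        m = make_matrix([[1], [2], [3], [1], [2], [3]], ["a"] * 3 + ["b"] * 3)
        out = differential_regulation(m)
        assert out.loc[0, "statistic"] == 0.0
        assert out.loc[0, "pvalue"] == 1.0
        assert out.loc[0, "regulation"] == "ns"

    def test_three_identical_groups_give_zero_f(self):
        m = make_matrix([[1], [2], [1], [2], [1], [2]], ["a", "a", "b", "b", "c", "c"])
        out = differential_regulation(m)
        omnibus = out[out["contrast"] == "omnibus"]
        assert omnibus["statistic"].iloc[0] == 0.0

    def test_two_group_equals_manual_ttest_plus_bh(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(10, 25))
        x[5:, :5] += 3.0
        m = make_matrix(x, ["a"] * 5 + ["b"] * 5)
        out = differential_regulation(m)
        t, p = sps.ttest_ind(x[5:], x[:5], axis=0, equal_var=True)
        np.testing.assert_allclose(out["statistic"], t)
        np.testing.assert_allclose(out["padj"], bh_fdr(p))

    def test_shared_subjects_trigger_paired_ttest(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(8, 12))
        subjects = [f"p{i}" for i in range(4)] * 2
        m = make_matrix(x, ["pre"] * 4 + ["post"] * 4, subjects=subjects)
        assert detect_design(m) == "two_group_paired"
        out = differential_regulation(m)
        assert (out["test"] == "paired_ttest").all()
        t, _ = sps.ttest_rel(x[:4], x[4:], axis=0)
        np.testing.assert_allclose(np.abs(out["statistic"]), np.abs(t))

    def test_repeated_measures_anova_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(10)
        n_subj, k = 6, 3
        x = rng.normal(size=(n_subj * k, 3))
        subjects = [f"p{i}" for i in range(n_subj)] * k
        groups = [g for g in ["t1", "t2", "t3"] for _ in range(n_subj)]
        m = make_matrix(x, groups, subjects=subjects)
        assert detect_design(m) == "multi_group_repeated"
        out = differential_regulation(m)
        omnibus = out[out["contrast"] == "omnibus"]
        long = pd.DataFrame({"y": x[:, 0], "subject": subjects, "cond": groups})
        oracle = pingouin.rm_anova(data=long, dv="y", within="cond", subject="subject")
        assert omnibus["statistic"].iloc[0] == pytest.approx(oracle["F"].iloc[0])
        assert omnibus["pvalue"].iloc[0] == pytest.approx(oracle["p_unc"].iloc[0])

    def test_anova_with_posthoc_flags_use_joint_bh(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(12, 8))
        x[8:, 0] += 4.0
        m = make_matrix(x, ["a"] * 4 + ["b"] * 4 + ["c"] * 4)
        out = differential_regulation(m)
        posthoc = out[out["test"] == "posthoc_ttest"]
        assert set(posthoc["contrast"]) == {"b_vs_a", "c_vs_a", "c_vs_b"}
        assert len(posthoc) == 3 * 8
        hit = posthoc[(posthoc["feature"] == "f0") & (posthoc["contrast"] == "c_vs_a")]
        assert hit["regulation"].iloc[0] == "up"

    def test_flag_thresholds_follow_fold_change_rule(self):
        thresholds = SignificanceThresholds()
        assert thresholds.flag([1.5], [0.01])[0] == "up"  # FC 2.83 > 2
        assert thresholds.flag([-1.5], [0.01])[0] == "down"
        assert thresholds.flag([0.5], [0.01])[0] == "ns"
        assert thresholds.flag([1.5], [0.2])[0] == "ns"


class TestPermutationFdr:
    def make_separated(self, n_per=5, n_feat=12, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(2 * n_per, n_feat))
        x[n_per:, 0] += 20.0  # perfectly separated feature
        return make_matrix(x, ["a"] * n_per + ["b"] * n_per)

    def test_same_seed_identical_estimates(self):
        m = self.make_separated()
        a = permutation_fdr(m, permutations=60, seed=5)
        b = permutation_fdr(m, permutations=60, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_perfect_separation_gets_near_zero_fdr(self):
        m = self.make_separated()
        out = permutation_fdr(m, permutations=100, seed=2)
        top = out.loc[out["statistic"].abs().idxmax()]
        assert top["feature"] == "f0"
        # label permutations retaining the split contribute; estimate stays small
        assert top["qvalue"] <= 0.05

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            permutation_fdr(self.make_separated(), permutations=5)

    def test_tiny_design_falls_back_to_bh_with_warning(self):
        m = self.make_separated(n_per=2)  # C(4,2)=6 distinct labelings < 10
        with pytest.warns(UserWarning, match="falling back to BH"):
            out = permutation_fdr(m, permutations=50, seed=1)
        assert out.attrs["method"] == "bh_fallback"

    def test_qvalues_monotone_in_statistic_magnitude(self):
        m = self.make_separated(n_feat=20, seed=3)
        out = permutation_fdr(m, permutations=80, seed=3)
        ordered = out.reindex(out["statistic"].abs().sort_values(ascending=False).index)
        assert (np.diff(ordered["qvalue"]) >= -1e-12).all()


def hypergeom_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher p by enumeration over the hypergeometric support."""
    n_hit, n_term, total = a + b, a + c, a + b + c + d

    def prob(k):
        return (comb(n_hit, k) * comb(total - n_hit, n_term - k)) / comb(total, n_term)

    p_obs = prob(a)
    support = range(max(0, n_term + n_hit - total), min(n_term, n_hit) + 1)
    return sum(prob(k) for k in support if prob(k) <= p_obs + 1e-12)


class TestFisherEnrichment:
    def test_printed_style_two_by_two_table(self):
        # universe {p1..p4}, hits {p1,p2}, term {p1,p2} -> table [[2,0],[0,2]]
        out = fisher_enrichment({"p1", "p2"}, {"T": {"p1", "p2"}},
                                {"p1", "p2", "p3", "p4"})
        assert out["pvalue"].iloc[0] == pytest.approx(1 / 3)

    def test_hits_equal_universe_gives_p_one(self):
        universe = {f"p{i}" for i in range(6)}
        out = fisher_enrichment(universe, {"T1": {"p0", "p1"}, "T2": {"p2"}}, universe)
        assert (out["pvalue"] == 1.0).all()

    def test_matches_hypergeometric_enumeration_oracle(self):
        rng = np.random.default_rng(12)
        universe = [f"p{i}" for i in range(30)]
        for _ in range(10):
            hits = set(rng.choice(universe, size=8, replace=False))
            term = set(rng.choice(universe, size=10, replace=False))
            out = fisher_enrichment(hits, {"T": term}, universe)
            a = len(hits & term)
            b = len(hits - term)
            c = len(term - hits)
            d = 30 - a - b - c
            assert out["pvalue"].iloc[0] == pytest.approx(
                hypergeom_two_sided_oracle(a, b, c, d))

    def test_sorted_by_adjusted_p_then_term(self):
        universe = {f"p{i}" for i in range(20)}
        hits = {f"p{i}" for i in range(5)}
        sets = {"B": {"p0", "p1", "p2"}, "A": {"p10", "p11"}, "C": {"p0", "p1", "p2"}}
        out = fisher_enrichment(hits, sets, universe)
        assert list(out["term"])[:2] == ["B", "C"]  # tied padj -> term order

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment(set(), {"T": set()}, set())


def logrank_oracle(times, events, labels):
    """From-scratch two-group log-rank chi-square."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels = np.asarray(labels)
    o_minus_e, var = 0.0, 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & (labels == "high")).sum()
        d = ((times == t) & (events == 1)).sum()
        d_a = ((times == t) & (events == 1) & (labels == "high")).sum()
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


class TestKmLogrank:
    def test_no_events_reports_sentinel_and_flat_curves(self):
        res = km_logrank([5, 6, 7, 8], [0, 0, 0, 0], [1, 2, 3, 4], split=0.5)
        assert res.note == "no-events"
        assert np.isnan(res.pvalue)
        for curve in res.curves.values():
            assert (curve["survival"] == 1.0).all()

    def test_identical_groups_give_zero_statistic(self):
        times = [1, 2, 3, 1, 2, 3]
        events = [1, 1, 1, 1, 1, 1]
        expr = [0, 0, 0, 1, 1, 1]
        res = km_logrank(times, events, expr, split=0.5)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)

    def test_matches_hand_observed_minus_expected_oracle(self):
        times = [1, 3, 5, 2, 4, 6]
        events = [1, 1, 1, 1, 1, 1]
        expr = [1, 1, 1, 0, 0, 0]  # first three samples form the high group
        res = km_logrank(times, events, expr, split=0.5)
        labels = res.groups.to_numpy()
        assert res.statistic == pytest.approx(logrank_oracle(times, events, labels))

    def test_top_quarter_split_sizes(self):
        expr = list(range(20))
        res = km_logrank([1] * 20, [1] * 20, expr, split=0.25)
        assert (res.groups == "high").sum() == 5
        assert res.rule == "top25pct"

    def test_survival_curves_are_non_increasing_from_one(self):
        rng = np.random.default_rng(14)
        times = rng.exponential(5, 30)
        events = rng.integers(0, 2, 30)
        events[0] = 1
        res = km_logrank(times, events, rng.normal(size=30), split=0.5)
        for curve in res.curves.values():
            surv = curve["survival"].to_numpy()
            assert surv[0] == 1.0
            assert (np.diff(surv) <= 1e-12).all()
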