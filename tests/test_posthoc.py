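"""Post-hoc battery: network means, ANCOVA, correlations, effect sizes, ROC, specificity."""

import numpy as np
import pytest
from scipy import stats

import crossconn as cc
from crossconn.exceptions import ParameterError
from crossconn.nbs import NetworkMask


def mask_of(edges, n_nodes):
    return NetworkMask(edges=np.asarray(edges), n_nodes=n_nodes)


class TestNetworkMean:
    def test_two_edge_example(self):
        vec = np.zeros(cc.n_edges(4))
        m = mask_of([(0, 1), (2, 3)], 4)
        vec[m.edge_indices()] = [0.2, 0.4]
        assert cc.network_mean(vec, m) == pytest.approx(0.3)

    def test_constant_edges(self):
        vec = np.full(cc.n_edges(5), 0.7)
        assert cc.network_mean(vec, mask_of([(0, 1), (1, 2), (3, 4)], 5)) == pytest.approx(0.7)

    def test_matches_direct_summation(self, rng):
        y = rng.normal(size=(12, cc.n_edges(10)))
        m = mask_of([(0, 3), (2, 7), (5, 9), (1, 2)], 10)
        idx = m.edge_indices()
        assert np.allclose(cc.network_mean(y, m), y[:, idx].sum(axis=1) / 4, atol=1e-12)

    def test_empty_mask_rejected(self, rng):
        empty = NetworkMask(edges=np.empty((0, 2), dtype=int), n_nodes=5)
        with pytest.raises(ParameterError, match="empty"):
            cc.network_mean(rng.normal(size=cc.n_edges(5)), empty)


class TestAncova:
    def test_identical_groups(self, design_factory):
        design = design_factory(5, n_groups=3)
        rep = cc.ancova_group_test(np.full(15, 1.3), design)
        assert rep.value == pytest.approx(0.0)

    @staticmethod
    def _oneway_f(y, codes):
        groups = [y[codes == g] for g in np.unique(codes)]
        grand = y.mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        return (ssb / (len(groups) - 1)) / (ssw / (len(y) - len(groups)))

    def test_no_covariates_equals_textbook_anova(self, design_factory, rng):
        design = design_factory(9, n_groups=3)
        y = rng.normal(size=27)
        rep = cc.ancova_group_test(y, design)
        assert rep.value == pytest.approx(self._oneway_f(y, design.group_codes()), abs=1e-10)

    def test_trend_detects_ordered_means(self, design_factory, rng):
        design = design_factory(20, n_groups=3)
        y = np.repeat([0.0, 0.5, 1.0], 20) + rng.normal(0, 0.1, 60)
        rep = cc.ancova_group_test(y, design, contrast="linear_trend")
        assert rep.p < 0.001
        assert rep.value > 0

    def test_trend_matches_statsmodels(self, design_factory, rng):
        pytest.importorskip("statsmodels")
        from statsmodels.formula.api import ols
        import pandas as pd

        design = design_factory(10, n_groups=3, covariates="numeric", seed=5)
        y = rng.normal(size=30)
        rep = cc.ancova_group_test(y, design, contrast="linear_trend")
        df = design.covariates.copy()
        df["y"] = y
        df["score"] = design.group_codes() - design.group_codes().mean()
        fit = ols("y ~ age + fd + score", df).fit()
        assert rep.value == pytest.approx(fit.tvalues["score"], rel=1e-8)
        assert rep.p == pytest.approx(fit.pvalues["score"], rel=1e-8)


class TestParadigmWise:
    def test_bonferroni_arithmetic(self, design_factory, rng):
        design = design_factory(20, n_groups=2)
        y = rng.normal(size=(40, 5))
        reports = cc.paradigm_wise_group_tests(y, design)
        assert len(reports) == 5
        for r in reports:
            assert r.p_corrected == pytest.approx(min(1.0, 5 * r.p))

    def test_familywise_error_controlled(self, design_factory, rng):
        design = design_factory(15, n_groups=2)
        fails = 0
        n_rep = 300
        for _ in range(n_rep):
            y = rng.normal(size=(30, 5))
            reports = cc.paradigm_wise_group_tests(y, design)
            fails += any(r.p_corrected <= 0.05 for r in reports)
        # binomial 3-sigma envelope around 0.05
        assert fails / n_rep <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)


class TestCorrelate:
    def test_monotone_pairs(self):
        x = np.arange(10.0)
        assert cc.correlate(x, 2 * x + 1).value == pytest.approx(1.0)
        assert cc.correlate(x, -x).value == pytest.approx(-1.0)

    def test_tied_ranks_hand_value(self):
        rep = cc.correlate([1, 2, 2, 3], [1, 3, 2, 4])
        assert rep.value == pytest.approx(4.5 / np.sqrt(4.5 * 5.0))

    def test_exact_small_sample_p(self, rng):
        # exact permutation p enumerates all orderings; for n=5 and a perfect
        # monotone pair the two-sided p is 2/5!
        x = np.arange(5.0)
        rep = cc.correlate(x, x**3)
        assert rep.p == pytest.approx(2 / 120)

    def test_t_approximation_for_larger_n(self, rng):
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        rep = cc.correlate(x, y)
        assert rep.p == pytest.approx(stats.spearmanr(x, y).pvalue, rel=1e-10)

    def test_constant_input_rejected(self):
        with pytest.raises(ParameterError, match="constant"):
            cc.correlate([1, 1, 1, 1], [1, 2, 3, 4])

    def test_bonferroni_family(self):
        rep = cc.correlate(np.arange(20.0), np.arange(20.0) ** 2, fwe_n=5)
        assert rep.p_corrected == pytest.approx(min(1.0, 5 * rep.p))


class TestCohensD:
    def test_hand_computed_example(self):
        assert cc.cohens_d([0, 2], [1, 3]) == pytest.approx(-1 / np.sqrt(2))

    def test_equal_means(self, rng):
        a = rng.normal(size=30)
        assert cc.cohens_d(a, a) == pytest.approx(0.0)

    def test_location_invariance(self, rng):
        a, b = rng.normal(size=20), rng.normal(1, 1, 25)
        assert cc.cohens_d(a + 5, b + 5) == pytest.approx(cc.cohens_d(a, b))


class TestSpecificity:
    def test_full_mask_is_degenerate(self, design_factory, rng):
        design = design_factory(15, n_groups=2)
        n_nodes = 8
        y = rng.normal(size=(30, cc.n_edges(n_nodes)))
        iu, ju = cc.edge_pairs(n_nodes)
        full = mask_of(list(zip(iu, ju)), n_nodes)
        rep = cc.edge_specificity_test(y, design, full, n_draws=50, seed=0)
        draws = rep.extra["draw_p_values"]
        assert np.allclose(draws, rep.p, atol=1e-12)

    def test_effect_confined_to_mask_is_specific(self, design_factory, rng):
        design = design_factory(20, n_groups=2)
        n_nodes = 20
        y = rng.normal(size=(40, cc.n_edges(n_nodes)))
        m = mask_of([(0, 1), (0, 2), (1, 2), (3, 4), (4, 5)], n_nodes)
        y[:, m.edge_indices()] += design.group_codes()[:, None] * 1.5
        rep = cc.edge_specificity_test(y, design, m, n_draws=200, seed=1)
        assert rep.extra["rank_among_draws"] <= 2
        assert rep.extra["observed_survives_bonferroni"]

    def test_reproducible_given_seed(self, design_factory, rng):
        design = design_factory(10, n_groups=2)
        y = rng.normal(size=(20, cc.n_edges(10)))
        m = mask_of([(0, 1), (2, 3)], 10)
        r1 = cc.edge_specificity_test(y, design, m, n_draws=100, seed=9)
        r2 = cc.edge_specificity_test(y, design, m, n_draws=100, seed=9)
        assert np.array_equal(r1.extra["draw_p_values"], r2.extra["draw_p_values"])


class TestROC:
    def test_perfect_separation(self):
        rep = cc.roc_transfer([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1],
                              n_permutations=200, seed=0)
        assert rep.value == pytest.approx(1.0)

    def test_pair_counting_example(self):
        rep = cc.roc_transfer([0.9, 0.8, 0.85, 0.1], [1, 1, 0, 0],
                              n_permutations=100, seed=0)
        assert rep.value == pytest.approx(0.75)

    def test_ties_contribute_half(self):
        rep = cc.roc_transfer([1.0, 1.0], [1, 0], n_permutations=100, seed=0)
        assert rep.value == pytest.approx(0.5)

    def test_matches_mannwhitney_auc(self, rng):
        scores = rng.normal(size=50)
        labels = rng.random(50) < 0.4
        if labels.all() or not labels.any():
            labels[:2] = [True, False]
        rep = cc.roc_transfer(scores, labels, n_permutations=100, seed=0)
        u = stats.mannwhitneyu(scores[labels], scores[~labels]).statistic
        assert rep.value == pytest.approx(u / (labels.sum() * (~labels).sum()))

    def test_null_auc_near_half_and_p_not_tiny(self, rng):
        scores = rng.normal(size=400)
        labels = np.arange(400) < 200
        rep = cc.roc_transfer(scores, labels, n_permutations=500, seed=4)
        assert abs(rep.value - 0.5) < 0.1
        assert rep.p > 0.01

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError, match="both classes"):
            cc.roc_transfer([1, 2, 3], [1, 1, 1], n_permutations=100)


class TestPairwisePosthoc:
    def test_two_groups_single_uncorrected_test(self, design_factory, rng):
        design = design_factory(10, n_groups=2)
        y = rng.normal(size=20)
        reports = cc.pairwise_posthoc(y, design)
        assert len(reports) == 1
        assert reports[0].p_corrected == pytest.approx(reports[0].p)

    def test_four_groups_six_comparisons(self, design_factory, rng):
        design = design_factory(8, n_groups=4)
        y = rng.normal(size=32)
        reports = cc.pairwise_posthoc(y, design)
        assert len(reports) == 6
        for r in reports:
            assert r.p_corrected == pytest.approx(min(1.0, 6 * r.p))

    def test_matches_two_sample_t_without_covariates(self, design_factory, rng):
        design = design_factory(12, n_groups=2)
        y = rng.normal(size=24)
        rep = cc.pairwise_posthoc(y, design)[0]
        t, p = stats.ttest_ind(y[12:], y[:12])
        assert rep.value == pytest.approx(t, rel=1e-10)
        assert rep.p == pytest.approx(p, rel=1e-10)

    def test_driven_by_one_group(self, design_factory, rng):
        design = design_factory(20, n_groups=3)
        y = rng.normal(size=60)
        y[40:] += 2.0  # only the last group departs
        reports = cc.pairwise_posthoc(y, design)
        by_pair = {r.groups: r for r in reports}
        assert by_pair[("g0", "g2")].p_corrected < 0.01
        assert by_pair[("g0", "g1")].p_corrected > 0.1
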