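"""Edge-wise GLM, suprathreshold components, and the permutation NBS."""

import numpy as np
import pytest
from scipy import stats

import crossconn as cc
from crossconn.exceptions import ParameterError
from crossconn.nbs import threshold_and_components


def oneway_anova_f(y, codes):
    """Textbook one-way ANOVA F (closed form)."""
    groups = [y[codes == g] for g in np.unique(codes)]
    grand = y.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = len(groups) - 1
    df2 = len(y) - len(groups)
    return (ssb / df1) / (ssw / df2)


def bfs_components(edges, n_nodes):
    """Independent BFS oracle: frozenset of frozensets of edges."""
    adj = {}
    for i, j in edges:
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)
    seen, comps = set(), []
    for start in adj:
        if start in seen:
            continue
        queue, nodes = [start], {start}
        seen.add(start)
        while queue:
            u = queue.pop()
            for v in adj[u]:
                if v not in nodes:
                    nodes.add(v)
                    seen.add(v)
                    queue.append(v)
        comps.append(frozenset((min(i, j), max(i, j)) for i, j in edges
                               if i in nodes and j in nodes))
    return frozenset(comps)


class TestEdgewiseGLM:
    def test_identical_groups_give_zero_f(self, design_factory):
        design = design_factory(6, n_groups=3)
        y = np.tile(np.linspace(0, 1, 18)[:, None] * 0 + 0.4, (1, 5))
        f, p = cc.edgewise_glm(y, design)
        assert np.allclose(f, 0.0)
        assert np.allclose(p, 1.0)

    def test_matches_closed_form_anova(self, design_factory, rng):
        design = design_factory(12, n_groups=2)
        y = rng.normal(size=(24, 40))
        f, _ = cc.edgewise_glm(y, design)
        codes = design.group_codes()
        oracle = np.array([oneway_anova_f(y[:, e], codes) for e in range(40)])
        assert np.allclose(f, oracle, atol=1e-10)

    def test_matches_statsmodels_ancova(self, design_factory, rng):
        sm = pytest.importorskip("statsmodels.api")
        design = design_factory(15, n_groups=3, covariates="mixed", seed=3)
        y = rng.normal(size=(45, 6)) + design.group_codes()[:, None] * 0.4
        f, p = cc.edgewise_glm(y, design)
        import pandas as pd

        df = design.covariates.copy()
        df["group"] = design.group
        from statsmodels.formula.api import ols

        for e in range(6):
            df["y"] = y[:, e]
            full = ols("y ~ age + C(sex) + C(site) + C(group)", df).fit()
            red = ols("y ~ age + C(sex) + C(site)", df).fit()
            fo = (red.ssr - full.ssr) / 2 / (full.ssr / full.df_resid)
            assert f[e] == pytest.approx(fo, rel=1e-8)
            assert p[e] == pytest.approx(stats.f.sf(fo, 2, full.df_resid), rel=1e-8)

    def test_confound_mediated_difference_is_adjusted_away(self, design_factory, rng):
        import pandas as pd

        codes = np.repeat([0, 1], 20)
        confound = codes * 1.0 + rng.normal(0, 0.1, 40)
        design = cc.CohortDesign(
            subject_ids=[f"s{i}" for i in range(40)],
            group=np.array(["a", "b"])[codes],
            group_levels=("a", "b"),
            covariates=pd.DataFrame({"conf": confound}),
        )
        y = confound[:, None] * np.ones((1, 3))  # group difference fully mediated
        f, _ = cc.edgewise_glm(y, design)
        assert np.all(f < 1e-16)

    def test_rank_deficient_design_reported(self, design_factory, rng):
        import pandas as pd

        design = design_factory(6, n_groups=2)
        design.covariates = pd.DataFrame(
            {"a": np.arange(12.0), "b": 2 * np.arange(12.0)}
        )
        with pytest.raises(ParameterError, match="collinear"):
            cc.edgewise_glm(rng.normal(size=(12, 4)), design)


class TestComponents:
    def test_explicit_partition(self):
        n = 6
        f = np.zeros(cc.n_edges(n))
        for i, j in [(1, 2), (2, 3), (4, 5)]:
            f[cc.edge_index(np.array([i]), np.array([j]), n)[0]] = 10.0
        comps = threshold_and_components(f, 5.0, n)
        assert sorted(c.size for c in comps) == [1, 2]
        assert comps[0].size == 2  # largest first

    def test_empty_suprathreshold_set(self):
        assert threshold_and_components(np.zeros(cc.n_edges(8)), 1.0, 8) == []

    def test_matches_bfs_oracle_on_random_graphs(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 50))
            e = cc.n_edges(n)
            f = (rng.random(e) < 0.05).astype(float) * 10
            comps = threshold_and_components(f, 5.0, n)
            iu, ju = cc.edge_pairs(n)
            supra = np.flatnonzero(f > 5.0)
            oracle = bfs_components(list(zip(iu[supra], ju[supra])), n)
            ours = frozenset(
                frozenset(map(tuple, c.edges)) for c in comps
            )
            assert ours == oracle


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(7)
    n_nodes, n = 30, 60
    e = cc.n_edges(n_nodes)
    mask = cc.plant_connected_network(n_nodes, 12, seed=3)
    y = rng.normal(size=(n, e))
    codes = np.repeat([0, 1], 30)
    y[:, mask.edge_indices()] += codes[:, None] * 1.2
    design = cc.CohortDesign(
        subject_ids=[f"s{i}" for i in range(n)],
        group=np.array(["ctrl", "case"])[codes],
        group_levels=("ctrl", "case"),
    )
    return y, design, mask


class TestNBSTest:
    def test_recovers_planted_component(self, planted):
        y, design, mask = planted
        res = cc.nbs_test(y, design, n_permutations=300, seed=5)
        assert res.min_fwe_p <= 0.05
        assert res.winning_mask.jaccard(mask) >= 0.5

    def test_deterministic_given_seed(self, planted):
        y, design, _ = planted
        r1 = cc.nbs_test(y, design, n_permutations=200, seed=11)
        r2 = cc.nbs_test(y, design, n_permutations=200, seed=11)
        assert np.array_equal(r1.null_max_stats, r2.null_max_stats)
        assert np.array_equal(r1.fwe_p, r2.fwe_p)
        assert np.array_equal(r1.winning_mask.edges, r2.winning_mask.edges)

    def test_subject_reordering_leaves_observed_outputs_unchanged(self, planted, rng):
        y, design, _ = planted
        perm = rng.permutation(len(design.subject_ids))
        design2 = cc.CohortDesign(
            subject_ids=[design.subject_ids[i] for i in perm],
            group=design.group[perm],
            group_levels=design.group_levels,
        )
        r1 = cc.nbs_test(y, design, n_permutations=150, seed=1)
        r2 = cc.nbs_test(y[perm], design2, n_permutations=150, seed=1)
        assert np.allclose(r1.f_stats, r2.f_stats)
        assert np.array_equal(r1.winning_mask.edges, r2.winning_mask.edges)

    def test_fwe_p_definition_and_monotonicity(self, planted):
        y, design, _ = planted
        res = cc.nbs_test(y, design, n_permutations=200, seed=2)
        for s, p in zip(res.component_stats, res.fwe_p):
            manual = (1 + np.sum(res.null_max_stats >= s)) / 201
            assert p == pytest.approx(manual)
        order = np.argsort(res.component_stats)[::-1]
        assert np.all(np.diff(res.fwe_p[order]) >= 0)

    def test_all_null_observed_gives_empty_valid_result(self, rng):
        y = rng.normal(size=(40, cc.n_edges(20)))
        design = cc.CohortDesign(
            subject_ids=[f"s{i}" for i in range(40)],
            group=np.repeat(["a", "b"], 20),
            group_levels=("a", "b"),
        )
        res = cc.nbs_test(y, design, primary_threshold_p=1e-6, n_permutations=100, seed=0)
        assert res.components == []
        assert res.winning_mask.size == 0
        assert np.isnan(res.min_fwe_p)

    def test_intensity_statistic(self, planted):
        y, design, _ = planted
        res = cc.nbs_test(y, design, n_permutations=100, seed=3, statistic="intensity")
        top = res.components[0]
        expected = float(np.sum(res.f_stats[top.edge_indices()] - res.f_critical))
        assert res.component_stats.max() == pytest.approx(expected)

    def test_parameter_validation(self, planted):
        y, design, _ = planted
        with pytest.raises(ParameterError):
            cc.nbs_test(y, design, n_permutations=50)
        with pytest.raises(ParameterError):
            cc.nbs_test(y, design, primary_threshold_p=1.5, n_permutations=100)
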