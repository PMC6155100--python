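"""Cohort generator: planted networks, reproducibility, degenerate modes, phenotypes."""

import dataclasses

import numpy as np
import pytest

import crossconn as cc
from crossconn.exceptions import ParameterError


class TestPlantNetwork:
    def test_exhaustive_three_nodes(self):
        for seed in range(5):
            m = cc.plant_network(3, 3, seed=seed)
            assert set(map(tuple, m.edges)) == {(0, 1), (0, 2), (1, 2)}

    def test_deterministic_given_seed(self):
        a = cc.plant_network(270, 84, seed=7)
        b = cc.plant_network(270, 84, seed=7)
        assert np.array_equal(a.edges, b.edges)

    def test_uniform_inclusion_frequency(self):
        # each of the 190 edges should be included ~ 50/190 of the time
        n, m, reps = 20, 50, 10_000
        counts = np.zeros(cc.n_edges(n))
        for seed in range(reps):
            counts[cc.plant_network(n, m, seed=seed).edge_indices()] += 1
        p = m / cc.n_edges(n)
        sd = np.sqrt(reps * p * (1 - p))
        assert np.all(np.abs(counts - reps * p) < 4 * sd)

    def test_too_many_edges_rejected(self):
        with pytest.raises(ParameterError):
            cc.plant_network(5, 11, seed=0)


class TestPlantConnectedNetwork:
    def test_single_connected_component(self):
        from crossconn.nbs import threshold_and_components

        for seed in range(10):
            m = cc.plant_connected_network(60, 30, seed=seed)
            assert m.size == 30
            f = np.zeros(cc.n_edges(60))
            f[m.edge_indices()] = 1.0
            comps = threshold_and_components(f, 0.5, 60)
            assert len(comps) == 1

    def test_small_counts(self):
        m = cc.plant_connected_network(10, 1, seed=0)
        assert m.size == 1


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(group_sizes=(1, 5)),
            dict(planted_edge_count=10_000),
            dict(shared_variance_fraction=1.4),
            dict(effect_sizes=(0.5, 0.2, 0.1)),  # decreasing while graded
            dict(effect_sizes=(0.0, 1.0)),  # wrong length for 3 groups
            dict(paradigm_dropout=1.0),
            dict(planted_topology="ring"),
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ParameterError):
            cc.SynthConfig(**kw)


def small_cfg(**kw):
    base = dict(
        n_nodes=20,
        group_sizes=(8, 8),
        effect_sizes=(0.0, 0.8),
        planted_edge_count=8,
        timepoints_per_paradigm=80,
        n_nuisance=4,
        seed=5,
    )
    base.update(kw)
    return cc.SynthConfig(**base)


class TestGenerateCohort:
    def test_bit_identical_given_seed(self):
        a = cc.generate_cohort(small_cfg())
        b = cc.generate_cohort(small_cfg())
        for key in a.scans:
            assert np.array_equal(a.scans[key].data, b.scans[key].data)
        assert np.array_equal(a.truth.edges, b.truth.edges)
        assert a.phenotypes.table.equals(b.phenotypes.table)

    def test_different_seed_differs(self):
        a = cc.generate_cohort(small_cfg())
        b = cc.generate_cohort(small_cfg(seed=6))
        key = list(a.scans)[0]
        assert not np.array_equal(a.scans[key].data, b.scans[key].data)

    def test_degenerate_replicates_identical_across_paradigms(self):
        cfg = small_cfg(
            shared_variance_fraction=1.0,
            noise_sd=0.0,
            paradigm_classes=("task", "task", "task"),
        )
        cohort = cc.generate_cohort(cfg)
        ct = cc.compute_cohort_traits(cohort)
        for sid in cohort.subject_ids[:3]:
            mats = [ct.paradigm_edges[p][cohort.subject_ids.index(sid)]
                    for p in cohort.paradigm_ids]
            assert np.allclose(mats[0], mats[1], atol=1e-12)
            assert np.allclose(mats[0], mats[2], atol=1e-12)

    def test_dropout_keeps_at_least_two_paradigms(self):
        cfg = small_cfg(paradigm_dropout=0.6, n_paradigms=4,
                        paradigm_classes=("rest", "task", "task", "task"),
                        timepoints_per_paradigm=(80, 80, 80, 80))
        cohort = cc.generate_cohort(cfg)
        lens = [len(cohort.subject_paradigms(s)) for s in cohort.subject_ids]
        assert min(lens) >= 2
        assert min(lens) < 4  # dropout actually happened somewhere

    def test_phenotype_schema(self):
        cohort = cc.generate_cohort(small_cfg())
        t = cohort.phenotypes.table
        months = t["months_to_conversion"]
        codes = cohort.design.group_codes()
        assert np.all(np.isfinite(months[codes == 1]))
        assert np.all(months[codes == 1] > 0)
        assert months[codes == 0].isna().all()
        conv = codes == 1
        assert np.all(t["follow_up_months"][conv] >= months[conv])

    def test_covariate_columns_present(self):
        cohort = cc.generate_cohort(small_cfg())
        assert list(cohort.design.covariates.columns) == [
            "age", "sex", "iq", "site", "mean_fd", "dose",
        ]
        assert (cohort.design.covariates["dose"][cohort.design.group_codes() == 0] == 0).all()

    def test_null_effect_group_difference_small(self):
        # with zero effects the groups differ only by sampling noise
        ds = []
        for seed in range(30):
            cfg = small_cfg(effect_sizes=(0.0, 0.0), seed=200 + seed)
            cohort = cc.generate_cohort(cfg)
            ct = cc.compute_cohort_traits(cohort)
            raw = np.nanmean(
                [cc.network_mean(ct.paradigm_edges[p], cohort.truth)
                 for p in cohort.paradigm_ids], axis=0)
            codes = cohort.design.group_codes()
            ds.append(cc.cohens_d(raw[codes == 1], raw[codes == 0]))
        assert abs(np.mean(ds)) < 0.2

    def test_variance_explained_monotone_in_shared_fraction(self):
        ves = []
        for s in (0.15, 0.3, 0.45):
            cfg = small_cfg(shared_variance_fraction=s, seed=9)
            ct = cc.compute_cohort_traits(cc.generate_cohort(cfg))
            ves.append(np.mean([t.variance_explained[0] for t in ct.traits]))
        assert ves[0] < ves[1] < ves[2]

    def test_observation_noise_changes_series(self):
        a = cc.generate_cohort(small_cfg(noise_sd=0.5))
        b = cc.generate_cohort(small_cfg(noise_sd=0.0))
        key = list(a.scans)[0]
        assert not np.array_equal(a.scans[key].data, b.scans[key].data)

    def test_degenerate_covariance_raises_construction_error(self):
        from crossconn.exceptions import ConstructionError

        # absurd planted-edge spread cannot be realized as a correlation matrix
        with pytest.raises(ConstructionError, match="non-positive-semi-definite"):
            cc.generate_cohort(small_cfg(network_strength_sd=4.0, planted_edge_count=20))

    def test_architecture_seed_shares_truth_only(self):
        a = cc.generate_cohort(small_cfg(seed=11, architecture_seed=42))
        b = cc.generate_cohort(small_cfg(seed=12, architecture_seed=42))
        assert np.array_equal(a.truth.edges, b.truth.edges)
        key = list(a.scans)[0]
        assert not np.array_equal(a.scans[key].data, b.scans[key].data)
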