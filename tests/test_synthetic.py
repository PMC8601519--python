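"""Synthetic generators: determinism, sign laws, frustration injection."""

import numpy as np
import pytest

from frustnet import (
    STAGES,
    SyntheticCohortSpec,
    binarize_signs,
    census_bruteforce,
    compare_features,
    compute_feature_table,
    flip_edges,
    frustration,
    generate_balanced_network,
    generate_factor_timeseries,
    generate_staged_cohort,
    negative_link_density,
    pearson_connectivity,
)
import pandas as pd


def small_ts_spec(**kw):
    defaults = dict(
        n_subjects_per_stage={"child": 2},
        n_regions=12,
        n_timepoints=80,
        generator_kind="factor_timeseries",
        neg_density_by_stage={"child": 0.3},
        noise_sd=0.5,
        seed=42,
    )
    defaults.update(kw)
    return SyntheticCohortSpec(**defaults)


class TestFactorTimeseries:
    def test_deterministic_for_fixed_seed(self):
        a = generate_factor_timeseries(small_ts_spec())
        b = generate_factor_timeseries(small_ts_spec())
        for (ts_a, gt_a), (ts_b, gt_b) in zip(a, b):
            assert np.array_equal(ts_a.values, ts_b.values)
            assert gt_a == gt_b

    def test_all_positive_loadings_give_near_zero_negative_density(self):
        rates = []
        for seed in range(20):
            spec = small_ts_spec(
                neg_density_by_stage={"child": 0.0}, noise_sd=0.2, seed=seed
            )
            for ts, _ in generate_factor_timeseries(spec):
                net = binarize_signs(pearson_connectivity(ts))
                rates.append(negative_link_density(net))
        assert np.mean(rates) < 0.05

    def test_sign_law_in_low_noise_limit(self):
        """With noise_sd -> 0 the correlation sign equals the loading-sign product."""
        spec = small_ts_spec(noise_sd=1e-6, n_regions=20, seed=5)
        for ts, truth in generate_factor_timeseries(spec):
            net = binarize_signs(pearson_connectivity(ts))
            assert negative_link_density(net) == pytest.approx(truth.true_neg_density)
            # every pair with opposite loading signs is anticorrelated
            r = pearson_connectivity(ts).r
            iu = np.triu_indices(20, k=1)
            assert np.all(np.abs(r[iu]) > 0.99)

    def test_matrix_dimensions(self):
        out = generate_factor_timeseries(small_ts_spec(n_regions=9, n_timepoints=33))
        assert all(ts.values.shape == (9, 33) for ts, _ in out)

    def test_invalid_noise_rejected(self):
        with pytest.raises(ValueError):
            small_ts_spec(noise_sd=0.0)


class TestBalancedNetwork:
    def test_two_faction_census_by_enumeration(self):
        net = generate_balanced_network(3, (2, 1))
        census = census_bruteforce(net)
        assert census.n_pnn == 1 and census.n_ppp == 0 and census.n_frustrated == 0

    def test_single_faction_is_all_positive_complete(self):
        census = census_bruteforce(generate_balanced_network(4, (4, 0)))
        assert census.n_ppp == 4
        assert census.n_ppn == census.n_pnn == census.n_nnn == 0

    def test_inconsistent_faction_sizes_rejected(self):
        with pytest.raises(ValueError):
            generate_balanced_network(5, (3, 3))


class TestFlipEdges:
    @pytest.mark.parametrize("n", range(5, 13))
    def test_single_flip_creates_n_minus_two_frustrations(self, n):
        net = generate_balanced_network(n, (n - 2, 2))
        flipped, pairs = flip_edges(net, 1, seed=n)
        assert len(pairs) == 1
        assert census_bruteforce(flipped).n_frustrated == n - 2

    def test_zero_flips_is_identity(self):
        net = generate_balanced_network(6, (3, 3))
        flipped, pairs = flip_edges(net, 0, seed=0)
        assert pairs == []
        assert np.array_equal(flipped.adjacency, net.adjacency)

    def test_double_flip_is_involution(self):
        net = generate_balanced_network(7, (4, 3))
        once, _ = flip_edges(net, 1, seed=3)
        twice, _ = flip_edges(once, 1, seed=3)  # same seed -> same edge
        assert np.array_equal(twice.adjacency, net.adjacency)
        assert frustration(twice) == 0

    def test_well_separated_flips_add_frustrations(self):
        """k flips on disjoint node pairs of a balanced K_n give k*(n-2)."""
        for n in (8, 10, 12):
            net = generate_balanced_network(n, (n, 0))
            a = net.adjacency.copy()
            for i, j in [(0, 1), (2, 3), (4, 5)]:
                a[i, j] = a[j, i] = -1
            from frustnet import SignedNetwork

            assert census_bruteforce(SignedNetwork(a)).n_frustrated == 3 * (n - 2)

    def test_flip_count_bounds(self):
        net = generate_balanced_network(5, (5, 0))
        with pytest.raises(ValueError):
            flip_edges(net, 11, seed=0)
        with pytest.raises(ValueError):
            flip_edges(net, -1, seed=0)


class TestStagedCohort:
    def spec(self, **kw):
        defaults = dict(
            n_subjects_per_stage={s: 4 for s in STAGES},
            n_regions=25,
            seed=7,
        )
        defaults.update(kw)
        return SyntheticCohortSpec(**defaults)

    def test_deterministic_for_fixed_seed(self):
        a, _ = generate_staged_cohort(self.spec())
        b, _ = generate_staged_cohort(self.spec())
        for sa, sb in zip(a, b):
            assert sa.subject_id == sb.subject_id
            assert np.array_equal(sa.network.adjacency, sb.network.adjacency)
            assert sa.truth == sb.truth

    def test_stage_and_sex_labels_attached(self):
        subjects, truths = generate_staged_cohort(self.spec())
        assert len(subjects) == 20
        assert {s.stage for s in subjects} == set(STAGES)
        assert {s.sex for s in subjects} <= {"male", "female"}
        for t in truths:
            assert t.constructed_frustration <= 25 * 24 * 23 // 6

    def test_expected_density_follows_stage_profile(self):
        spec = self.spec(
            n_subjects_per_stage={"child": 40, "early_adult": 40},
            neg_density_by_stage={"child": 0.3, "early_adult": 0.1},
            n_regions=30,
        )
        subjects, _ = generate_staged_cohort(spec)
        by_stage = {}
        for s in subjects:
            by_stage.setdefault(s.stage, []).append(negative_link_density(s.network))
        assert np.mean(by_stage["child"]) == pytest.approx(0.3, abs=0.03)
        assert np.mean(by_stage["early_adult"]) == pytest.approx(0.1, abs=0.03)

    def test_single_stage_table_refused_by_comparisons(self):
        spec = self.spec(n_subjects_per_stage={"child": 6})
        subjects, _ = generate_staged_cohort(spec)
        meta = pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in subjects],
                "age": [s.age for s in subjects],
                "sex": [s.sex for s in subjects],
                "stage": [s.stage for s in subjects],
            }
        )
        table = compute_feature_table({s.subject_id: s.network for s in subjects}, meta)
        assert set(table["stage"]) == {"child"}
        with pytest.raises(ValueError, match="at least 2 stages"):
            compare_features(table)

    def test_empty_stage_rejected(self):
        with pytest.raises(ValueError):
            self.spec(n_subjects_per_stage={"child": 0})
        with pytest.raises(ValueError):
            self.spec(n_subjects_per_stage={})
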