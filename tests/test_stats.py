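"""Stage binning and the nonparametric comparison / model-selection layer."""

import numpy as np
import pandas as pd
import pytest

from frustnet import (
    assign_stage,
    dunn_posthoc,
    fit_poly_select,
    interaction_test,
    kruskal_wallis,
    mann_whitney,
    normality_gate,
)
from frustnet.stats import bh_adjust


class TestStageAssignment:
    @pytest.mark.parametrize(
        "age, stage",
        [
            (9.7, "child"),
            (6, "child"),
            (11.99, "child"),
            (12, "adolescent"),  # boundary goes to the older stage
            (14.8, "adolescent"),
            (18, "early_adult"),
            (25.04, "early_adult"),
            (40, "middle_adult"),
            (54.06, "middle_adult"),
            (65, "late_adult"),
            (71.3, "late_adult"),
        ],
    )
    def test_erikson_bins(self, age, stage):
        assert assign_stage(age) == stage

    def test_below_study_range_rejected(self):
        with pytest.raises(ValueError):
            assign_stage(5.2)


class TestNormalityGate:
    def test_skewed_group_routes_nonparametric(self, rng):
        groups = {
            "a": rng.standard_normal(50),
            "b": rng.standard_normal(50),
            "c": rng.exponential(1.0, 200) ** 2,
        }
        res = normality_gate(groups)
        assert res.nonparametric
        assert res.p_by_group["c"] <= 0.05

    def test_all_normal_groups_stay_parametric(self, rng):
        decisions = []
        for _ in range(20):
            groups = {k: rng.standard_normal(50) for k in "abc"}
            decisions.append(normality_gate(groups).nonparametric)
        # nominal joint type-I rate is 1 - 0.95^3 ~ 14%
        assert np.mean(decisions) < 0.5

    def test_constant_group_flagged_degenerate(self, rng):
        res = normality_gate({"a": [3.0, 3.0, 3.0, 3.0], "b": rng.standard_normal(10)})
        assert "a" in res.degenerate_groups
        assert res.p_by_group["a"] == 0.0 and res.nonparametric

    def test_tiny_group_rejected(self, rng):
        with pytest.raises(ValueError):
            normality_gate({"a": [1.0, 2.0]})


class TestKruskalWallis:
    def test_hand_ranked_three_group_example(self):
        res = kruskal_wallis({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
        assert res.statistic == pytest.approx(7.2)
        assert res.df == 2
        assert res.group_sizes == (3, 3, 3)

    def test_rank_invariance_under_monotone_transform(self, rng):
        groups = {k: rng.gamma(2.0, size=15) for k in "abcd"}
        h1 = kruskal_wallis(groups).statistic
        h2 = kruskal_wallis({k: np.exp(v) for k, v in groups.items()}).statistic
        assert h1 == pytest.approx(h2)

    def test_all_constant_is_degenerate_zero(self):
        res = kruskal_wallis({"a": [5.0, 5.0], "b": [5.0, 5.0, 5.0]})
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis({"a": [1.0], "b": []})


class TestDunnBH:
    def test_bh_step_up_hand_example(self):
        adjusted = bh_adjust([0.01, 0.02, 0.03, 0.04, 0.05, 0.2])
        assert np.allclose(adjusted, [0.06, 0.06, 0.06, 0.06, 0.06, 0.2])

    def test_bh_monotone_in_raw_p(self, rng):
        raw = rng.uniform(size=25)
        adj = bh_adjust(raw)
        order = np.argsort(raw)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_separated_groups_all_pairs_significant(self):
        groups = {
            "a": np.arange(10.0),
            "b": np.arange(100.0, 110.0),
            "c": np.arange(200.0, 210.0),
        }
        table = dunn_posthoc(groups)
        assert len(table) == 3
        assert table["significant"].all()

    def test_identical_pair_rarely_flagged(self, rng):
        flags = []
        for _ in range(40):
            common = rng.standard_normal(20)
            groups = {
                "a": common,
                "b": rng.permutation(common),
                "c": common + 50.0,
            }
            t = dunn_posthoc(groups).set_index(["group_a", "group_b"])
            flags.append(bool(t.loc[("a", "b"), "significant"]))
        assert np.mean(flags) <= 0.1

    def test_two_groups_rejected(self, rng):
        with pytest.raises(ValueError):
            dunn_posthoc({"a": rng.standard_normal(5), "b": rng.standard_normal(5)})


class TestMannWhitney:
    def test_hand_enumerated_u(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.extra["u_a"] == 0.0
        assert res.extra["u_b"] == 9.0

    def test_identical_samples_full_ties(self):
        values = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = mann_whitney(values, values)
        assert res.statistic == pytest.approx(len(values) ** 2 / 2)
        assert res.pvalue == pytest.approx(1.0)

    def test_power_at_one_sd_shift(self, rng):
        rejections = [
            mann_whitney(rng.standard_normal(100), rng.standard_normal(100) + 1.0).pvalue
            <= 0.05
            for _ in range(100)
        ]
        assert np.mean(rejections) >= 0.9

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestPolySelection:
    def test_noiseless_quadratic_recovered_exactly(self):
        x = np.linspace(0.0, 1.0, 60)
        sel = fit_poly_select(x, 2 * x**2 + 3 * x + 1)
        assert sel.selected_degree == 2
        assert sel.rss[2] == pytest.approx(0.0, abs=1e-18)
        assert np.allclose(sel.coefficients[2], [1.0, 3.0, 2.0])
        f_quad, _ = sel.f_tests[(1, 2)]
        assert f_quad > 1e6

    def test_coefficients_within_two_se_on_noisy_quadratic(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, 200)
        y = 1.0 + 3.0 * x + 2.0 * x**2 + rng.normal(0, 0.3, 200)
        sel = fit_poly_select(x, y)
        truth = np.array([1.0, 3.0, 2.0])
        assert np.all(np.abs(sel.coefficients[2] - truth) <= 2 * sel.coefficient_se[2])

    def test_linear_data_rarely_selects_higher_degree(self):
        rng = np.random.default_rng(10)
        picks = []
        for _ in range(40)[:]:
            x = rng.uniform(0, 1, 80)
            y = 2.0 + 5.0 * x + rng.normal(0, 0.5, 80)
            picks.append(fit_poly_select(x, y).selected_degree)
        assert np.mean(np.array(picks) == 1) >= 0.8

    def test_rss_non_increasing_in_degree(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, 50)
        y = rng.normal(size=50)
        sel = fit_poly_select(x, y)
        assert sel.rss[1] >= sel.rss[2] >= sel.rss[3]
        assert all(f >= 0 for f, _ in sel.f_tests.values())

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            fit_poly_select(np.ones(30), np.arange(30.0))


class TestInteraction:
    @staticmethod
    def cohort(rng, stage_coeffs):
        rows = []
        for stage, (a, b, c) in stage_coeffs.items():
            x = rng.uniform(0.05, 0.25, 40)
            y = a + b * x + c * x**2 + rng.normal(0, 0.05, 40)
            for xi, yi in zip(x, y):
                rows.append({"stage": stage, "neg_density": xi, "frustration": yi})
        return pd.DataFrame(rows)

    def test_shared_curve_is_null(self, rng):
        pvals = [
            interaction_test(
                self.cohort(rng, {s: (1.0, 2.0, 3.0) for s in ("a", "b", "c")})
            ).pvalue
            for _ in range(20)
        ]
        assert np.mean(np.array(pvals) <= 0.05) <= 0.25

    def test_stagewise_curves_detected(self, rng):
        table = self.cohort(rng, {"a": (1, 2, 3), "b": (1, 4, -3), "c": (1, -1, 6)})
        res = interaction_test(table)
        assert res.pvalue <= 0.001

    def test_single_stage_rejected(self, rng):
        with pytest.raises(ValueError):
            interaction_test(self.cohort(rng, {"a": (1, 2, 3)}))
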