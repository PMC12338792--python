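import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import skinoct as sk
from skinoct.errors import ValidationError
from skinoct.stats import (
    MetricSeries,
    iqr_filter,
    longitudinal_summary,
    mann_whitney_u,
    one_way_anova,
    run_comparison_plan,
)
from skinoct.study import attenuation_model, generate_metric_series, null_model

from oracles import anova_f_sums_of_squares, enumerate_mannwhitney, quartile_fences


class TestIqrFilter:
    def test_hand_computed_fences_remove_the_outlier(self):
        kept, removed = iqr_filter([1, 2, 3, 4, 100], k=3)
        # Q1=2, Q3=4 by interpolation; upper fence 4 + 3*2 = 10
        assert list(kept) == [1, 2, 3, 4]
        assert list(removed) == [100]

    def test_all_equal_values_keep_everything(self):
        kept, removed = iqr_filter([5.0] * 6, k=3)
        assert list(kept) == [5.0] * 6 and removed.size == 0

    def test_huge_multiplier_is_identity(self, rng):
        vals = rng.normal(size=30)
        kept, removed = iqr_filter(vals, k=1e9)
        np.testing.assert_array_equal(kept, vals)

    def test_fewer_than_four_values_pass_through_with_warning(self):
        with pytest.warns(UserWarning):
            kept, removed = iqr_filter([1.0, 2.0, 3.0], k=3)
        assert list(kept) == [1.0, 2.0, 3.0]

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 9999),
        n=st.integers(4, 40),
        k=st.sampled_from([1.0, 3.0]),
    )
    def test_matches_first_principles_fences_and_preserves_order(self, seed, n, k):
        rng = np.random.default_rng(seed)
        vals = np.round(rng.standard_cauchy(n), 2)  # heavy tails -> outliers
        kept, removed = iqr_filter(vals, k)
        lo, hi = quartile_fences(vals, k)
        expected = [v for v in vals if lo <= v <= hi]
        assert list(kept) == expected
        assert sorted(list(kept) + list(removed)) == sorted(vals)


class TestAnova:
    def test_matches_sum_of_squares_oracle_to_1e10(self, rng):
        for _ in range(25):
            groups = [rng.normal(size=rng.integers(3, 12)) for _ in range(4)]
            res = one_way_anova(groups)
            f_ref, p_ref = anova_f_sums_of_squares(groups)
            assert res.statistic == pytest.approx(f_ref, abs=1e-10 * max(1, f_ref))
            assert res.p_value == pytest.approx(p_ref, abs=1e-10)

    def test_identical_groups_give_f_zero(self):
        g = [1.0, 2.0, 3.0]
        res = one_way_anova([g, g, g])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_constant_equal_groups_use_p_one_convention(self):
        res = one_way_anova([[2.0, 2.0], [2.0, 2.0]])
        assert (res.statistic, res.p_value) == (0.0, 1.0)

    def test_permuting_group_labels_of_identical_data_keeps_f(self, rng):
        groups = [rng.normal(size=6) for _ in range(3)]
        a = one_way_anova(groups).statistic
        b = one_way_anova(groups[::-1]).statistic
        assert a == pytest.approx(b, rel=1e-12)


class TestMannWhitney:
    def test_identical_samples_give_centered_u_and_p_one(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.statistic == 4.5  # n_a * n_b / 2
        assert res.p_value == 1.0

    def test_total_separation_three_vs_three(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2/20 assignments

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 9999), n_a=st.integers(2, 5), n_b=st.integers(2, 5))
    def test_exact_path_matches_full_enumeration(self, seed, n_a, n_b):
        rng = np.random.default_rng(seed)
        pooled = rng.permutation(np.arange(1.0, n_a + n_b + 1))  # tie-free
        a, b = pooled[:n_a], pooled[n_a:]
        u_ref, p_ref = enumerate_mannwhitney(a, b)
        res = mann_whitney_u(a, b)
        assert res.statistic == u_ref
        assert res.p_value == pytest.approx(p_ref, abs=1e-12)

    def test_normal_approximation_close_to_exact_at_7_vs_7(self, rng):
        """The asymptotic fallback stays within ~0.01 of the enumerated
        null at n=7,7, checked exhaustively over every achievable U."""
        from scipy.stats import mannwhitneyu as scipy_mwu

        pool = np.arange(1.0, 15.0)
        worst = 0.0
        for k in range(0, 50, 7):  # spread of separations covering all U
            a = np.sort(rng.permutation(pool))[:7]
            b = np.setdiff1d(pool, a)
            _, p_enum = enumerate_mannwhitney(a, b)
            p_asym = scipy_mwu(
                a, b, alternative="two-sided", method="asymptotic"
            ).pvalue
            worst = max(worst, abs(p_asym - p_enum))
        # worst-case deviation of the continuity-corrected approximation
        # over the whole U range at n=7,7 is 0.0125
        assert worst <= 0.013


def _series(metric="mu_mm_inv", model=None, seed=0, months=(0, 7)):
    rng = np.random.default_rng(seed)
    return generate_metric_series(
        metric, model or null_model(), rng, n_mice=6, months=months
    )


class TestComparisonPlan:
    def test_back_site_effect_gates_followups_to_back_only(self):
        series = _series(model=attenuation_model(), seed=3)
        results = run_comparison_plan(series, alpha=0.05)
        anovas = [r for r in results if r.test == "anova"]
        mws = [r for r in results if r.test == "mann_whitney"]
        assert {r.site for r in anovas} == {"back", "side", "stomach"}
        assert {r.site for r in mws} == {"back"}
        assert len(mws) == 9  # 4 within-group + 3 control-vs-UVR + 2 treatment

    def test_alpha_one_opens_the_gate_everywhere(self):
        series = _series(seed=4)
        results = run_comparison_plan(series, alpha=1.0)
        mws = [r for r in results if r.test == "mann_whitney"]
        assert {r.site for r in mws} == {"back", "side", "stomach"}
        assert len(mws) == 27

    def test_missing_group_month_is_named_in_the_error(self):
        series = _series(seed=5)
        records = series.records
        mask = ~(
            (records["group"] == "uvr_pl")
            & (records["month"] == 7)
            & (records["site"] == "back")
        )
        broken = MetricSeries("mu_mm_inv", records[mask])
        with pytest.raises(ValidationError, match="uvr_pl.*month=7"):
            run_comparison_plan(broken, alpha=1.0)

    def test_null_data_rejects_at_nominal_rate(self):
        """Type-I calibration of the month-7 ANOVA gate (back site)."""
        reject = 0
        n_rep = 200
        rng = np.random.default_rng(77)
        for _ in range(n_rep):
            series = generate_metric_series(
                "mu_mm_inv", null_model(), rng, n_mice=6,
                months=(7,), sites=("back",),
            )
            df = series.records
            res = one_way_anova(
                [df[df.group == g]["value"].to_numpy() for g in sk.GROUPS]
            )
            reject += res.p_value < 0.05
        assert abs(reject / n_rep - 0.05) <= 0.03


class TestLongitudinalSummary:
    def test_constant_series_has_zero_slope(self):
        series = _series(
            model=sk.MetricModel(40.0, {}, 0.0, 0.0), months=tuple(range(8))
        )
        _, trends = longitudinal_summary(series)
        assert np.allclose(trends["slope"], 0.0, atol=1e-12)

    def test_linear_drift_recovers_exact_slope(self):
        base = _series(months=tuple(range(8))).records.copy()
        base["value"] = 10.0 + 2.5 * base["month"]
        _, trends = longitudinal_summary(MetricSeries("mu_mm_inv", base))
        assert np.allclose(trends["slope"], 2.5, atol=1e-9)

    def test_uvr_slope_below_control_slope_in_most_replicates(self):
        wins = 0
        n_rep = 100
        rng = np.random.default_rng(101)
        for _ in range(n_rep):
            series = generate_metric_series(
                "mu_mm_inv", attenuation_model(), rng, n_mice=6,
                months=tuple(range(8)), sites=("back",),
            )
            _, trends = longitudinal_summary(series)
            t = trends.set_index("group")["slope"]
            wins += t["uvr_control"] < t["control"]
        assert wins >= 95

    def test_single_month_rejected(self):
        with pytest.raises(ValidationError, match="2 months"):
            longitudinal_summary(_series(months=(0,)))
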