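import numpy as np
import pytest
from hypothesis import given, strategies as st

from lingcast.cohorts_recast import BASELINE_COHORTS
from lingcast.formats_io import ValidationError
from lingcast.transmission import (
    LOG_FLOOR,
    PROJECTION_STEP_YEARS,
    XTFR_YEARS,
    classify_trend,
    compute_xtfr,
    estimate_xtfr_series,
    fit_project_paths,
    fit_trend,
    project_xtfr,
)

from .conftest import zero_mortality_schedule


def age_vector(c=0.0, w_per_group=0.0, pi_groups=(0.0, 0.0)):
    """Counts over ages 0–80: C in 0–4, seven reproductive groups 15–49."""
    counts = np.zeros(17)
    counts[0] = c
    counts[3:10] = w_per_group
    counts[5] = pi_groups[0]
    counts[6] = pi_groups[1]
    return counts


class TestXtfrFormula:
    def test_hand_evaluation(self):
        # C=100, W=1000, pi = 0.2 → (10.65 − 2.51)·0.1 = 0.814
        counts = np.zeros(17)
        counts[0] = 100
        counts[3:10] = [160, 160, 100, 100, 160, 160, 160]  # W = 1000, 25–34 = 200
        assert compute_xtfr(counts) == pytest.approx(0.814)

    def test_zero_root_at_critical_share(self):
        pi_star = 10.65 / 12.55
        counts = np.zeros(17)
        counts[0] = 500
        counts[5] = pi_star * 1000 / 2
        counts[6] = pi_star * 1000 / 2
        counts[3] = (1 - pi_star) * 1000
        assert compute_xtfr(counts) == pytest.approx(0.0, abs=1e-12)

    def test_linear_in_child_count(self):
        base = age_vector(c=50, w_per_group=100)
        doubled = base.copy()
        doubled[0] *= 2
        assert compute_xtfr(doubled) == pytest.approx(2 * compute_xtfr(base))

    def test_undefined_without_reproductive_population(self):
        with pytest.raises(ValidationError, match="15–49"):
            compute_xtfr(age_vector(c=10))

    @given(scale=st.floats(min_value=0.01, max_value=1000.0))
    def test_invariant_to_uniform_scaling(self, scale):
        counts = age_vector(c=80, w_per_group=120, pi_groups=(150, 90))
        assert compute_xtfr(counts * scale) == pytest.approx(compute_xtfr(counts))


class TestSeries:
    def test_stationary_pyramid_gives_equal_values(self):
        sched = zero_mortality_schedule()
        cohort_counts = np.full(17, 100.0)
        values = estimate_xtfr_series(cohort_counts, sched)
        assert np.allclose(values, values[0])

    def test_no_young_speakers_means_zero(self):
        # no one under 35 in 2001: C = 0, so the 2001 value is zero
        cohort_counts = np.zeros(17)
        cohort_counts[:10] = 50.0  # cohorts 1917 … 1962 → ages 35+ in 2001
        values = estimate_xtfr_series(cohort_counts, zero_mortality_schedule())
        assert values[-1] == 0.0

    def test_dormant_population_substitutes_zero_with_warning(self):
        # only the 1917–1921 cohort is populated: nobody aged 15–49 anywhere
        cohort_counts = np.zeros(17)
        cohort_counts[0] = 30.0
        with pytest.warns(UserWarning, match="substituting"):
            values = estimate_xtfr_series(cohort_counts, zero_mortality_schedule())
        assert np.all(values == 0.0)


class TestTrendClassification:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ((1.0, 0.8, 0.6, 0.4, 0.2), "decreasing"),
            ((0.2, 0.3, 0.4, 0.5, 0.6), "non-decreasing"),
            ((0.7, 0.7, 0.7, 0.7, 0.7), "non-decreasing"),
        ],
    )
    def test_slope_sign(self, values, expected):
        assert classify_trend(values) == expected

    def test_slope_matches_polyfit(self):
        values = np.array([0.9, 0.7, 0.75, 0.5, 0.45])
        slope = np.polyfit(np.array(XTFR_YEARS, float), values, 1)[0]
        assert classify_trend(values) == ("decreasing" if slope < 0 else "non-decreasing")


class TestTrendFit:
    def test_exact_exponential_recovered(self):
        a, b = -0.3, -0.02
        values = np.exp(a + b * (np.array(XTFR_YEARS) - 2001))
        model = fit_trend(values)
        assert model.form == "log-response"
        assert model.intercept == pytest.approx(a, abs=1e-9)
        assert model.slope == pytest.approx(b, abs=1e-9)
        path = model.predict([2006, 2026])
        assert path[0] == pytest.approx(np.exp(a + b * 5), abs=1e-9)

    def test_constant_series_projects_itself(self):
        for scenario in ("freeze", "unlimited"):
            model = fit_trend([0.7] * 5, scenario=scenario)
            np.testing.assert_allclose(
                project_xtfr(model), np.full(len(PROJECTION_STEP_YEARS), 0.7)
            )

    def test_increasing_series_anchored_at_mean(self):
        values = np.array([0.2, 0.3, 0.4, 0.5, 0.6])
        model = fit_trend(values, scenario="unlimited")
        assert model.form == "log-year"
        assert model.predict([2096])[0] == pytest.approx(values.mean())

    def test_all_zero_series_is_degenerate(self):
        model = fit_trend([0.0] * 5)
        assert model.form == "degenerate"
        assert np.all(project_xtfr(model) == 0.0)

    def test_freeze_constant_after_2046(self):
        model = fit_trend([1.0, 0.8, 0.6, 0.4, 0.2], scenario="freeze")
        path = dict(zip(PROJECTION_STEP_YEARS, project_xtfr(model)))
        for year in range(2051, 2097, 5):
            assert path[year] == pytest.approx(path[2046])

    def test_unlimited_decreasing_is_monotone(self):
        model = fit_trend([1.0, 0.8, 0.6, 0.4, 0.2], scenario="unlimited")
        path = project_xtfr(model)
        assert np.all(np.diff(path) < 0)

    def test_scenarios_agree_through_2046(self):
        values = [1.2, 1.0, 0.8, 0.7, 0.5]
        freeze = project_xtfr(fit_trend(values, scenario="freeze"))
        unlimited = project_xtfr(fit_trend(values, scenario="unlimited"))
        years = np.array(PROJECTION_STEP_YEARS)
        np.testing.assert_allclose(freeze[years <= 2046], unlimited[years <= 2046])

    def test_log_floor_applied_to_zeros(self):
        values = [0.2, 0.1, 0.05, 0.0, 0.0]
        model = fit_trend(values)
        z = np.log(np.clip(values, LOG_FLOOR, None))
        slope = np.polyfit(np.array(XTFR_YEARS, float) - 2001, z, 1)[0]
        assert model.slope == pytest.approx(slope, abs=1e-12)


class TestVectorisedPaths:
    def test_matches_scalar_api_on_both_branches(self, rng):
        series = np.vstack(
            [
                rng.uniform(0.05, 2.0, size=5) * np.linspace(1.5, 0.5, 5),  # decreasing-ish
                rng.uniform(0.05, 2.0, size=5) * np.linspace(0.5, 1.5, 5),  # increasing-ish
                np.zeros(5),
                np.full(5, 0.9),
            ]
        )
        for scenario in ("freeze", "unlimited"):
            batch = fit_project_paths(series, scenario=scenario)
            for i in range(series.shape[0]):
                model = fit_trend(series[i], scenario=scenario)
                np.testing.assert_allclose(
                    batch[i], project_xtfr(model), atol=1e-12, err_msg=f"row {i}"
                )


class TestRenewalThreshold:
    def test_uniform_pyramid_with_unit_xtfr_is_stationary(self):
        """A flat age pyramid with xTFR ≈ 1 renews itself (drift < 2%)."""
        counts = np.full(20, 1000.0)
        xtfr = compute_xtfr(counts[:17])
        assert xtfr == pytest.approx(1.0, abs=0.02)
        weights = np.full(7, 1.0 / 7.0)
        state = counts.copy()
        for _ in range(5):  # expectation recursion, no mortality below 100
            births = xtfr * state[3:10] @ weights
            state[1:] = state[:-1]
            state[0] = births
        drift = abs(state.sum() - counts.sum()) / counts.sum()
        assert drift < 0.02
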