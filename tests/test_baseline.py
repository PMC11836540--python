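import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from lingcast.baseline import (
    BaselineModel,
    CohortSizeDistribution,
    TotalSizeDistribution,
    allocate_integer_total,
    fit_baseline_model,
    fit_cohort_distribution,
    fit_total_distribution,
    sample_baseline,
    sample_baseline_counts,
)
from lingcast.cohorts_recast import BASELINE_COHORTS
from lingcast.formats_io import ValidationError

from .test_quality import recast_from_matrix, flat_matrix


def model_from(mu_total, tau, cohort_dists) -> BaselineModel:
    return BaselineModel(
        language="toy",
        total=TotalSizeDistribution(mu=mu_total, tau=tau, df=4),
        cohorts=dict(zip(BASELINE_COHORTS, cohort_dists)),
    )


class TestTotalFit:
    def test_constant_totals(self):
        d = fit_total_distribution([100, 100, 100, 100, 100])
        assert (d.mu, d.tau, d.df) == (100.0, 0.0, 4)

    def test_spread_totals_standard_error(self):
        d = fit_total_distribution([90, 95, 100, 105, 110])
        assert d.mu == pytest.approx(100.0)
        # sd = 7.9057, tau = sd / sqrt(5)
        assert d.tau == pytest.approx(3.5355, abs=1e-3)
        assert d.df == 4

    def test_needs_three_estimates(self):
        with pytest.raises(ValidationError):
            fit_total_distribution([100, 110])


class TestCohortFit:
    def test_dispersion_is_variance_over_mean_squared(self):
        # mean 100, sample variance 400 → phi = 0.04, reciprocal 1/phi = 25
        d = fit_cohort_distribution([80.0, 80.0, 100.0, 120.0, 120.0])
        assert d.mu == pytest.approx(100.0)
        assert d.phi == pytest.approx(0.04)
        assert 1.0 / d.phi == pytest.approx(25.0)
        assert d.family == "negative-binomial"
        assert d.variance == pytest.approx(400.0)

    def test_all_zero_is_degenerate(self):
        d = fit_cohort_distribution([0.0] * 5)
        assert d.family == "degenerate" and d.mu == 0.0

    def test_underdispersion_falls_back_to_poisson(self):
        d = fit_cohort_distribution([99.0, 100.0, 100.0, 100.0, 101.0])
        assert d.family == "poisson"
        assert d.variance == pytest.approx(d.mu)


class TestLargestRemainder:
    def test_exact_sum_and_shares(self):
        out = allocate_integer_total(np.array([1.0, 1.0, 1.0]), 10)
        assert out.sum() == 10
        assert sorted(out) == [3, 3, 4]

    @given(
        total=st.integers(min_value=0, max_value=10_000),
        weights=st.lists(
            st.floats(min_value=0.0, max_value=100.0), min_size=2, max_size=17
        ).filter(lambda w: sum(w) > 0),
    )
    def test_sum_preserved_and_near_proportional(self, total, weights):
        w = np.asarray(weights)
        out = allocate_integer_total(w, total)
        assert out.sum() == total
        exact = total * w / w.sum()
        assert np.all(np.abs(out - exact) < 1.0)


class TestSampling:
    def test_degenerate_model_is_deterministic(self, rng):
        cohorts = [
            CohortSizeDistribution(mu=0.0, phi=0.0, family="degenerate")
            for _ in range(16)
        ] + [CohortSizeDistribution(mu=100.0, phi=0.0, family="degenerate")]
        model = model_from(100.0, 0.0, cohorts)
        draw = sample_baseline(model, rng)
        assert draw.total == 100
        assert draw.cohort_counts[-1] == 100

    def test_draw_sums_to_realized_total(self, rng):
        cohorts = [
            CohortSizeDistribution(mu=50.0, phi=0.04, family="negative-binomial")
            for _ in range(17)
        ]
        model = model_from(850.0, 40.0, cohorts)
        for _ in range(50):
            draw = sample_baseline(model, rng)
            assert draw.cohort_counts.sum() == draw.total
            assert draw.cohort_counts.shape == (17,)
            assert (draw.cohort_counts >= 0).all()

    def test_age_counts_reverse_cohort_order(self, rng):
        cohorts = [
            CohortSizeDistribution(mu=float(10 + i), phi=0.0, family="degenerate")
            for i in range(17)
        ]
        model = model_from(sum(range(10, 27)), 0.0, cohorts)
        draw = sample_baseline(model, rng)
        # oldest cohort (1917–1921, mu=10) sits at ages 80–84
        assert draw.age_counts[-1] == draw.cohort_counts[0]
        assert draw.age_counts[0] == draw.cohort_counts[-1]

    def test_negative_binomial_moments(self, rng):
        """3000 draws of NB(mu=100, phi=0.04) match the target moments."""
        cohorts = [
            CohortSizeDistribution(mu=100.0, phi=0.04, family="negative-binomial")
            for _ in range(17)
        ]
        # huge total so rescaling is essentially inactive per cohort
        model = model_from(1700.0, 0.0, cohorts)
        counts, _ = sample_baseline_counts(model, rng, size=3000)
        sample_mu = counts.mean()
        # CLT bound: 3 sigma of the mean of 3000 draws with var 400
        assert abs(sample_mu - 100.0) < 3 * np.sqrt(400 / (3000 * 17)) + 1.0

    def test_totals_follow_t_distribution(self, rng):
        """KS test of sampled totals against the specified t (mu >> tau)."""
        cohorts = [
            CohortSizeDistribution(mu=10_000.0, phi=0.01, family="negative-binomial")
            for _ in range(17)
        ]
        model = model_from(170_000.0, 500.0, cohorts)
        _, totals = sample_baseline_counts(model, rng, size=3000)
        ks = stats.kstest(
            totals, stats.t(df=4, loc=170_000.0, scale=500.0).cdf
        )
        assert ks.pvalue > 0.01

    def test_zero_cohort_draws_redistributed_by_means(self, rng):
        cohorts = [
            CohortSizeDistribution(mu=0.0, phi=0.0, family="degenerate")
            for _ in range(16)
        ] + [CohortSizeDistribution(mu=5.0, phi=0.0, family="degenerate")]
        model = model_from(40.0, 0.0, cohorts)
        draw = sample_baseline(model, rng)
        # all mass goes to the only cohort with a positive mean
        assert draw.cohort_counts[-1] == 40


class TestModelFit:
    def test_17_distributions_per_language(self):
        recast = recast_from_matrix(flat_matrix(100.0))
        model = fit_baseline_model(recast, "toy")
        assert len(model.cohorts) == 17

    def test_json_round_trip(self):
        recast = recast_from_matrix(flat_matrix(100.0) * np.linspace(0.9, 1.1, 5))
        model = fit_baseline_model(recast, "toy")
        back = BaselineModel.from_json(model.to_json())
        assert back.total == model.total
        assert back.cohorts == model.cohorts
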