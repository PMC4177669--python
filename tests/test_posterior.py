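"""Posterior nutrient estimates and regime classification under readout noise."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from enzopt import (
    GaussianPrior,
    MeasurementModel,
    MixturePrior,
    PayoffSpec,
    RegimeParams,
    beta_ratio,
    classify_measurement_regime,
    noisy_optimal_strategy,
    optimal_enzyme_graded,
    perfect_strategy,
    posterior_mean_bimodal_tanh,
    posterior_mean_gaussian,
    posterior_mean_mixture,
    posterior_mean_uniform,
    posterior_variance_gaussian,
    sigma_m_for_xi,
    xi_ratio,
)
from enzopt.oracles import posterior_mean_quadrature


class TestBetaRatio:
    @pytest.mark.parametrize(
        "sigma_E, sigma_m, expected", [(1.0, 0.0, 0.0), (1.0, 1.0, 1.0), (0.1, 1.0, 100.0)]
    )
    def test_examples(self, sigma_E, sigma_m, expected):
        assert beta_ratio(
            GaussianPrior(sigma_E=sigma_E), MeasurementModel(sigma_m)
        ) == pytest.approx(expected)


class TestGaussianPosterior:
    def test_definitive_measurement_returns_readout(self):
        assert posterior_mean_gaussian(
            2.0, GaussianPrior(mu=0.0), MeasurementModel(0.0)
        ) == pytest.approx(2.0)

    def test_equal_variances_split_the_difference(self):
        assert posterior_mean_gaussian(
            2.0, GaussianPrior(mu=0.0, sigma_E=1.0), MeasurementModel(1.0)
        ) == pytest.approx(1.0)

    def test_matches_quadrature_oracle(self):
        prior = GaussianPrior(mu=0.3, sigma_E=0.8)
        meas = MeasurementModel(1.1)
        closed = posterior_mean_gaussian(1.7, prior, meas)
        assert abs(closed - posterior_mean_quadrature(1.7, prior, meas)) < 1e-8

    def test_posterior_variance(self):
        prior = GaussianPrior(sigma_E=0.8)
        meas = MeasurementModel(1.1)
        beta = beta_ratio(prior, meas)
        assert posterior_variance_gaussian(prior, meas) == pytest.approx(
            meas.sigma_m**2 / (1 + beta)
        )

    @given(
        m=st.floats(-5.0, 5.0),
        mu=st.floats(-3.0, 3.0),
        sigma_E=st.floats(0.1, 3.0),
        sigma_m=st.floats(0.0, 5.0),
    )
    def test_shrinkage_stays_between_readout_and_prior_mean(self, m, mu, sigma_E, sigma_m):
        post = posterior_mean_gaussian(
            m, GaussianPrior(mu=mu, sigma_E=sigma_E), MeasurementModel(sigma_m)
        )
        lo, hi = sorted([m, mu])
        assert lo - 1e-9 <= post <= hi + 1e-9


def test_uniform_prior_is_identity():
    for m in (0.0, 3.2, -1.0):
        assert posterior_mean_uniform(m) == m


class TestMixturePosterior:
    def test_symmetry_at_the_midpoint(self):
        prior = MixturePrior.bimodal(mu_bar=0.7, delta_mu=2.0, sigma=0.3)
        assert posterior_mean_mixture(0.7, prior, MeasurementModel(0.5)) == pytest.approx(0.7)

    def test_single_component_equals_gaussian_posterior(self):
        prior = MixturePrior(components=((1.0, 0.4, 0.9),))
        meas = MeasurementModel(0.6)
        assert posterior_mean_mixture(1.3, prior, meas) == pytest.approx(
            posterior_mean_gaussian(1.3, GaussianPrior(mu=0.4, sigma_E=0.9), meas)
        )

    def test_matches_quadrature_oracle(self):
        prior = MixturePrior.bimodal(mu_bar=0.0, delta_mu=2.0, sigma=0.2)
        meas = MeasurementModel(0.5)
        closed = posterior_mean_mixture(0.4, prior, meas)
        assert abs(closed - posterior_mean_quadrature(0.4, prior, meas)) < 1e-6

    def test_tanh_form_is_algebraically_identical(self):
        prior = MixturePrior.bimodal(mu_bar=0.5, delta_mu=3.0, sigma=0.4)
        meas = MeasurementModel(0.7)
        m = np.linspace(-4.0, 5.0, 101)
        np.testing.assert_allclose(
            posterior_mean_mixture(m, prior, meas),
            posterior_mean_bimodal_tanh(m, prior, meas),
            atol=1e-12,
        )

    def test_stable_far_into_the_tails(self):
        prior = MixturePrior.bimodal(mu_bar=0.0, delta_mu=2.0, sigma=0.1)
        meas = MeasurementModel(0.2)
        out = posterior_mean_mixture(50.0, prior, meas)
        assert np.isfinite(out)

    @given(m1=st.floats(-6.0, 6.0), m2=st.floats(-6.0, 6.0))
    def test_posterior_mean_monotone_in_readout(self, m1, m2):
        """Shrinkage never reverses the order of two readouts."""
        prior = MixturePrior(
            components=((0.3, -1.0, 0.3), (0.5, 0.5, 0.6), (0.2, 2.0, 0.2))
        )
        meas = MeasurementModel(0.8)
        lo, hi = sorted([m1, m2])
        assert posterior_mean_mixture(lo, prior, meas) <= posterior_mean_mixture(
            hi, prior, meas
        ) + 1e-9

    def test_empty_mixture_rejected(self):
        with pytest.raises(ValueError):
            MixturePrior(components=())


class TestXiRatio:
    def test_perfect_measurement_gives_zero(self):
        prior = MixturePrior.bimodal(0.0, 2.0, 0.1)
        assert xi_ratio(prior, MeasurementModel(0.0)) == 0.0

    def test_coincident_modes_give_infinity(self):
        prior = MixturePrior.bimodal(0.0, 0.0, 0.1)
        assert math.isinf(xi_ratio(prior, MeasurementModel(0.5)))

    def test_arithmetic(self):
        prior = MixturePrior.bimodal(0.0, 2.0, 0.1)
        expected = 0.25 / (2.0 * math.sqrt(0.26))
        assert xi_ratio(prior, MeasurementModel(0.5)) == pytest.approx(expected)

    def test_sigma_m_for_xi_inverts(self):
        prior = MixturePrior.bimodal(0.0, 2.0, 0.3)
        for xi in (0.01, 0.5, 7.0):
            meas = MeasurementModel(sigma_m_for_xi(prior, xi))
            assert xi_ratio(prior, meas) == pytest.approx(xi, rel=1e-10)


class TestRegimeClassifier:
    @pytest.mark.parametrize(
        "beta, label", [(1e-3, "naive"), (1.0, "bayesian"), (1e3, "constitutive")]
    )
    def test_unimodal_labels(self, beta, label):
        assert classify_measurement_regime(RegimeParams(beta=beta)) == label

    @pytest.mark.parametrize(
        "xi, label",
        [(1e-3, "classification"), (1.0, "ambiguous"), (1e3, "constitutive")],
    )
    def test_bimodal_labels(self, xi, label):
        assert classify_measurement_regime(RegimeParams(xi=xi)) == label

    def test_configurable_cut_points(self):
        assert classify_measurement_regime(RegimeParams(beta=0.5), low=0.9) == "naive"


class TestNoisyOptimalStrategy:
    def test_zero_noise_recovers_perfect_strategy(self):
        spec = PayoffSpec(alpha=2.0)
        grid = np.linspace(0.0, 3.0, 61)
        noisy = noisy_optimal_strategy(
            spec, GaussianPrior(mu=1.0), MeasurementModel(0.0), grid
        )
        np.testing.assert_allclose(noisy.levels, perfect_strategy(spec, grid).levels)

    def test_huge_noise_collapses_to_constitutive_level(self):
        spec = PayoffSpec(alpha=2.0)
        prior = GaussianPrior(mu=1.0, sigma_E=1.0)
        table = noisy_optimal_strategy(
            spec, prior, MeasurementModel(1e6), np.linspace(-3.0, 5.0, 81)
        )
        level = optimal_enzyme_graded(spec, prior.mu)
        np.testing.assert_allclose(table.levels, level, atol=1e-6)

    def test_composed_closed_form_value(self):
        # alpha=2, b=c=1, mu=1, beta=1, m=3: E[S|m] = (3+1)/2 = 2, E* = 1
        spec = PayoffSpec(alpha=2.0)
        table = noisy_optimal_strategy(
            spec, GaussianPrior(mu=1.0, sigma_E=1.0), MeasurementModel(1.0), [0.0, 3.0]
        )
        assert table(3.0) == pytest.approx(1.0)

    def test_thresholding_class_thresholds_the_posterior_mean(self):
        spec = PayoffSpec(alpha=0.5, E_max=4.0)  # S_t = 0.5
        prior = GaussianPrior(mu=1.0, sigma_E=1.0)
        meas = MeasurementModel(1.0)
        table = noisy_optimal_strategy(spec, prior, meas, np.linspace(-3.0, 5.0, 401))
        post = posterior_mean_gaussian(table.grid, prior, meas)
        np.testing.assert_allclose(table.levels, np.where(post > 0.5, 4.0, 0.0))

    def test_michaelis_menten_with_noise_is_rejected(self):
        spec = PayoffSpec(benefit_mode="michaelis_menten", alpha=2.0)
        with pytest.raises(ValueError, match="quadrature"):
            noisy_optimal_strategy(
                spec, GaussianPrior(), MeasurementModel(0.5), [0.0, 1.0]
            )

    def test_metadata_records_regime_coordinates(self):
        table = noisy_optimal_strategy(
            PayoffSpec(alpha=2.0),
            GaussianPrior(sigma_E=2.0),
            MeasurementModel(1.0),
            [0.0, 1.0],
        )
        assert table.meta["beta"] == pytest.approx(0.25)
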