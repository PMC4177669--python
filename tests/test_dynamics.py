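"""Memory-carrying posterior means in the mean-reverting environment."""

import math

import numpy as np
import pytest

from enzopt import (
    GaussianPrior,
    MarkovEnvSpec,
    MeasurementModel,
    PayoffSpec,
    StrategyTable2D,
    correlation_time,
    dynamic_optimal_strategy,
    memory_weights,
    posterior_mean_gaussian,
    posterior_mean_memory,
    posterior_mean_memory1,
    posterior_mean_memory2,
    simulate_with_readouts,
)
from enzopt.oracles import kalman_posterior_mean, optimal_enzyme_grid


class TestCorrelationTime:
    def test_geometric_decay_identity(self):
        assert correlation_time(math.exp(-1.0)) == pytest.approx(1.0)
        assert correlation_time(math.exp(-0.1)) == pytest.approx(10.0)

    def test_memoryless_convention(self):
        assert correlation_time(0.0) == 0.0

    def test_domain(self):
        for lam in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError):
                correlation_time(lam)


class TestMemoryPosterior:
    def test_perfect_measurement_returns_current_readout(self):
        env = MarkovEnvSpec(mu=0.3, sigma_E=1.2, lam=0.7)
        meas = MeasurementModel(0.0)
        assert posterior_mean_memory1(1.5, -2.0, env, meas) == pytest.approx(1.5)
        assert posterior_mean_memory2(1.5, -2.0, 0.9, env, meas) == pytest.approx(1.5)

    def test_memoryless_environment_ignores_the_past(self):
        env = MarkovEnvSpec(mu=0.5, sigma_E=1.0, lam=0.0)
        meas = MeasurementModel(0.8)
        expected = posterior_mean_gaussian(
            1.2, GaussianPrior(mu=0.5, sigma_E=1.0), meas
        )
        for m_prev in (-3.0, 0.0, 4.0):
            assert posterior_mean_memory1(1.2, m_prev, env, meas) == pytest.approx(expected)
            assert posterior_mean_memory2(1.2, m_prev, 2.0, env, meas) == pytest.approx(
                expected
            )

    def test_matches_kalman_recursion_at_reference_point(self):
        env = MarkovEnvSpec(mu=0.0, sigma_E=1.0, lam=0.9)
        meas = MeasurementModel(1.0)
        mine = posterior_mean_memory1(1.0, 2.0, env, meas)
        kalman, _ = kalman_posterior_mean([2.0, 1.0], env, meas)
        assert abs(mine - kalman) < 1e-8

    def test_matches_kalman_recursion_random_draws(self, rng):
        """Gaussian conditioning and the sequential filter agree everywhere."""
        for _ in range(100):
            env = MarkovEnvSpec(
                mu=rng.normal(0.0, 2.0),
                sigma_E=rng.uniform(0.2, 2.0),
                lam=rng.uniform(0.0, 0.99),
            )
            meas = MeasurementModel(rng.uniform(0.0, 2.0))
            m = rng.normal(env.mu, 2.0, size=3)
            got1 = posterior_mean_memory1(m[2], m[1], env, meas)
            ref1, _ = kalman_posterior_mean(m[1:], env, meas)
            got2 = posterior_mean_memory2(m[2], m[1], m[0], env, meas)
            ref2, _ = kalman_posterior_mean(m, env, meas)
            assert abs(got1 - ref1) < 1e-8
            assert abs(got2 - ref2) < 1e-8

    def test_matches_statsmodels_state_space_filter(self):
        """Independent library cross-check of the Kalman equivalence."""
        from statsmodels.tsa.statespace.kalman_filter import KalmanFilter

        env = MarkovEnvSpec(mu=0.4, sigma_E=1.1, lam=0.8)
        meas = MeasurementModel(0.7)
        obs = np.array([0.9, -0.2, 1.4])
        kf = KalmanFilter(k_endog=1, k_states=1)
        kf["design", 0, 0] = 1.0
        kf["obs_cov", 0, 0] = meas.sigma_m**2
        kf["transition", 0, 0] = env.lam
        kf["selection", 0, 0] = 1.0
        kf["state_cov", 0, 0] = env.sigma_d**2
        kf["state_intercept", 0, 0] = (1.0 - env.lam) * env.mu
        kf.initialize_known(np.array([env.mu]), np.array([[env.sigma_E**2]]))
        kf.bind(obs.reshape(-1, 1))
        filtered = kf.filter().filtered_state[0]
        got = posterior_mean_memory2(obs[2], obs[1], obs[0], env, meas)
        assert got == pytest.approx(filtered[-1], abs=1e-10)

    def test_generic_memory_extends_the_closed_forms(self):
        env = MarkovEnvSpec(mu=0.0, sigma_E=1.0, lam=0.85)
        meas = MeasurementModel(0.6)
        m = [0.5, 1.0, -0.2, 0.3]  # newest first
        ref, _ = kalman_posterior_mean(m[::-1], env, meas)
        assert posterior_mean_memory(m, env, meas) == pytest.approx(ref, abs=1e-10)

    def test_memory_weight_positive_only_with_persistence_and_noise(self):
        meas = MeasurementModel(1.0)
        w_nolam = memory_weights(MarkovEnvSpec(lam=0.0), meas, 1)
        assert w_nolam[1] == pytest.approx(0.0, abs=1e-12)
        w_nonoise = memory_weights(MarkovEnvSpec(lam=0.8), MeasurementModel(0.0), 1)
        assert w_nonoise[1] == pytest.approx(0.0, abs=1e-12)
        for lam in (0.1, 0.5, 0.9, 0.99):
            w = memory_weights(MarkovEnvSpec(lam=lam), meas, 1)
            assert w[1] > 0.0

    def test_longer_memory_never_hurts_estimation(self):
        """MSE ordering memory2 <= memory1 <= memoryless on simulated paths."""
        env = MarkovEnvSpec(mu=1.0, sigma_E=1.0, lam=0.9)
        meas = MeasurementModel(1.0)
        traj = simulate_with_readouts(env, meas, 200_000, seed=11)
        S, m = traj.S[2:], traj.m
        prior = env.stationary_prior
        e0 = posterior_mean_gaussian(m[2:], prior, meas) - S
        e1 = posterior_mean_memory1(m[2:], m[1:-1], env, meas) - S
        e2 = posterior_mean_memory2(m[2:], m[1:-1], m[:-2], env, meas) - S
        n = S.size

        def mean_se(x):
            return x.mean(), x.std(ddof=1) / math.sqrt(n)

        d10, se10 = mean_se(e1**2 - e0**2)
        d21, se21 = mean_se(e2**2 - e1**2)
        assert d10 < 3 * se10  # memory1 at least as good as memoryless
        assert d21 < 3 * se21
        assert d10 < 0  # strictly better in this persistent regime


class TestDynamicStrategy:
    def test_zero_noise_strategy_ignores_the_past(self):
        spec = PayoffSpec(alpha=2.0)
        table = dynamic_optimal_strategy(
            spec,
            MarkovEnvSpec(mu=1.0, lam=0.8),
            MeasurementModel(0.0),
            np.linspace(-2.0, 4.0, 31),
        )
        spread = table.levels.max(axis=1) - table.levels.min(axis=1)
        assert np.all(spread < 1e-12)

    def test_huge_noise_strategy_is_constitutive(self):
        spec = PayoffSpec(alpha=2.0)
        env = MarkovEnvSpec(mu=1.0, lam=0.8)
        table = dynamic_optimal_strategy(
            spec, env, MeasurementModel(1e6), np.linspace(-2.0, 4.0, 31)
        )
        np.testing.assert_allclose(table.levels, 0.5, atol=1e-6)

    def test_cells_match_expected_payoff_grid_maximization(self, rng):
        """Composed closed form equals argmax of the conditional expected payoff.

        For linear benefit the expected payoff given readouts is
        b*E*E[S|m_t, m_prev] - c*E**alpha, so grid-maximizing it per cell is
        an independent route to the same table.
        """
        spec = PayoffSpec(alpha=2.0)
        env = MarkovEnvSpec(mu=1.0, sigma_E=1.0, lam=0.9)
        meas = MeasurementModel(1.0)
        grid = np.linspace(-2.0, 4.0, 7)
        table = dynamic_optimal_strategy(spec, env, meas, grid)
        e_grid = np.arange(0.0, 4.0, 1e-4)
        for _ in range(20):
            i, j = rng.integers(0, 7, size=2)
            s_eff = max(posterior_mean_memory1(grid[i], grid[j], env, meas), 0.0)
            oracle = optimal_enzyme_grid(spec, s_eff, e_grid)
            assert abs(table.levels[i, j] - oracle) <= 1e-4

    def test_long_format_csv_round_trip(self, tmp_path):
        spec = PayoffSpec(alpha=2.0)
        table = dynamic_optimal_strategy(
            spec,
            MarkovEnvSpec(mu=1.0, lam=0.5),
            MeasurementModel(0.5),
            np.linspace(-1.0, 3.0, 9),
        )
        path = tmp_path / "dynamic.csv"
        table.to_csv(path)
        again = StrategyTable2D.from_csv(path)
        np.testing.assert_allclose(again.levels, table.levels)
        assert again(0.3, 1.2) == pytest.approx(table(0.3, 1.2))
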