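"""Inference and optimal regulation in a temporally correlated environment.

The environment is a stationary mean-reverting AR(1) chain with persistence
lam; readouts carry unbiased Gaussian noise.  Everything is jointly
Gaussian, so the expected current nutrient level given the current and any
number of past readouts follows from Gaussian conditioning, and coincides
with the Kalman-filter estimate run over those readouts (verified
numerically against the recursion in :mod:`enzopt.oracles`).
"""

from __future__ import annotations

import math

import numpy as np

from .specs import MarkovEnvSpec, MeasurementModel, PayoffSpec
from .static import classify_response, static_optimal_enzyme
from .tables import StrategyTable2D

__all__ = [
    "correlation_time",
    "memory_weights",
    "posterior_mean_memory",
    "posterior_mean_memory1",
    "posterior_mean_memory2",
    "dynamic_optimal_strategy",
]


def correlation_time(lam: float) -> float:
    """Correlation time tau = -1/ln(lam) in units of discrete time steps.

    The lag-k autocorrelation lam**k equals exp(-k/tau).  By convention
    tau = 0 for lam = 0 (memoryless environment); tau diverges as lam -> 1.
    """
    if not (0.0 <= lam < 1.0):
        raise ValueError(f"lam must lie in [0, 1), got {lam!r}")
    if lam == 0.0:
        return 0.0
    return -1.0 / math.log(lam)


def memory_weights(env: MarkovEnvSpec, meas: MeasurementModel, k: int) -> np.ndarray:
    """Linear conditioning weights of E[S_t | m_t, ..., m_{t-k}].

    The stationary chain and the readouts are jointly Gaussian with
    Cov(S_t, m_{t-j}) = lam**j * sigma_E^2 and
    Cov(m_{t-i}, m_{t-j}) = lam**|i-j| * sigma_E^2 + delta_ij * sigma_m^2,
    so E[S_t | m] = mu + w . (m - mu) with w the solution of the (k+1)-dim
    normal equations.  Weights are ordered newest first.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    lags = np.arange(k + 1)
    var_e = env.sigma_E**2
    cross = var_e * env.lam**lags
    K = var_e * env.lam ** np.abs(lags[:, None] - lags[None, :])
    K[np.diag_indices_from(K)] += meas.sigma_m**2
    return np.linalg.solve(K, cross)


def posterior_mean_memory(readouts, env: MarkovEnvSpec, meas: MeasurementModel):
    """E[S_t | readouts], readouts ordered newest first along the last axis."""
    readouts = np.asarray(readouts, dtype=float)
    w = memory_weights(env, meas, readouts.shape[-1] - 1)
    out = env.mu + (readouts - env.mu) @ w
    return out if np.ndim(out) else float(out)


def posterior_mean_memory1(m_t, m_prev, env: MarkovEnvSpec, meas: MeasurementModel):
    """Expected current nutrient level given the current and previous readouts.

    The one-step-memory Bayesian estimate: a linear blend of m_t, m_prev and
    the stationary mean mu whose weights depend on the persistence lam and
    beta = sigma_m^2/sigma_E^2.  Reduces to m_t when sigma_m = 0 and to the
    memoryless Gaussian posterior mean when lam = 0.
    """
    m_t, m_prev = np.broadcast_arrays(
        np.asarray(m_t, dtype=float), np.asarray(m_prev, dtype=float)
    )
    w = memory_weights(env, meas, 1)
    out = env.mu + w[0] * (m_t - env.mu) + w[1] * (m_prev - env.mu)
    return out if out.ndim else float(out)


def posterior_mean_memory2(
    m_t, m_prev, m_prev2, env: MarkovEnvSpec, meas: MeasurementModel
):
    """E[S_t | m_t, m_{t-1}, m_{t-2}] by 4-variate Gaussian conditioning."""
    m_t, m_prev, m_prev2 = np.broadcast_arrays(
        np.asarray(m_t, dtype=float),
        np.asarray(m_prev, dtype=float),
        np.asarray(m_prev2, dtype=float),
    )
    w = memory_weights(env, meas, 2)
    out = (
        env.mu
        + w[0] * (m_t - env.mu)
        + w[1] * (m_prev - env.mu)
        + w[2] * (m_prev2 - env.mu)
    )
    return out if out.ndim else float(out)


def dynamic_optimal_strategy(
    spec: PayoffSpec,
    env: MarkovEnvSpec,
    meas: MeasurementModel,
    grid_t,
    grid_prev=None,
) -> StrategyTable2D:
    """Optimal strategy E*(m_t, m_prev) in the mean-reverting environment.

    As in the static noisy case, benefit linear in S makes the optimal
    response the perfect-measurement optimum evaluated at the (clamped)
    one-step-memory posterior mean, tabulated on a 2-D readout grid.
    """
    if spec.benefit_mode != "linear" and meas.sigma_m > 0:
        raise ValueError("closed-form dynamic strategies require linear benefit")
    grid_t = np.asarray(grid_t, dtype=float)
    grid_prev = grid_t if grid_prev is None else np.asarray(grid_prev, dtype=float)
    mt, mp = np.meshgrid(grid_t, grid_prev, indexing="ij")
    s_eff = np.clip(posterior_mean_memory1(mt, mp, env, meas), 0.0, None)
    levels = np.asarray(static_optimal_enzyme(spec, s_eff), dtype=float)
    meta = {
        "strategy": "bayes_memory1",
        "payoff": spec.to_dict(),
        "environment": env.to_dict(),
        "measurement": meas.to_dict(),
        "response_class": classify_response(spec.alpha, spec.gamma).value,
        "beta": meas.sigma_m**2 / env.sigma_E**2,
    }
    return StrategyTable2D(grid_t=grid_t, grid_prev=grid_prev, levels=levels, meta=meta)
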