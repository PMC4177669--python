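"""Brute-force numerical references for the closed-form theory.

Every closed form in the package is validated against an independent slow
route implemented here: adaptive quadrature for posterior expectations,
dense grid search for payoff maximization, the sequential Kalman recursion
for the memory posterior means, and Monte-Carlo estimation of expected
fitness.  These are deliberately written for transparency, not speed.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad

from .payoff import payoff as payoff_fn
from .simulate import add_measurements, sample_static, simulate_with_readouts
from .specs import (
    GaussianPrior,
    MarkovEnvSpec,
    MeasurementModel,
    MixturePrior,
    PayoffSpec,
)
from .tables import apply_strategy

__all__ = [
    "prior_density",
    "default_bounds",
    "posterior_mean_quadrature",
    "posterior_functional_quadrature",
    "optimal_enzyme_grid",
    "kalman_posterior_mean",
    "expected_fitness_mc",
]

_WINDOW_SD = 8.0  # integration window half-width, in combined standard deviations


def prior_density(prior):
    """Density function of a static prior (Gaussian or mixture)."""
    if isinstance(prior, GaussianPrior):
        mu, s = prior.mu, prior.sigma_E

        def dens(x):
            return math.exp(-0.5 * ((x - mu) / s) ** 2) / (s * math.sqrt(2 * math.pi))

        return dens
    if isinstance(prior, MixturePrior):
        comps = prior.components

        def dens(x):
            total = 0.0
            for p, mu, s in comps:
                total += (
                    p
                    * math.exp(-0.5 * ((x - mu) / s) ** 2)
                    / (s * math.sqrt(2 * math.pi))
                )
            return total

        return dens
    raise TypeError(f"unsupported prior type: {type(prior).__name__}")


def default_bounds(prior, meas: MeasurementModel, m: float):
    """Integration window covering +/- 8 combined SD around every center.

    Centers are the prior mode means and the readout; the combined SD adds
    the largest prior scale and the measurement scale in quadrature.
    """
    if isinstance(prior, GaussianPrior):
        centers = [prior.mu, m]
        scale = prior.sigma_E
    elif isinstance(prior, MixturePrior):
        centers = list(prior.means) + [m]
        scale = max(prior.sigmas)
    else:
        raise TypeError(f"unsupported prior type: {type(prior).__name__}")
    w = _WINDOW_SD * math.sqrt(scale**2 + meas.sigma_m**2)
    return min(centers) - w, max(centers) + w


def posterior_functional_quadrature(
    m: float, f, prior_dens, meas: MeasurementModel, bounds
) -> float:
    """E[f(S) | m] = int f(S) p(S) N(m; S, sigma_m^2) dS / normalizer.

    ``prior_dens`` may be a prior object (density and default bounds derived
    automatically when ``bounds`` is None) or a bare density callable, in
    which case explicit bounds are required.  Perfect measurement
    (sigma_m = 0) returns f(m) directly.
    """
    if meas.sigma_m == 0.0:
        return float(f(m))
    features = [(m, meas.sigma_m)]
    if callable(prior_dens):
        dens = prior_dens
        if bounds is None:
            raise ValueError("explicit bounds are required for a bare density")
    else:
        dens = prior_density(prior_dens)
        if bounds is None:
            bounds = default_bounds(prior_dens, meas, m)
        if isinstance(prior_dens, GaussianPrior):
            features.append((prior_dens.mu, prior_dens.sigma_E))
        else:
            features.extend(zip(prior_dens.means, prior_dens.sigmas))
    lo, hi = bounds
    # segment the window so that features (likelihood spike, narrow prior
    # modes) much sharper than the window are never skipped by the initial
    # Gauss-Kronrod sampling
    edges = {lo, hi}
    for center, width in features:
        for e in (center - 10.0 * width, center, center + 10.0 * width):
            if lo < e < hi:
                edges.add(e)
    edges = sorted(edges)
    inv2v = 0.5 / meas.sigma_m**2

    def like(s):
        return math.exp(-inv2v * (m - s) ** 2)

    def integrate(g):
        total = 0.0
        for a, b in zip(edges[:-1], edges[1:]):
            part, _ = quad(g, a, b, epsabs=1e-13, epsrel=1e-12, limit=400)
            total += part
        return total

    num = integrate(lambda s: f(s) * dens(s) * like(s))
    den = integrate(lambda s: dens(s) * like(s))
    if den <= 0.0 or not math.isfinite(den):
        raise FloatingPointError(
            "posterior normalizer vanished: readout lies outside numerical support"
        )
    return num / den


def posterior_mean_quadrature(
    m: float, prior_dens, meas: MeasurementModel, bounds=None
) -> float:
    """E[S | m] by adaptive quadrature (the oracle for every closed form)."""
    return posterior_functional_quadrature(m, lambda s: s, prior_dens, meas, bounds)


def optimal_enzyme_grid(spec: PayoffSpec, S_eff: float, E_grid) -> float:
    """Payoff argmax over a dense enzyme grid; ties go to the smallest E."""
    E_grid = np.asarray(E_grid, dtype=float)
    if E_grid.size == 0:
        raise ValueError("E_grid must be nonempty")
    if np.any(E_grid > spec.E_max):
        raise ValueError("E_grid exceeds E_max")
    values = payoff_fn(spec, E_grid, max(S_eff, 0.0))
    return float(E_grid[int(np.argmax(values))])


def kalman_posterior_mean(
    readouts, env: MarkovEnvSpec, meas: MeasurementModel
) -> tuple[float, float]:
    """E[S_t | m_{t-k}, ..., m_t] by the standard Kalman recursion.

    ``readouts`` are ordered oldest first.  The filter is initialized at the
    stationary marginal, alternates measurement updates and one-step AR(1)
    predictions, and ends on the update with the newest readout.  Returns
    (posterior mean, posterior variance).
    """
    readouts = np.asarray(readouts, dtype=float)
    if readouts.ndim != 1 or readouts.size < 1:
        raise ValueError("readouts must be a nonempty 1-D sequence, oldest first")
    xhat, P = env.mu, env.sigma_E**2
    r = meas.sigma_m**2
    for i, m in enumerate(readouts):
        if P + r > 0:
            gain = P / (P + r)
        else:  # deterministic state and perfect sensor
            gain = 1.0
        xhat = xhat + gain * (m - xhat)
        P = (1.0 - gain) * P
        if i < readouts.size - 1:
            xhat = env.lam * xhat + (1.0 - env.lam) * env.mu
            P = env.lam**2 * P + env.sigma_d**2
    return float(xhat), float(P)


def _realized_payoff(spec: PayoffSpec, E: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Payoff evaluated on simulated nutrient levels, extended to signed S.

    Gaussian environment models put (small) mass on negative concentrations;
    the payoff formulas extend linearly there so that Bayes-optimal
    strategies remain exactly optimal under the generating model.
    """
    if spec.benefit_mode == "linear":
        ben = spec.b * E * S
    elif spec.benefit_mode == "michaelis_menten":
        ben = spec.b * E * S / (spec.K_M + S)
    else:
        ben = spec.b * S * E**spec.gamma
    return ben - spec.c * E**spec.alpha


def _batch_se(values: np.ndarray, n_batches: int = 100) -> float:
    """Batch-means standard error, robust to serial correlation."""
    n = values.size
    k = max(2, min(n_batches, n // 2))
    usable = (n // k) * k
    means = values[:usable].reshape(k, -1).mean(axis=1)
    return float(means.std(ddof=1) / math.sqrt(k))


def expected_fitness_mc(
    strategy,
    env_model,
    meas: MeasurementModel,
    spec: PayoffSpec,
    n: int,
    seed: int,
) -> tuple[float, float]:
    """Monte-Carlo mean payoff of a strategy under the joint (S, m) law.

    Static priors draw i.i.d. (S, m) pairs; a Markov environment simulates
    a stationary trajectory with readouts and evaluates the strategy with
    as many lagged readouts as it consumes (``strategy.n_inputs``).  The
    standard error uses batch means on trajectories, where payoffs are
    serially correlated.  Returns (mean payoff, standard error).
    """
    if n < 100:
        raise ValueError("n < 100: the Monte-Carlo standard error is meaningless")
    if isinstance(env_model, (GaussianPrior, MixturePrior)):
        S = sample_static(env_model, n, seed)
        m = add_measurements(S, meas, seed)
        E = np.asarray(apply_strategy(strategy, m), dtype=float)
        values = _realized_payoff(spec, E, S)
        return float(values.mean()), float(values.std(ddof=1) / math.sqrt(n))
    if isinstance(env_model, MarkovEnvSpec):
        traj = simulate_with_readouts(env_model, meas, n + 2, seed)
        S, m = traj.S[2:], traj.m
        E = np.asarray(
            apply_strategy(strategy, m[2:], m[1:-1], m[:-2]), dtype=float
        )
        values = _realized_payoff(spec, E, S)
        return float(values.mean()), _batch_se(values)
    raise TypeError(f"unsupported environment model: {type(env_model).__name__}")
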