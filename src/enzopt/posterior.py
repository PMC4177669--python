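"""Posterior nutrient estimates from a noisy readout, and noise regimes.

With an unbiased Gaussian sensor (m = S + eps, eps ~ N(0, sigma_m^2)) and a
known environmental prior over S, the fitness-maximizing response to a
readout depends on S only through the posterior mean E[S | m] whenever the
benefit is linear in S.  This module provides closed-form posterior means
for uniform, Gaussian, bimodal, and general Gaussian-mixture priors, the
dimensionless regime coordinates beta and xi, and the composition of the
posterior mean with the perfect-measurement optimum.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import logsumexp

from .specs import GaussianPrior, MeasurementModel, MixturePrior, RegimeParams
from .static import ResponseClass, classify_response, static_optimal_enzyme
from .specs import PayoffSpec
from .tables import StrategyTable

__all__ = [
    "beta_ratio",
    "posterior_mean_uniform",
    "posterior_mean_gaussian",
    "posterior_variance_gaussian",
    "posterior_mean_mixture",
    "posterior_mean_bimodal_tanh",
    "xi_ratio",
    "sigma_m_for_xi",
    "classify_measurement_regime",
    "noisy_optimal_strategy",
]


def beta_ratio(prior: GaussianPrior, meas: MeasurementModel) -> float:
    """Inverse signal-to-noise ratio beta = sigma_m^2 / sigma_E^2."""
    return meas.sigma_m**2 / prior.sigma_E**2


def posterior_mean_uniform(m):
    """Posterior mean under an uninformative (flat) prior: the readout itself."""
    m = np.asarray(m, dtype=float)
    return m if m.ndim else float(m)


def posterior_mean_gaussian(m, prior: GaussianPrior, meas: MeasurementModel):
    """E[S | m] for a Gaussian prior: (m + beta*mu) / (1 + beta).

    The classic linear shrinkage of the readout toward the prior mean, with
    weight set by beta = sigma_m^2 / sigma_E^2.  beta = 0 returns m
    (definitive measurement); beta -> inf returns mu (useless measurement).
    """
    m = np.asarray(m, dtype=float)
    beta = beta_ratio(prior, meas)
    out = (m + beta * prior.mu) / (1.0 + beta)
    return out if out.ndim else float(out)


def posterior_variance_gaussian(prior: GaussianPrior, meas: MeasurementModel) -> float:
    """Var[S | m] for a Gaussian prior: sigma_m^2 / (1 + beta), independent of m."""
    beta = beta_ratio(prior, meas)
    return meas.sigma_m**2 / (1.0 + beta)


def posterior_mean_mixture(m, prior: MixturePrior, meas: MeasurementModel):
    """E[S | m] for a Gaussian-mixture prior.

    A responsibility-weighted sum of per-mode Gaussian posterior means:
    w_i(m) proportional to p_i * N(m; mu_i, sigma_i^2 + sigma_m^2), and each
    mode contributes (m + beta_i * mu_i) / (1 + beta_i) with the within-mode
    beta_i = sigma_m^2 / sigma_i^2.  Computed with log-sum-exp for stability
    far into the tails.
    """
    m = np.asarray(m, dtype=float)
    scalar = m.ndim == 0
    m2 = np.atleast_1d(m)[:, None]  # (n, 1)
    p = np.array(prior.weights)
    mu = np.array(prior.means)
    sig2 = np.array(prior.sigmas) ** 2
    s2 = sig2 + meas.sigma_m**2  # marginal readout variance per mode
    log_w = (
        np.log(p)
        - 0.5 * np.log(2.0 * math.pi * s2)
        - 0.5 * (m2 - mu) ** 2 / s2
    )
    log_w -= logsumexp(log_w, axis=1, keepdims=True)
    beta_i = meas.sigma_m**2 / sig2
    mode_means = (m2 + beta_i * mu) / (1.0 + beta_i)
    out = np.sum(np.exp(log_w) * mode_means, axis=1)
    return float(out[0]) if scalar else out


def posterior_mean_bimodal_tanh(m, prior: MixturePrior, meas: MeasurementModel):
    """E[S | m] for the symmetric bimodal prior, in explicit sigmoidal form.

    For an equiprobable two-Gaussian mixture with common within-mode sigma
    and mode separation delta_mu, the posterior mean is

        m/(1+beta) + beta/(1+beta) * [mu_bar
            + (delta_mu/2) * tanh((m - mu_bar) * delta_mu / (2*(sigma^2 + sigma_m^2)))]

    The tanh steepness — the effective cooperativity of the optimal
    thresholded response — is set by delta_mu over the summed environmental
    and measurement variances.  Algebraically identical to
    :func:`posterior_mean_mixture`; kept as an independent form.
    """
    if not prior.is_bimodal:
        raise ValueError("tanh form requires an equiprobable equal-sigma bimodal prior")
    m = np.asarray(m, dtype=float)
    sigma = prior.sigmas[0]
    beta = meas.sigma_m**2 / sigma**2
    s2 = sigma**2 + meas.sigma_m**2
    mu_bar = prior.mu_bar
    dmu = prior.delta_mu
    sgn = 1.0 if prior.components[1][1] >= prior.components[0][1] else -1.0
    mode_pull = 0.5 * dmu * np.tanh(sgn * (m - mu_bar) * dmu / (2.0 * s2)) * sgn
    out = m / (1.0 + beta) + beta / (1.0 + beta) * (mu_bar + mode_pull)
    return out if out.ndim else float(out)


def xi_ratio(prior: MixturePrior, meas: MeasurementModel) -> float:
    """Mode-distinguishability parameter for a bimodal environment.

    xi = sigma_m^2 / (delta_mu * sqrt(sigma_E^2 + sigma_m^2)): the
    measurement variance over the product of the mode separation and the
    typical distance of a readout from a mode mean.  xi << 1: modes
    distinguishable (classification); xi >> 1: indistinguishable
    (constitutive response at the overall mean).  Returns inf when the mode
    means coincide.
    """
    if not prior.is_bimodal:
        raise ValueError("xi is defined for the equiprobable bimodal prior")
    dmu = prior.delta_mu
    if dmu == 0.0:
        return math.inf
    sigma = prior.sigmas[0]
    return meas.sigma_m**2 / (dmu * math.sqrt(sigma**2 + meas.sigma_m**2))


def sigma_m_for_xi(prior: MixturePrior, xi: float) -> float:
    """Measurement noise level giving a target xi for a bimodal prior.

    Inverts xi = x / (delta_mu * sqrt(sigma^2 + x)) in x = sigma_m^2.
    """
    if xi < 0:
        raise ValueError("xi must be >= 0")
    if xi == 0.0:
        return 0.0
    dmu = prior.delta_mu
    sigma = prior.sigmas[0]
    a = (xi * dmu) ** 2
    x = 0.5 * (a + math.sqrt(a**2 + 4.0 * a * sigma**2))
    return math.sqrt(x)


def classify_measurement_regime(
    params: RegimeParams, low: float = 0.1, high: float = 10.0
) -> str:
    """Label the noise regime from the dimensionless coordinate.

    Unimodal (beta): 'naive' (beta < low), 'bayesian' (intermediate),
    'constitutive' (beta > high).  Bimodal (xi): 'classification',
    'ambiguous', 'constitutive'.  The cut points are presentation defaults;
    the underlying transitions are gradual.
    """
    if params.xi is not None:
        labels = ("classification", "ambiguous", "constitutive")
        value = params.xi
    else:
        labels = ("naive", "bayesian", "constitutive")
        value = params.beta
    if value < low:
        return labels[0]
    if value > high:
        return labels[2]
    return labels[1]


def _posterior_mean(m, prior, meas: MeasurementModel):
    if prior is None:
        return posterior_mean_uniform(m)
    if isinstance(prior, GaussianPrior):
        return posterior_mean_gaussian(m, prior, meas)
    if isinstance(prior, MixturePrior):
        return posterior_mean_mixture(m, prior, meas)
    raise TypeError(f"unsupported prior type: {type(prior).__name__}")


def noisy_optimal_strategy(
    spec: PayoffSpec, prior, meas: MeasurementModel, grid
) -> StrategyTable:
    """Optimal strategy E*(m) under readout noise, tabulated on a grid.

    Because the (unsaturated) benefit is linear in S, the expected payoff
    given m depends on the environment only through E[S | m]; the optimal
    response is therefore the perfect-measurement optimum evaluated at the
    posterior mean (clamped at zero, since negative effective concentrations
    carry no benefit).  Graded class: E*(m) = E*_static(max(E[S|m], 0));
    thresholding class: E[S|m] is thresholded against S_t.
    """
    if spec.benefit_mode != "linear" and meas.sigma_m > 0:
        raise ValueError(
            "closed-form noisy strategies require benefit linear in S; for "
            "Michaelis-Menten benefit under noise use "
            "oracles.posterior_functional_quadrature"
        )
    grid = np.asarray(grid, dtype=float)
    s_eff = np.clip(np.asarray(_posterior_mean(grid, prior, meas), float), 0.0, None)
    levels = np.asarray(static_optimal_enzyme(spec, s_eff), dtype=float)
    meta = {
        "strategy": "bayes",
        "payoff": spec.to_dict(),
        "prior": prior.to_dict() if prior is not None else None,
        "measurement": meas.to_dict(),
        "response_class": classify_response(spec.alpha, spec.gamma).value,
        "E_max": spec.E_max,
    }
    if isinstance(prior, GaussianPrior):
        meta["beta"] = beta_ratio(prior, meas)
    elif isinstance(prior, MixturePrior) and prior.is_bimodal:
        meta["xi"] = xi_ratio(prior, meas)
    return StrategyTable(grid=grid, levels=levels, meta=meta)
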