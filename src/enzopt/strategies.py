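"""Regulatory strategies as scikit-learn-style estimators.

Each strategy is an estimator mapping readout(s) to an enzyme expression
level.  ``fit`` validates the model specification and precomputes the
fitted quantities (thresholds, shrinkage weights, constitutive levels);
``predict`` evaluates the strategy on readout columns.  The estimators
compose with sklearn pipelines and ``get_params``/``set_params``-based
model selection, and ``tabulate`` exports the classical grid
representation used for serialization and interpolation.

Strategy families
-----------------
NaiveResponse        treat the readout as the true nutrient level
ConstitutiveResponse fixed enzyme level at the optimum for the prior mean
BayesResponse        perfect-measurement optimum at the posterior mean
MemoryBayesResponse  as BayesResponse, conditioning on past readouts too
                     (mean-reverting Markov environment; Kalman-equivalent)
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .dynamics import memory_weights
from .posterior import (
    beta_ratio,
    posterior_mean_gaussian,
    posterior_mean_mixture,
    posterior_mean_uniform,
)
from .specs import (
    GaussianPrior,
    MarkovEnvSpec,
    MeasurementModel,
    MixturePrior,
    PayoffSpec,
)
from .static import classify_response, static_optimal_enzyme
from .tables import StrategyTable, StrategyTable2D

__all__ = [
    "RegulatoryStrategy",
    "NaiveResponse",
    "ConstitutiveResponse",
    "BayesResponse",
    "MemoryBayesResponse",
]


class RegulatoryStrategy(BaseEstimator):
    """Base class: readout(s) in, enzyme level out."""

    @property
    def n_inputs(self) -> int:
        return 1

    def fit(self, X=None, y=None):  # noqa: D102 - no data needed; parameters define the fit
        raise NotImplementedError

    def _validate_readouts(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            if self.n_inputs == 1:
                X = X[:, None]
            else:
                raise ValueError(
                    f"{type(self).__name__} expects {self.n_inputs} readout columns"
                )
        if X.ndim != 2 or X.shape[1] != self.n_inputs:
            raise ValueError(
                f"expected readout array of shape (n, {self.n_inputs}), got {X.shape}"
            )
        return X

    def __call__(self, *readouts):
        shape = np.broadcast_shapes(*(np.shape(r) for r in readouts)) if readouts else ()
        cols = [np.broadcast_to(np.asarray(r, float), shape).ravel() for r in readouts]
        out = self.predict(np.column_stack(cols))
        return float(out[0]) if shape == () else out.reshape(shape)

    def tabulate(self, grid, grid_prev=None):
        """Export the strategy as a grid table (1-D or 2-D by memory)."""
        check_is_fitted(self)
        grid = np.asarray(grid, dtype=float)
        meta = {"strategy": type(self).__name__, "params": repr(self.get_params())}
        if self.n_inputs == 1:
            return StrategyTable(grid=grid, levels=np.asarray(self(grid)), meta=meta)
        if self.n_inputs == 2:
            gp = grid if grid_prev is None else np.asarray(grid_prev, dtype=float)
            mt, mp = np.meshgrid(grid, gp, indexing="ij")
            return StrategyTable2D(
                grid_t=grid, grid_prev=gp, levels=np.asarray(self(mt, mp)), meta=meta
            )
        raise ValueError("tabulate supports at most two readout inputs")


class NaiveResponse(RegulatoryStrategy):
    """Respond to the readout as if it were the true nutrient level.

    Optimal in the low-noise limit (beta << 1).  Negative readouts clamp to
    zero effective concentration before the static optimum.
    """

    def __init__(self, payoff: PayoffSpec = PayoffSpec()):
        self.payoff = payoff

    def fit(self, X=None, y=None):
        self.response_class_ = classify_response(self.payoff.alpha, self.payoff.gamma)
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = self._validate_readouts(X)
        s_eff = np.clip(X[:, 0], 0.0, None)
        return np.asarray(static_optimal_enzyme(self.payoff, s_eff), dtype=float)


class ConstitutiveResponse(RegulatoryStrategy):
    """Hold a fixed enzyme level, ignoring the readout.

    The level is the perfect-measurement optimum at the prior (or
    stationary) mean — the optimal strategy in the useless-measurement
    limit (beta >> 1).
    """

    def __init__(self, payoff: PayoffSpec = PayoffSpec(), prior=GaussianPrior()):
        self.payoff = payoff
        self.prior = prior

    def fit(self, X=None, y=None):
        if isinstance(self.prior, MixturePrior):
            mean = self.prior.mu_bar
        else:  # GaussianPrior or MarkovEnvSpec
            mean = self.prior.mu
        self.level_ = float(
            static_optimal_enzyme(self.payoff, max(mean, 0.0))
        )
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = self._validate_readouts(X)
        return np.full(X.shape[0], self.level_)


class BayesResponse(RegulatoryStrategy):
    """Optimal response to a noisy readout in a static environment.

    Composes the perfect-measurement optimum with the posterior mean
    E[S | m] of the configured prior (Gaussian, mixture, or None for the
    uninformative prior).  Interpolates between NaiveResponse (beta -> 0)
    and ConstitutiveResponse (beta -> inf).
    """

    def __init__(
        self,
        payoff: PayoffSpec = PayoffSpec(),
        prior=GaussianPrior(),
        measurement: MeasurementModel = MeasurementModel(),
    ):
        self.payoff = payoff
        self.prior = prior
        self.measurement = measurement

    def fit(self, X=None, y=None):
        if self.payoff.benefit_mode != "linear" and self.measurement.sigma_m > 0:
            raise ValueError(
                "closed-form Bayes response requires benefit linear in S"
            )
        self.response_class_ = classify_response(self.payoff.alpha, self.payoff.gamma)
        if isinstance(self.prior, GaussianPrior):
            self.beta_ = beta_ratio(self.prior, self.measurement)
        return self

    def posterior_mean(self, m):
        if self.prior is None:
            return posterior_mean_uniform(m)
        if isinstance(self.prior, GaussianPrior):
            return posterior_mean_gaussian(m, self.prior, self.measurement)
        if isinstance(self.prior, MixturePrior):
            return posterior_mean_mixture(m, self.prior, self.measurement)
        raise TypeError(f"unsupported prior type: {type(self.prior).__name__}")

    def predict(self, X):
        check_is_fitted(self)
        X = self._validate_readouts(X)
        s_eff = np.clip(np.asarray(self.posterior_mean(X[:, 0]), float), 0.0, None)
        return np.asarray(static_optimal_enzyme(self.payoff, s_eff), dtype=float)


class MemoryBayesResponse(RegulatoryStrategy):
    """Optimal response using current and past readouts (Markov environment).

    Conditions on ``memory`` past readouts in the stationary mean-reverting
    AR(1) environment; the posterior mean is the Kalman-filter estimate and
    enters the static optimum exactly as in :class:`BayesResponse`.  Fitted
    attribute ``weights_`` holds the linear conditioning weights (newest
    readout first).
    """

    def __init__(
        self,
        payoff: PayoffSpec = PayoffSpec(),
        env: MarkovEnvSpec = MarkovEnvSpec(),
        measurement: MeasurementModel = MeasurementModel(),
        memory: int = 1,
    ):
        self.payoff = payoff
        self.env = env
        self.measurement = measurement
        self.memory = memory

    @property
    def n_inputs(self) -> int:
        return self.memory + 1

    def fit(self, X=None, y=None):
        if self.memory < 0:
            raise ValueError("memory must be >= 0")
        if self.payoff.benefit_mode != "linear" and self.measurement.sigma_m > 0:
            raise ValueError(
                "closed-form Bayes response requires benefit linear in S"
            )
        self.response_class_ = classify_response(self.payoff.alpha, self.payoff.gamma)
        self.weights_ = memory_weights(self.env, self.measurement, self.memory)
        return self

    def posterior_mean(self, X):
        X = np.asarray(X, dtype=float)
        return self.env.mu + (X - self.env.mu) @ self.weights_

    def predict(self, X):
        check_is_fitted(self)
        X = self._validate_readouts(X)
        s_eff = np.clip(self.posterior_mean(X), 0.0, None)
        return np.asarray(static_optimal_enzyme(self.payoff, s_eff), dtype=float)
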