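"""Head-to-head fitness comparison of regulatory strategy families.

Quantifies the regime structure of the theory: naive response wins at low
measurement noise, constitutive expression at high noise, and the Bayesian
decision rule interpolates and never loses (under the generating model).
In dynamic environments the comparison extends to memory-carrying
strategies, and the *value of memory* — the paired fitness gain of
conditioning on the previous readout — peaks at intermediate noise.

All comparisons use common random numbers: every strategy is evaluated on
the same simulated environment and readout stream, so paired differences
are sharp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .oracles import _batch_se, _realized_payoff
from .posterior import sigma_m_for_xi, xi_ratio
from .simulate import add_measurements, sample_static, simulate_with_readouts
from .specs import (
    GaussianPrior,
    MarkovEnvSpec,
    MeasurementModel,
    MixturePrior,
    PayoffSpec,
)
from .strategies import (
    BayesResponse,
    ConstitutiveResponse,
    MemoryBayesResponse,
    NaiveResponse,
)
from .tables import apply_strategy

__all__ = [
    "StrategyComparison",
    "build_reference_estimators",
    "build_reference_strategies",
    "compare_strategies",
    "payoff_samples",
    "value_of_memory",
    "memory_value_sweep",
    "regime_map",
]


@dataclass
class StrategyComparison:
    """Mean payoffs (with MC standard errors) of competing strategies."""

    labels: list
    mean_payoffs: list
    standard_errors: list
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.labels) == len(self.mean_payoffs) == len(self.standard_errors)):
            raise ValueError("labels, mean_payoffs, standard_errors must align")
        if any(se < 0 for se in self.standard_errors):
            raise ValueError("standard errors must be nonnegative")

    @property
    def winner(self) -> str:
        return self.labels[int(np.argmax(self.mean_payoffs))]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "strategy": self.labels,
                "mean_payoff": self.mean_payoffs,
                "standard_error": self.standard_errors,
            }
        )
        for k, v in self.params.items():
            df[k] = v
        return df


def build_reference_estimators(spec: PayoffSpec, prior_or_env, meas: MeasurementModel):
    """Fitted reference strategies keyed by label.

    Static priors: naive, constitutive, bayes.  Markov environments add the
    memory-carrying Bayesian variants (the memoryless 'bayes' uses the
    stationary marginal as its prior).
    """
    if isinstance(prior_or_env, MarkovEnvSpec):
        static_prior = prior_or_env.stationary_prior
        out = {
            "naive": NaiveResponse(spec).fit(),
            "constitutive": ConstitutiveResponse(spec, static_prior).fit(),
            "bayes": BayesResponse(spec, static_prior, meas).fit(),
            "bayes_memory1": MemoryBayesResponse(spec, prior_or_env, meas, memory=1).fit(),
            "bayes_memory2": MemoryBayesResponse(spec, prior_or_env, meas, memory=2).fit(),
        }
    else:
        out = {
            "naive": NaiveResponse(spec).fit(),
            "constitutive": ConstitutiveResponse(spec, prior_or_env).fit(),
            "bayes": BayesResponse(spec, prior_or_env, meas).fit(),
        }
    return out


def build_reference_strategies(spec: PayoffSpec, prior_or_env, meas, grid):
    """Reference strategies tabulated on a readout grid (see estimators).

    Strategies consuming more than two readouts (memory >= 2) have no table
    representation and are returned as fitted estimators.
    """
    grid = np.asarray(grid, dtype=float)
    return {
        label: est.tabulate(grid) if est.n_inputs <= 2 else est
        for label, est in build_reference_estimators(spec, prior_or_env, meas).items()
    }


def payoff_samples(strategies: dict, spec, env_model, meas, n, seed):
    """Per-strategy payoff samples on one shared simulation.

    Returns (samples, correlated): a dict of per-step payoff arrays keyed by
    strategy label, all evaluated on the same (S, m) stream, and a flag
    marking whether the samples are serially correlated (Markov
    environments).  Paired differences of these arrays give sharp
    common-random-number comparisons.
    """
    if n < 100:
        raise ValueError("n < 100: the Monte-Carlo standard error is meaningless")
    if isinstance(env_model, MarkovEnvSpec):
        traj = simulate_with_readouts(env_model, meas, n + 2, seed)
        S, m = traj.S[2:], traj.m
        args = (m[2:], m[1:-1], m[:-2])
        correlated = True
    else:
        S = sample_static(env_model, n, seed)
        m = add_measurements(S, meas, seed)
        args = (m,)
        correlated = False
    out = {}
    for label, strat in strategies.items():
        E = np.asarray(apply_strategy(strat, *args), dtype=float)
        out[label] = _realized_payoff(spec, E, S)
    return out, correlated


def _se(values: np.ndarray, correlated: bool) -> float:
    if correlated:
        return _batch_se(values)
    return float(values.std(ddof=1) / math.sqrt(values.size))


def compare_strategies(
    strategies: dict,
    spec: PayoffSpec,
    env_model,
    meas: MeasurementModel,
    n: int,
    seed: int,
    params: dict | None = None,
) -> StrategyComparison:
    """MC fitness of each strategy on one common simulated (S, m) stream."""
    samples, correlated = payoff_samples(strategies, spec, env_model, meas, n, seed)
    labels = list(samples)
    return StrategyComparison(
        labels=labels,
        mean_payoffs=[float(samples[k].mean()) for k in labels],
        standard_errors=[_se(samples[k], correlated) for k in labels],
        params=dict(params or {}),
    )


def value_of_memory(
    spec: PayoffSpec,
    env: MarkovEnvSpec,
    meas: MeasurementModel,
    n: int,
    seed: int,
) -> tuple[float, float]:
    """Fitness gain of one-step memory over memoryless Bayesian response.

    Both strategies are evaluated on the same simulated trajectory (common
    random numbers); the return value is the mean paired payoff difference
    and its standard error (batch means, since trajectory payoffs are
    serially correlated).
    """
    if not (0.0 < env.lam < 1.0):
        raise ValueError("value_of_memory requires persistence lam in (0, 1)")
    strategies = {
        "bayes": BayesResponse(spec, env.stationary_prior, meas).fit(),
        "bayes_memory1": MemoryBayesResponse(spec, env, meas, memory=1).fit(),
    }
    samples, _ = payoff_samples(strategies, spec, env, meas, n, seed)
    diff = samples["bayes_memory1"] - samples["bayes"]
    return float(diff.mean()), _batch_se(diff)


def memory_value_sweep(
    spec: PayoffSpec,
    env: MarkovEnvSpec,
    betas,
    n: int,
    seed: int,
) -> pd.DataFrame:
    """Value of memory across measurement-noise levels beta at fixed lam.

    The environment substream is identical across beta (same path; only the
    readout corruption differs), isolating the effect of noise.
    """
    rows = []
    for beta in betas:
        meas = MeasurementModel(sigma_m=math.sqrt(beta) * env.sigma_E)
        v, se = value_of_memory(spec, env, meas, n, seed)
        rows.append({"beta": beta, "lam": env.lam, "value_of_memory": v, "standard_error": se})
    return pd.DataFrame(rows)


def _cell_model(family: str, beta=None, lam=None, xi=None, sigma_E=1.0,
                mu=1.0, delta_mu=2.0, sigma_mode=0.1):
    """Environment model + measurement model for one sweep cell."""
    if family == "gaussian":
        prior = GaussianPrior(mu=mu, sigma_E=sigma_E)
        meas = MeasurementModel(sigma_m=math.sqrt(beta) * sigma_E)
        return prior, meas, {"beta": beta}
    if family == "bimodal":
        prior = MixturePrior.bimodal(mu_bar=mu, delta_mu=delta_mu, sigma=sigma_mode)
        meas = MeasurementModel(sigma_m=sigma_m_for_xi(prior, xi))
        return prior, meas, {"xi": xi_ratio(prior, meas)}
    if family == "markov":
        env = MarkovEnvSpec(mu=mu, sigma_E=sigma_E, lam=lam)
        meas = MeasurementModel(sigma_m=math.sqrt(beta) * sigma_E)
        return env, meas, {"beta": beta, "lam": lam}
    raise ValueError(f"unknown prior family: {family!r}")


def regime_map(
    spec: PayoffSpec,
    family: str,
    sweep: dict,
    n: int,
    seed: int,
    **model_kwargs,
) -> pd.DataFrame:
    """Best-performing strategy per cell of a noise/persistence sweep.

    ``family`` is 'gaussian' (sweep beta), 'bimodal' (sweep xi), or
    'markov' (sweep beta x lam).  Each cell runs the reference strategies
    through a common-random-number MC fitness comparison and records the
    winner and its margin over the runner-up (in payoff units and in
    combined standard errors).
    """
    if family == "gaussian":
        cells = [{"beta": b} for b in sweep["beta"]]
    elif family == "bimodal":
        cells = [{"xi": x} for x in sweep["xi"]]
    elif family == "markov":
        cells = [
            {"beta": b, "lam": l} for b in sweep["beta"] for l in sweep["lam"]
        ]
    else:
        raise ValueError(f"unknown prior family: {family!r}")
    rows = []
    for i, cell in enumerate(cells):
        model, meas, coords = _cell_model(family, **cell, **model_kwargs)
        strategies = build_reference_estimators(spec, model, meas)
        comp = compare_strategies(
            strategies, spec, model, meas, n, seed + i, params=coords
        )
        order = np.argsort(comp.mean_payoffs)[::-1]
        best, second = order[0], order[1]
        margin = comp.mean_payoffs[best] - comp.mean_payoffs[second]
        margin_se = math.hypot(
            comp.standard_errors[best], comp.standard_errors[second]
        )
        row = dict(coords)
        row.update(
            winner=comp.labels[best],
            runner_up=comp.labels[second],
            margin=margin,
            margin_in_se=margin / margin_se if margin_se > 0 else math.inf,
        )
        for label, mp, se in zip(comp.labels, comp.mean_payoffs, comp.standard_errors):
            row[f"payoff_{label}"] = mp
            row[f"se_{label}"] = se
        rows.append(row)
    return pd.DataFrame(rows)
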