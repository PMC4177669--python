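"""Optimal enzyme levels under perfect measurement.

The relative convexity of cost (c*E**alpha) and benefit (~ E**gamma) in the
enzyme level decides the character of the optimal response:

- alpha > gamma (cost strictly convex relative to benefit): the payoff has a
  unique interior maximum and the optimal response is *graded*, tracking the
  nutrient level continuously.
- alpha < gamma (cost strictly concave relative to benefit): the payoff has
  no interior maximum for nonnegative enzyme, so the optimum sits on the
  boundary {0, E_max} — all-or-none *thresholding* at the nutrient level
  where the payoff at E_max changes sign.
- alpha == gamma: payoff is linear in E**alpha; degenerate boundary case,
  handled as thresholding.
"""

from __future__ import annotations

import enum

import numpy as np

from .payoff import payoff
from .specs import PayoffSpec
from .tables import StrategyTable

__all__ = [
    "ResponseClass",
    "classify_response",
    "optimal_enzyme_graded",
    "optimal_enzyme_threshold",
    "threshold_nutrient_level",
    "static_optimal_enzyme",
    "perfect_strategy",
]


class ResponseClass(enum.Enum):
    GRADED = "graded"
    THRESHOLDING = "thresholding"
    DEGENERATE_LINEAR = "degenerate_linear"


def classify_response(alpha: float, gamma: float = 1.0) -> ResponseClass:
    """Classify the optimal response from the cost/benefit exponents."""
    if alpha <= 0 or gamma <= 0:
        raise ValueError("alpha and gamma must be positive")
    if alpha > gamma:
        return ResponseClass.GRADED
    if alpha < gamma:
        return ResponseClass.THRESHOLDING
    return ResponseClass.DEGENERATE_LINEAR


def _benefit_slope(spec: PayoffSpec, S: np.ndarray) -> np.ndarray:
    """Coefficient u(S) in benefit = u(S) * E**gamma."""
    if spec.benefit_mode == "linear":
        return spec.b * S
    if spec.benefit_mode == "michaelis_menten":
        return spec.b * S / (spec.K_M + S)
    return spec.b * S  # power_law


def optimal_enzyme_graded(spec: PayoffSpec, S):
    """Interior payoff maximizer for the graded (alpha > gamma) class.

    Setting the E-derivative of u(S)*E**gamma - c*E**alpha to zero gives
    E* = (gamma * u(S) / (alpha * c)) ** (1 / (alpha - gamma)), clamped to
    [0, E_max].  For benefit linear in enzyme (gamma = 1) this is the
    familiar E* = (u(S) / (alpha * c)) ** (1 / (alpha - 1)).
    """
    if classify_response(spec.alpha, spec.gamma) is not ResponseClass.GRADED:
        raise ValueError("optimal_enzyme_graded requires alpha > gamma")
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("S must be nonnegative")
    u = _benefit_slope(spec, S)
    E = (spec.gamma * u / (spec.alpha * spec.c)) ** (1.0 / (spec.alpha - spec.gamma))
    E = np.clip(E, 0.0, spec.E_max)
    return E if E.ndim else float(E)


def threshold_nutrient_level(spec: PayoffSpec) -> float:
    """Nutrient level S_t at which payoff(E_max, S_t) = 0 (linear benefit).

    For benefit b*E*S and cost c*E**alpha at E = E_max:
    S_t = (c / b) * E_max ** (alpha - 1).
    """
    if not np.isfinite(spec.E_max):
        raise ValueError("threshold requires a finite E_max")
    if spec.benefit_mode == "linear":
        return (spec.c / spec.b) * spec.E_max ** (spec.alpha - 1.0)
    if spec.benefit_mode == "michaelis_menten":
        # solve b*S/(K_M+S) = c*E_max**(alpha-1) for S
        r = (spec.c / spec.b) * spec.E_max ** (spec.alpha - 1.0)
        if r >= 1.0:
            return np.inf  # benefit saturates below cost: never profitable
        return spec.K_M * r / (1.0 - r)
    # power_law: b*S*E**gamma = c*E**alpha at E_max
    return (spec.c / spec.b) * spec.E_max ** (spec.alpha - spec.gamma)


def optimal_enzyme_threshold(spec: PayoffSpec, S):
    """Boundary optimum for the thresholding (alpha <= gamma) class.

    Returns E_max where payoff(E_max, S) > 0 and 0 otherwise.  At the exact
    threshold the two boundary payoffs tie at zero and the parsimonious
    choice of zero enzyme is returned.
    """
    if classify_response(spec.alpha, spec.gamma) is ResponseClass.GRADED:
        raise ValueError("optimal_enzyme_threshold requires alpha <= gamma")
    if not np.isfinite(spec.E_max):
        raise ValueError("thresholding requires a finite E_max")
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("S must be nonnegative")
    on = np.asarray(payoff(spec, spec.E_max, S)) > 0
    E = np.where(on, spec.E_max, 0.0)
    return E if E.ndim else float(E)


def static_optimal_enzyme(spec: PayoffSpec, S):
    """Optimal enzyme level E*(S) under perfect measurement (dispatch)."""
    if classify_response(spec.alpha, spec.gamma) is ResponseClass.GRADED:
        return optimal_enzyme_graded(spec, S)
    return optimal_enzyme_threshold(spec, S)


def perfect_strategy(spec: PayoffSpec, grid) -> StrategyTable:
    """Tabulate the perfect-measurement optimal strategy E*(S) on a grid."""
    grid = np.asarray(grid, dtype=float)
    levels = np.asarray(static_optimal_enzyme(spec, grid), dtype=float)
    meta = {
        "strategy": "perfect",
        "payoff": spec.to_dict(),
        "response_class": classify_response(spec.alpha, spec.gamma).value,
        "E_max": spec.E_max,
    }
    return StrategyTable(grid=grid, levels=levels, meta=meta)
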