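"""Benefit, cost, and net payoff of an enzyme level in a given environment.

The payoff P(E, S) = B(E, S) - C(E) is the instantaneous fitness currency of
the model: downstream product generated by enzyme-catalyzed metabolism of
the nutrient, minus the cost of synthesizing the enzyme.
"""

from __future__ import annotations

import numpy as np

from .specs import PayoffSpec

__all__ = ["benefit", "cost", "payoff"]


def _check_nonneg(name: str, x: np.ndarray) -> None:
    if np.any(np.asarray(x) < 0):
        raise ValueError(f"{name} must be nonnegative")


def benefit(spec: PayoffSpec, E, S):
    """Metabolic benefit B(E, S).

    Linear mode: b*E*S; Michaelis-Menten: b*E*S/(K_M + S); power-law:
    b*S*E**gamma.  Monotone nondecreasing in both arguments.  Scalar in,
    scalar out; arrays broadcast.
    """
    E = np.asarray(E, dtype=float)
    S = np.asarray(S, dtype=float)
    _check_nonneg("E", E)
    _check_nonneg("S", S)
    if spec.benefit_mode == "linear":
        out = spec.b * E * S
    elif spec.benefit_mode == "michaelis_menten":
        out = spec.b * E * S / (spec.K_M + S)
    else:  # power_law
        out = spec.b * S * E**spec.gamma
    return out if out.ndim else float(out)


def cost(spec: PayoffSpec, E):
    """Enzyme production cost C(E) = c * E**alpha; C(0) = 0."""
    E = np.asarray(E, dtype=float)
    _check_nonneg("E", E)
    out = spec.c * E**spec.alpha
    return out if out.ndim else float(out)


def payoff(spec: PayoffSpec, E, S):
    """Net payoff P(E, S) = benefit - cost; may be negative."""
    out = np.asarray(benefit(spec, E, S)) - np.asarray(cost(spec, E))
    return out if out.ndim else float(out)
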