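"""Parameter containers for the enzyme-regulation decision problem.

Each dataclass is a frozen value object holding one ingredient of the model:
the payoff (cost/benefit) family, the environmental nutrient prior (static
Gaussian or Gaussian mixture, or a mean-reverting Markov chain), and the
measurement-noise model.  All containers validate on construction and
round-trip through plain dictionaries for YAML/JSON configuration files.

Units: concentrations (nutrient S, enzyme E) are in arbitrary consistent
units; the regime structure of the model depends only on dimensionless
ratios such as beta = sigma_m^2 / sigma_E^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "BENEFIT_MODES",
    "PayoffSpec",
    "MeasurementModel",
    "GaussianPrior",
    "MixturePrior",
    "MarkovEnvSpec",
    "RegimeParams",
]

BENEFIT_MODES = ("linear", "michaelis_menten", "power_law")


def _require_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be positive, got {value!r}")


@dataclass(frozen=True)
class PayoffSpec:
    """Benefit and cost model for a single metabolic enzyme.

    The benefit of expressing enzyme at level E when the nutrient is at
    concentration S is, depending on ``benefit_mode``:

    - ``linear``:            b * E * S            (unsaturated kinetics)
    - ``michaelis_menten``:  b * E * S / (K_M + S)
    - ``power_law``:         b * S * E**gamma

    The production cost is the power law c * E**alpha.  The exponent pair
    (alpha, gamma) controls whether cost is convex or concave *relative to*
    benefit in E, which in turn decides graded versus thresholded optimal
    regulation.  ``gamma`` is fixed at 1 for the linear and Michaelis-Menten
    modes, where benefit is linear in enzyme.

    Parameters
    ----------
    benefit_mode : {"linear", "michaelis_menten", "power_law"}
    b : float
        Benefit rate coefficient (product per enzyme per nutrient per time).
    K_M : float
        Michaelis constant, nutrient-concentration units.
    c : float
        Cost coefficient.
    alpha : float
        Cost exponent (> 0).  alpha > gamma: graded response optimal;
        alpha < gamma: thresholding optimal.
    gamma : float
        Benefit exponent in enzyme (> 0); must be 1 except in power_law mode.
    E_max : float
        Maximal producible enzyme level; may be ``inf`` for graded analyses
        but must be finite whenever thresholding applies (alpha <= gamma).
    """

    benefit_mode: str = "linear"
    b: float = 1.0
    K_M: float = 1.0
    c: float = 1.0
    alpha: float = 2.0
    gamma: float = 1.0
    E_max: float = math.inf

    def __post_init__(self) -> None:
        if self.benefit_mode not in BENEFIT_MODES:
            raise ValueError(
                f"benefit_mode must be one of {BENEFIT_MODES}, got {self.benefit_mode!r}"
            )
        for name in ("b", "K_M", "c", "alpha", "gamma", "E_max"):
            _require_positive(name, getattr(self, name))
        if self.benefit_mode in ("linear", "michaelis_menten") and self.gamma != 1.0:
            raise ValueError(
                f"gamma must be 1 for benefit_mode={self.benefit_mode!r}, got {self.gamma!r}"
            )

    def to_dict(self) -> dict:
        return {
            "benefit_mode": self.benefit_mode,
            "b": self.b,
            "K_M": self.K_M,
            "c": self.c,
            "alpha": self.alpha,
            "gamma": self.gamma,
            "E_max": self.E_max if math.isfinite(self.E_max) else "inf",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PayoffSpec":
        d = dict(d)
        if str(d.get("E_max", "inf")).lower() in ("inf", "infinity", ".inf"):
            d["E_max"] = math.inf
        return cls(**d)


@dataclass(frozen=True)
class MeasurementModel:
    """Unbiased Gaussian readout noise: m = S + eps, eps ~ N(0, sigma_m^2).

    ``sigma_m = 0`` is the perfect-measurement limit.
    """

    sigma_m: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_m < 0:
            raise ValueError(f"sigma_m must be >= 0, got {self.sigma_m!r}")

    def to_dict(self) -> dict:
        return {"sigma_m": self.sigma_m}

    @classmethod
    def from_dict(cls, d: dict) -> "MeasurementModel":
        return cls(**d)


@dataclass(frozen=True)
class GaussianPrior:
    """Static Gaussian environment: S ~ N(mu, sigma_E^2) i.i.d. in time."""

    mu: float = 0.0
    sigma_E: float = 1.0

    def __post_init__(self) -> None:
        _require_positive("sigma_E", self.sigma_E)

    def to_dict(self) -> dict:
        return {"mu": self.mu, "sigma_E": self.sigma_E}

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianPrior":
        return cls(**d)


@dataclass(frozen=True)
class MixturePrior:
    """Gaussian-mixture environment prior.

    ``components`` is a sequence of (weight, mean, sigma) triples.  The
    canonical bimodal environment of the theory is two equiprobable
    components with equal sigma, separated by ``delta_mu``; use
    :meth:`bimodal` to build it.
    """

    components: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        comps = tuple((float(p), float(mu), float(s)) for p, mu, s in self.components)
        object.__setattr__(self, "components", comps)
        if not comps:
            raise ValueError("MixturePrior requires at least one component")
        total = sum(p for p, _, _ in comps)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"component weights must sum to 1, got {total!r}")
        for p, _, s in comps:
            if p < 0:
                raise ValueError("component weights must be nonnegative")
            _require_positive("component sigma", s)

    @classmethod
    def bimodal(cls, mu_bar: float, delta_mu: float, sigma: float) -> "MixturePrior":
        """Equiprobable two-Gaussian mixture with means mu_bar +/- delta_mu/2."""
        if delta_mu < 0:
            raise ValueError("delta_mu must be >= 0")
        half = 0.5 * delta_mu
        return cls(components=((0.5, mu_bar - half, sigma), (0.5, mu_bar + half, sigma)))

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def weights(self):
        return tuple(p for p, _, _ in self.components)

    @property
    def means(self):
        return tuple(mu for _, mu, _ in self.components)

    @property
    def sigmas(self):
        return tuple(s for _, _, s in self.components)

    @property
    def mu_bar(self) -> float:
        """Overall environmental mean."""
        return sum(p * mu for p, mu, _ in self.components)

    @property
    def is_bimodal(self) -> bool:
        """Two equiprobable components with a common sigma."""
        if self.n_components != 2:
            return False
        (p1, _, s1), (p2, _, s2) = self.components
        return abs(p1 - 0.5) < 1e-12 and abs(p2 - 0.5) < 1e-12 and abs(s1 - s2) < 1e-12

    @property
    def delta_mu(self) -> float:
        """Separation of the two mode means (bimodal case)."""
        if self.n_components != 2:
            raise ValueError("delta_mu is defined for two-component mixtures only")
        return abs(self.components[1][1] - self.components[0][1])

    def to_dict(self) -> dict:
        return {
            "components": [
                {"weight": p, "mu": mu, "sigma": s} for p, mu, s in self.components
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixturePrior":
        comps = tuple(
            (c["weight"], c["mu"], c["sigma"]) for c in d["components"]
        )
        return cls(components=comps)


@dataclass(frozen=True)
class MarkovEnvSpec:
    """Stationary mean-reverting discrete-time (AR(1)) environment.

    Conditional law: S_t | S_{t-1} ~ N(lam * S_{t-1} + (1 - lam) * mu,
    sigma_d^2) with innovation variance sigma_d^2 = (1 - lam^2) * sigma_E^2,
    so the marginal N(mu, sigma_E^2) is constant in time and the lag-k
    autocorrelation is lam^k.  The persistence lam lies in [0, 1); lam = 1
    (a plain random walk) has no stationary law and is excluded.
    """

    mu: float = 0.0
    sigma_E: float = 1.0
    lam: float = 0.5

    def __post_init__(self) -> None:
        _require_positive("sigma_E", self.sigma_E)
        if not (0.0 <= self.lam < 1.0):
            raise ValueError(f"lam must lie in [0, 1), got {self.lam!r}")

    @property
    def sigma_d(self) -> float:
        """Innovation standard deviation enforcing stationarity."""
        return self.sigma_E * math.sqrt(1.0 - self.lam**2)

    @property
    def stationary_prior(self) -> GaussianPrior:
        """Marginal (stationary) distribution of the chain."""
        return GaussianPrior(mu=self.mu, sigma_E=self.sigma_E)

    def autocorrelation(self, lag: int) -> float:
        return self.lam ** abs(int(lag))

    def to_dict(self) -> dict:
        return {"mu": self.mu, "sigma_E": self.sigma_E, "lam": self.lam}

    @classmethod
    def from_dict(cls, d: dict) -> "MarkovEnvSpec":
        return cls(**d)


@dataclass(frozen=True)
class RegimeParams:
    """Dimensionless regime coordinates.

    beta = sigma_m^2 / sigma_E^2 is the inverse signal-to-noise ratio for a
    unimodal environment; xi is the mode-distinguishability parameter for a
    bimodal environment.  Exactly one of the two is typically relevant.
    """

    beta: float | None = None
    xi: float | None = None

    def __post_init__(self) -> None:
        if self.beta is None and self.xi is None:
            raise ValueError("provide beta (unimodal) or xi (bimodal)")
        for name in ("beta", "xi"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v!r}")
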