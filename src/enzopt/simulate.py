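"""Synthetic environments and noisy readouts.

Generates i.i.d. draws from the static priors, stationary AR(1) nutrient
trajectories, and Gaussian-corrupted readouts.  Environment and measurement
noise use independent seed-derived substreams, so the measurement noise
level can be varied while holding the environmental path fixed (useful for
paired comparisons of inference strategies).  Everything is reproducible
bit-exactly from (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .specs import GaussianPrior, MarkovEnvSpec, MeasurementModel, MixturePrior

__all__ = [
    "Trajectory",
    "sample_static",
    "simulate_trajectory",
    "add_measurements",
    "simulate_with_readouts",
]


def _substreams(seed: int, n: int = 2):
    """Independent child generators derived from one seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


@dataclass
class Trajectory:
    """A simulated nutrient path with optional readouts."""

    S: np.ndarray
    m: np.ndarray | None = None
    seed: int | None = None
    spec: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if self.m is not None:
            self.m = np.asarray(self.m, dtype=float)
            if self.m.shape != self.S.shape:
                raise ValueError("S and m must have equal lengths")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.S.size)

    def __len__(self) -> int:
        return self.S.size

    def to_csv(self, path) -> None:
        cols = {"step": self.times, "S": self.S}
        if self.m is not None:
            cols["m"] = self.m
        pd.DataFrame(cols).to_csv(path, index=False)
        meta = {"seed": self.seed, "spec": self.spec}
        Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2, default=str))

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        meta_file = Path(str(path) + ".meta.json")
        meta = json.loads(meta_file.read_text()) if meta_file.exists() else {}
        return cls(
            S=df["S"].to_numpy(),
            m=df["m"].to_numpy() if "m" in df else None,
            seed=meta.get("seed"),
            spec=meta.get("spec", {}),
        )


def sample_static(prior, n: int, seed: int) -> np.ndarray:
    """i.i.d. nutrient levels from a static prior (Gaussian or mixture)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _substreams(seed, 1)[0]
    if isinstance(prior, GaussianPrior):
        return rng.normal(prior.mu, prior.sigma_E, size=n)
    if isinstance(prior, MixturePrior):
        idx = rng.choice(prior.n_components, size=n, p=np.array(prior.weights))
        mu = np.array(prior.means)[idx]
        sig = np.array(prior.sigmas)[idx]
        return rng.normal(mu, sig)
    raise TypeError(f"unsupported prior type: {type(prior).__name__}")


def simulate_trajectory(env: MarkovEnvSpec, n_steps: int, seed: int) -> Trajectory:
    """Stationary AR(1) nutrient trajectory of length n_steps.

    S_0 is drawn from the stationary marginal N(mu, sigma_E^2); thereafter
    S_t | S_{t-1} ~ N(lam*S_{t-1} + (1-lam)*mu, sigma_d^2).  The recursion
    runs as a linear filter over the innovations, so long paths are cheap.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    env_rng, _ = _substreams(seed)
    x = np.empty(n_steps)
    x[0] = env_rng.normal(0.0, env.sigma_E)
    if n_steps > 1:
        eta = env_rng.normal(0.0, env.sigma_d, size=n_steps - 1)
        x[1:], _ = lfilter([1.0], [1.0, -env.lam], eta, zi=np.array([env.lam * x[0]]))
    return Trajectory(S=env.mu + x, seed=seed, spec={"environment": env.to_dict()})


def add_measurements(S, meas: MeasurementModel, seed: int) -> np.ndarray:
    """Gaussian-corrupted readouts m_i = S_i + eps_i, eps ~ N(0, sigma_m^2).

    Uses the measurement substream of ``seed``, independent of the
    environment substream consumed by :func:`simulate_trajectory`.
    """
    S = np.asarray(S, dtype=float)
    if meas.sigma_m == 0.0:
        return S.copy()
    _, meas_rng = _substreams(seed)
    return S + meas_rng.normal(0.0, meas.sigma_m, size=S.shape)


def simulate_with_readouts(
    env: MarkovEnvSpec, meas: MeasurementModel, n_steps: int, seed: int
) -> Trajectory:
    """Trajectory plus readouts from the two independent substreams of seed."""
    traj = simulate_trajectory(env, n_steps, seed)
    traj.m = add_measurements(traj.S, meas, seed)
    traj.spec["measurement"] = meas.to_dict()
    return traj
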