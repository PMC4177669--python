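"""Tabulated regulatory strategies with an interpolation contract.

A regulatory strategy maps a readout (or a pair of readouts, for one-step
memory) to an enzyme level.  Strategies are tabulated on grids and
interpolated linearly between nodes; readouts outside the grid clamp to the
edge levels.  Tables round-trip to CSV with a JSON metadata sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

__all__ = ["StrategyTable", "StrategyTable2D", "apply_strategy"]


def _meta_path(path) -> Path:
    return Path(str(path) + ".meta.json")


def _validate_grid(name: str, grid: np.ndarray) -> None:
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError(f"{name} must be a 1-D grid with at least 2 nodes")
    if np.any(np.diff(grid) <= 0):
        raise ValueError(f"{name} must be strictly increasing")


@dataclass
class StrategyTable:
    """Enzyme level as a function of a single readout, tabulated on a grid."""

    grid: np.ndarray
    levels: np.ndarray
    meta: dict = field(default_factory=dict)

    n_inputs = 1

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.levels = np.asarray(self.levels, dtype=float)
        _validate_grid("grid", self.grid)
        if self.levels.shape != self.grid.shape:
            raise ValueError("grid and levels must have matching shapes")
        if np.any(self.levels < 0):
            raise ValueError("enzyme levels must be nonnegative")
        e_max = self.meta.get("E_max")
        if e_max is not None and np.any(self.levels > float(e_max) + 1e-12):
            raise ValueError("enzyme levels exceed E_max")

    def __call__(self, m):
        """Interpolate the enzyme level at readout(s) m (edge-clamped)."""
        out = np.interp(np.asarray(m, dtype=float), self.grid, self.levels)
        return out if out.ndim else float(out)

    def to_csv(self, path) -> None:
        pd.DataFrame({"readout": self.grid, "enzyme_level": self.levels}).to_csv(
            path, index=False
        )
        _meta_path(path).write_text(json.dumps(self.meta, indent=2, default=str))

    @classmethod
    def from_csv(cls, path) -> "StrategyTable":
        df = pd.read_csv(path)
        meta_file = _meta_path(path)
        meta = json.loads(meta_file.read_text()) if meta_file.exists() else {}
        return cls(
            grid=df["readout"].to_numpy(),
            levels=df["enzyme_level"].to_numpy(),
            meta=meta,
        )


@dataclass
class StrategyTable2D:
    """Enzyme level as a function of (current, previous) readouts.

    ``levels[i, j]`` is the enzyme level at ``(grid_t[i], grid_prev[j])``;
    evaluation is bilinear with edge clamping.  Serializes to long-format
    CSV with columns (m_t, m_prev, enzyme_level).
    """

    grid_t: np.ndarray
    grid_prev: np.ndarray
    levels: np.ndarray
    meta: dict = field(default_factory=dict)

    n_inputs = 2

    def __post_init__(self) -> None:
        self.grid_t = np.asarray(self.grid_t, dtype=float)
        self.grid_prev = np.asarray(self.grid_prev, dtype=float)
        self.levels = np.asarray(self.levels, dtype=float)
        _validate_grid("grid_t", self.grid_t)
        _validate_grid("grid_prev", self.grid_prev)
        if self.levels.shape != (self.grid_t.size, self.grid_prev.size):
            raise ValueError("levels must have shape (len(grid_t), len(grid_prev))")
        if np.any(self.levels < 0):
            raise ValueError("enzyme levels must be nonnegative")
        self._interp = RegularGridInterpolator(
            (self.grid_t, self.grid_prev), self.levels, method="linear"
        )

    def __call__(self, m_t, m_prev):
        m_t = np.clip(np.asarray(m_t, dtype=float), self.grid_t[0], self.grid_t[-1])
        m_prev = np.clip(
            np.asarray(m_prev, dtype=float), self.grid_prev[0], self.grid_prev[-1]
        )
        pts = np.stack(np.broadcast_arrays(m_t, m_prev), axis=-1)
        out = self._interp(pts)
        return out if out.ndim else float(out)

    def to_csv(self, path) -> None:
        tt, pp = np.meshgrid(self.grid_t, self.grid_prev, indexing="ij")
        pd.DataFrame(
            {
                "m_t": tt.ravel(),
                "m_prev": pp.ravel(),
                "enzyme_level": self.levels.ravel(),
            }
        ).to_csv(path, index=False)
        _meta_path(path).write_text(json.dumps(self.meta, indent=2, default=str))

    @classmethod
    def from_csv(cls, path) -> "StrategyTable2D":
        df = pd.read_csv(path)
        grid_t = np.unique(df["m_t"].to_numpy())
        grid_prev = np.unique(df["m_prev"].to_numpy())
        levels = (
            df.sort_values(["m_t", "m_prev"])["enzyme_level"]
            .to_numpy()
            .reshape(grid_t.size, grid_prev.size)
        )
        meta_file = _meta_path(path)
        meta = json.loads(meta_file.read_text()) if meta_file.exists() else {}
        return cls(grid_t=grid_t, grid_prev=grid_prev, levels=levels, meta=meta)


def apply_strategy(strategy, m, m_prev=None, m_prev2=None):
    """Evaluate a strategy (table or fitted estimator) on readout arrays.

    Accepts anything callable on its readout arguments, or an object with a
    scikit-learn ``predict`` taking stacked readout columns.
    """
    args = [a for a in (m, m_prev, m_prev2) if a is not None]
    n_inputs = getattr(strategy, "n_inputs", len(args))
    args = args[:n_inputs]
    if hasattr(strategy, "predict"):
        X = np.column_stack([np.atleast_1d(np.asarray(a, float)) for a in args])
        return strategy.predict(X)
    return strategy(*args)
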