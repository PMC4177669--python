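"""YAML/JSON configuration for model specifications.

A configuration file holds up to four blocks — ``payoff``, ``prior``,
``measurement``, ``environment`` — each mapping directly onto a container
in :mod:`enzopt.specs`.  The ``prior`` block carries a ``kind`` key
('gaussian', 'bimodal', or 'mixture').  Example::

    payoff: {benefit_mode: linear, b: 1.0, c: 1.0, alpha: 2.0}
    prior: {kind: gaussian, mu: 1.0, sigma_E: 1.0}
    measurement: {sigma_m: 0.5}
    environment: {mu: 1.0, sigma_E: 1.0, lam: 0.9}
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .specs import (
    GaussianPrior,
    MarkovEnvSpec,
    MeasurementModel,
    MixturePrior,
    PayoffSpec,
)

__all__ = ["prior_from_dict", "prior_to_dict", "parse_config", "load_config", "save_config"]


def prior_from_dict(d: dict):
    """Build a static prior from a config block with a 'kind' key."""
    d = dict(d)
    kind = d.pop("kind", "gaussian")
    if kind == "gaussian":
        return GaussianPrior.from_dict(d)
    if kind == "bimodal":
        return MixturePrior.bimodal(**d)
    if kind == "mixture":
        return MixturePrior.from_dict(d)
    raise ValueError(f"unknown prior kind: {kind!r}")


def prior_to_dict(prior) -> dict:
    if isinstance(prior, GaussianPrior):
        return {"kind": "gaussian", **prior.to_dict()}
    if isinstance(prior, MixturePrior):
        return {"kind": "mixture", **prior.to_dict()}
    raise TypeError(f"unsupported prior type: {type(prior).__name__}")


def parse_config(raw: dict) -> dict:
    """Convert raw config blocks into spec objects (missing blocks → None)."""
    out = {}
    out["payoff"] = PayoffSpec.from_dict(raw["payoff"]) if "payoff" in raw else None
    out["prior"] = prior_from_dict(raw["prior"]) if "prior" in raw else None
    out["measurement"] = (
        MeasurementModel.from_dict(raw["measurement"]) if "measurement" in raw else None
    )
    out["environment"] = (
        MarkovEnvSpec.from_dict(raw["environment"]) if "environment" in raw else None
    )
    return out


def load_config(path) -> dict:
    """Read a YAML or JSON config file into spec objects."""
    text = Path(path).read_text()
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return parse_config(raw or {})


def save_config(path, payoff=None, prior=None, measurement=None, environment=None) -> None:
    """Write spec objects back to a YAML or JSON config file."""
    raw: dict = {}
    if payoff is not None:
        raw["payoff"] = payoff.to_dict()
    if prior is not None:
        raw["prior"] = prior_to_dict(prior)
    if measurement is not None:
        raw["measurement"] = measurement.to_dict()
    if environment is not None:
        raw["environment"] = environment.to_dict()
    path = Path(path)
    if str(path).endswith(".json"):
        path.write_text(json.dumps(raw, indent=2))
    else:
        path.write_text(yaml.safe_dump(raw, sort_keys=False))
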