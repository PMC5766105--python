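"""YAML/JSON configuration for the simulator and the fitting defaults.

A config file supplies :class:`sightabund.synthgen.TruthConfig` fields
(any omitted field keeps its default) and, optionally, an ``mcmc``
section with :class:`sightabund.twostep.MCMCConfig` fields and a
``priors`` section with :class:`sightabund.hierarchical.PriorConfig`
fields.
"""
from __future__ import annotations

import json
from pathlib import Path

import yaml

from .hierarchical import PriorConfig
from .synthgen import TruthConfig
from .twostep import MCMCConfig

__all__ = ["load_config", "load_truth_config"]


def _read(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}


def load_truth_config(path) -> TruthConfig:
    raw = dict(_read(path))
    raw.pop("mcmc", None)
    raw.pop("priors", None)
    return TruthConfig(**raw)


def load_config(path) -> tuple[TruthConfig, MCMCConfig, PriorConfig]:
    """Load (truth, mcmc, priors) from one YAML/JSON file."""
    raw = dict(_read(path))
    mcmc = MCMCConfig(**raw.pop("mcmc", {}))
    pr = raw.pop("priors", {})
    for k in ("mu_bounds", "rho_bounds"):
        if k in pr:
            pr[k] = tuple(pr[k])
    priors = PriorConfig(**pr)
    truth = TruthConfig(**raw) if raw else TruthConfig()
    return truth, mcmc, priors
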