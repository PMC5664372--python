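"""Flat parameter configs: load from JSON/YAML, merge CLI overrides, validate."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .model import CodeAttrition, CohortSpec, GeneticArchitecture

__all__ = ["PARAM_KEYS", "DEFAULTS", "load_config", "merge_params", "build_model"]

PARAM_KEYS = ("q", "R", "n1", "m", "delta", "epsilon", "alpha")

DEFAULTS = {"alpha": 0.05}


def load_config(path: str | Path) -> dict:
    """Read a flat JSON or YAML mapping with keys among q, R, n1, m, delta, epsilon, alpha."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {p}")
    text = p.read_text()
    data = json.loads(text) if p.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config must be a flat mapping, got {type(data).__name__}")
    unknown = set(data) - set(PARAM_KEYS)
    if unknown:
        raise ValueError(
            f"unknown config keys {sorted(unknown)}; valid keys: {', '.join(PARAM_KEYS)}"
        )
    return {k: float(v) for k, v in data.items()}


def merge_params(config: dict | None, overrides: dict) -> dict:
    """Defaults < config file < explicit CLI flags; None overrides are ignored."""
    params = dict(DEFAULTS)
    if config:
        params.update(config)
    params.update({k: float(v) for k, v in overrides.items() if v is not None})
    missing = [k for k in PARAM_KEYS if k not in params]
    if missing:
        raise ValueError(f"missing required parameters: {', '.join(missing)}")
    return {k: params[k] for k in PARAM_KEYS}


def build_model(params: dict) -> tuple[GeneticArchitecture, CohortSpec, CodeAttrition, float]:
    """Validate a flat parameter dict into the three model objects plus alpha."""
    gen = GeneticArchitecture(q=params["q"], R=params["R"])
    cohort = CohortSpec(n1=params["n1"], m=params["m"])
    attrition = CodeAttrition(delta=params["delta"], epsilon=params["epsilon"])
    alpha = params["alpha"]
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return gen, cohort, attrition, alpha
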