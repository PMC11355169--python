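"""Run configuration: strict YAML/JSON parsing with defaults.

Unknown keys anywhere in the document are rejected (with their full key
paths) so a typo can never silently fall back to a default.  Every block is
optional; a minimal file containing only ``seed: 1`` yields a fully
defaulted configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .exceptions import ConfigError
from .logistic import (
    FactorFunction,
    GrowthAggregate,
    RemodelingLumen,
    factor_constant,
    factor_linear,
    factor_saturating,
)
from .markov import TransitionWeights

logger = logging.getLogger("plaquedyn")

__all__ = ["RunConfig", "load_config", "dump_config", "make_factor"]

# Default value of every recognized key, organized exactly as the file is.
_SCHEMA: dict[str, Any] = {
    "seed": 0,
    "output_dir": ".",
    "log_level": "INFO",
    "growth": {
        "alpha": 1.0,
        "betas": [0.0, 0.0, 0.0, 0.0],
        "factors": [
            {"kind": "constant", "value": 1.0},
            {"kind": "constant", "value": 1.0},
            {"kind": "constant", "value": 1.0},
            {"kind": "constant", "value": 1.0},
        ],
        "lower_bound": 1.0,
        "increment": 0.0,
        "increment_mode": "additive",
    },
    "lumen": {"A0": 1.0, "Amax": 1.0, "rate": 0.0},
    "simulate": {"P0": 0.1, "n_visits": 60, "seed": None},
    "markov": {
        "base": 0.1,
        "w1": 0.0,
        "w2": 0.0,
        "w3": 0.0,
        "w4": 0.0,
        "w5": 0.0,
        "p_us": 0.3,
        "hazard_su": 0.5,
        "link": "linear",
    },
    "spatial": {
        "kernel": "uniform",
        "range_param": 1.0,
        "adjacency": "von_neumann",
        "periodic": False,
        "update_mode": "synchronous",
    },
    "mrf": {
        "v_u": 0.0,
        "J": 0.0,
        "beta_temp": 1.0,
        "sweeps": 5000,
        "burn_in": 1000,
    },
    "fixtures": {
        "series": {
            "n_visits": 50,
            "P0": 0.1,
            "r_constant": 1.8,
            "r0": None,
            "r_increment": 0.0,
            "noise_sd": 0.01,
            "patient_id": "synthetic-001",
        },
        "grid": {
            "height": 12,
            "width": 12,
            "means": {"I": 1.0, "L": 1.0, "S": 1.0, "B": 1.0},
            "noise_sd": 0.25,
            "correlation_range": 2,
            "hotspot": None,
        },
    },
}

# Keys whose value is a free-form container rather than a nested block.
_LEAF_CONTAINERS = {
    "growth.betas",
    "growth.factors",
    "fixtures.grid.means",
    "fixtures.grid.hotspot",
}


def _merge(schema: Any, data: Any, path: str, unknown: list[str], defaulted: list[str]) -> Any:
    if path in _LEAF_CONTAINERS or not isinstance(schema, dict):
        return data
    if not isinstance(data, dict):
        raise ConfigError(f"expected a mapping at {path or '<root>'}, got {type(data).__name__}")
    out = {}
    for key, default in schema.items():
        child = f"{path}.{key}" if path else key
        if key in data:
            out[key] = _merge(default, data[key], child, unknown, defaulted)
        else:
            out[key] = default
            defaulted.append(child)
    for key in data:
        if key not in schema:
            unknown.append(f"{path}.{key}" if path else key)
    return out


@dataclass
class RunConfig:
    """Validated run configuration with all defaults applied."""

    seed: int
    output_dir: str
    log_level: str
    growth: dict[str, Any]
    lumen: dict[str, Any]
    simulate: dict[str, Any]
    markov: dict[str, Any]
    spatial: dict[str, Any]
    mrf: dict[str, Any]
    fixtures: dict[str, Any]

    def as_dict(self) -> dict[str, Any]:
        return {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "log_level": self.log_level,
            "growth": self.growth,
            "lumen": self.lumen,
            "simulate": self.simulate,
            "markov": self.markov,
            "spatial": self.spatial,
            "mrf": self.mrf,
            "fixtures": self.fixtures,
        }

    def growth_aggregate(self) -> GrowthAggregate:
        g = self.growth
        return GrowthAggregate(
            alpha=float(g["alpha"]),
            betas=tuple(float(b) for b in g["betas"]),  # type: ignore[arg-type]
            factors=tuple(make_factor(spec) for spec in g["factors"]),
            r_lower_bound=None if g["lower_bound"] is None else float(g["lower_bound"]),
            r_update_increment=float(g["increment"]),
            increment_mode=g["increment_mode"],
        )

    def remodeling_lumen(self) -> RemodelingLumen:
        return RemodelingLumen(
            A0=float(self.lumen["A0"]),
            Amax=float(self.lumen["Amax"]),
            rate=float(self.lumen["rate"]),
        )

    def transition_weights(self) -> TransitionWeights:
        m = self.markov
        return TransitionWeights(
            base=float(m["base"]),
            w1=float(m["w1"]),
            w2=float(m["w2"]),
            w3=float(m["w3"]),
            w4=float(m["w4"]),
            w5=float(m["w5"]),
        )


def make_factor(spec: dict[str, Any]) -> FactorFunction:
    """Build a growth-aggregate factor function from its config spec.

    Recognized kinds: ``constant`` (value), ``linear`` (slope),
    ``saturating`` (k).
    """
    if not isinstance(spec, dict) or "kind" not in spec:
        raise ConfigError(f"factor spec {spec!r} must be a mapping with a 'kind'")
    kind = spec["kind"]
    if kind == "constant":
        return factor_constant(float(spec.get("value", 1.0)))
    if kind == "linear":
        return factor_linear(float(spec.get("slope", 1.0)))
    if kind == "saturating":
        return factor_saturating(float(spec.get("k", 0.5)))
    raise ConfigError(f"unknown factor kind {kind!r}")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON configuration file.

    Raises :class:`~plaquedyn.exceptions.ConfigError` listing every unknown
    key (with its full path); every key that fell back to a default is
    echoed to the ``plaquedyn`` logger at DEBUG level.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} does not exist")
    text = path.read_text()
    if path.suffix == ".json":
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    else:
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
    if data is None:
        data = {}
    unknown: list[str] = []
    defaulted: list[str] = []
    merged = _merge(_SCHEMA, data, "", unknown, defaulted)
    if unknown:
        raise ConfigError(
            f"{path}: unknown configuration key(s): " + ", ".join(sorted(unknown))
        )
    for key in defaulted:
        logger.debug("config: %s defaulted", key)
    return RunConfig(**merged)


def dump_config(config: RunConfig) -> str:
    """Serialize a configuration back to YAML (round-trips through
    :func:`load_config`)."""
    return yaml.safe_dump(config.as_dict(), sort_keys=False)
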