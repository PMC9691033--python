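"""Run configuration: YAML/JSON documents, schema validation, named parameter presets.

The presets carry the across-day mean fitted parameters for each animal and
model (the values behind the simulation defaults); the policy parameters
beta = 10 and epsilon = 0.02 are fixed everywhere and are not fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from ruleswitch.agents import HQLParams, IOParams, PolicyParams, QLParams
from ruleswitch.synthetic import SimulationConfig
from ruleswitch.task import DEFAULT_P_NEUTRAL

#: Mean fitted parameters per animal and model.
PARAMETER_PRESETS: dict[str, Any] = {
    "monkeyS_ql": QLParams(kappa_color=2.2, kappa_shape=1.3, alpha=0.23),
    "monkeyS_io": IOParams(kappa_color=2.4, kappa_shape=1.3, b1=0.091, b3=0.14),
    "monkeyS_hql": HQLParams(
        kappa_color=11.0,
        kappa_shape=5.1,
        alpha=0.23,
        b_ax=0.29,
        eta=0.046,
        w0=np.array([-0.61, 0.79, 0.77, -0.64, -0.83, 0.035, 0.74, 0.040]),
    ),
    "monkeyC_ql": QLParams(kappa_color=1.2, kappa_shape=0.71, alpha=0.18),
    "monkeyC_io": IOParams(kappa_color=1.3, kappa_shape=0.71, b1=0.35, b3=0.32),
    "monkeyC_hql": HQLParams(
        kappa_color=12.0,
        kappa_shape=7.0,
        alpha=0.12,
        b_ax=0.5,
        eta=0.067,
        w0=np.array([-0.45, 0.56, 0.60, -0.56, -0.83, -0.12, 0.70, -0.19]),
    ),
}

_PARAM_CLASSES = {"QL": QLParams, "IO": IOParams, "HQL": HQLParams}

_SCHEMA = {
    "seed": None,
    "task": {"criteria", "p_incongruent", "p_neutral", "blocks_per_day", "n_days"},
    "model": {"kind", "preset", "params"},
    "policy": {"beta", "epsilon"},
    "fit": {"n_particles", "n_starts", "maxiter", "xtol", "bounds", "free"},
    "analyze": {"window"},
}


class ConfigError(ValueError):
    """The configuration document violated the schema."""


@dataclass
class RunConfig:
    """Validated configuration with resolved model parameters."""

    seed: int
    model: str
    params: Any
    task: dict = field(default_factory=dict)
    policy: PolicyParams = field(default_factory=PolicyParams)
    fit: dict = field(default_factory=dict)
    analyze: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)

    def simulation_config(self) -> SimulationConfig:
        task = self.task
        return SimulationConfig(
            model=self.model,
            params=self.params,
            criteria=task.get("criteria", "monkey_S"),
            blocks_per_day=task.get("blocks_per_day", 14),
            p_incongruent=task.get("p_incongruent", 0.8),
            p_neutral=task.get("p_neutral", DEFAULT_P_NEUTRAL),
            policy=self.policy,
            seed=self.seed,
        )


def resolve_params(kind: Optional[str] = None, preset: Optional[str] = None,
                   params: Optional[dict] = None):
    """Model parameters from a preset name and/or explicit overrides."""
    if preset is not None:
        if preset not in PARAMETER_PRESETS:
            raise ConfigError(f"unknown preset {preset!r}; choose from {sorted(PARAMETER_PRESETS)}")
        base = PARAMETER_PRESETS[preset]
        kind = kind or {"QLParams": "QL", "IOParams": "IO", "HQLParams": "HQL"}[type(base).__name__]
        if params:
            merged = {**vars(base), **params}
            base = _PARAM_CLASSES[kind](**merged)
        return kind, base
    if kind is None or params is None:
        raise ConfigError("model section needs either a preset or both kind and params")
    if kind not in _PARAM_CLASSES:
        raise ConfigError(f"unknown model kind {kind!r}")
    return kind, _PARAM_CLASSES[kind](**params)


def _validate_sections(doc: dict, source: str) -> None:
    unknown_sections = set(doc) - set(_SCHEMA)
    if unknown_sections:
        raise ConfigError(f"{source}: unknown sections {sorted(unknown_sections)}")
    for section, allowed in _SCHEMA.items():
        if allowed is None or section not in doc:
            continue
        if not isinstance(doc[section], dict):
            raise ConfigError(f"{source}: section {section!r} must be a mapping")
        unknown = set(doc[section]) - allowed
        if unknown:
            raise ConfigError(f"{source}: unknown keys {sorted(unknown)} in section {section!r}")


def parse_config(doc: dict, source: str = "<config>") -> RunConfig:
    if not isinstance(doc, dict) or not doc:
        raise ConfigError(f"{source}: empty or non-mapping configuration")
    _validate_sections(doc, source)
    model_section = doc.get("model", {})
    kind, params = resolve_params(
        model_section.get("kind"), model_section.get("preset"), model_section.get("params")
    )
    policy = PolicyParams(**doc.get("policy", {}))
    return RunConfig(
        seed=int(doc.get("seed", 0)),
        model=kind,
        params=params,
        task=dict(doc.get("task", {})),
        policy=policy,
        fit=dict(doc.get("fit", {})),
        analyze=dict(doc.get("analyze", {})),
        raw=doc,
    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    doc = yaml.safe_load(text)
    if doc is None:
        raise ConfigError(f"{path}: empty configuration file")
    return parse_config(doc, str(path))


def dump_config(config: RunConfig) -> str:
    """Serialize the resolved configuration back to YAML (round-trips with load)."""
    return yaml.safe_dump(config.raw, sort_keys=True)
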