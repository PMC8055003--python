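"""Flat sectioned YAML configuration with strict key validation.

One section per module; every key must match a dataclass field (or a listed
run option) — unknown sections or keys are rejected by name so a typo never
silently falls back to a default.  Dotted overrides (``section.key=value``)
come from the command line.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .exceptions import ConfigError
from .feedback_model import FeedbackParams
from .population_sim import EvolutionParams, PassageRegime
from .synthetic_assays import QpcrAssay

__all__ = ["load_config", "apply_overrides", "build_feedback",
           "build_evolution", "build_regime", "build_qpcr", "SECTIONS"]

_RUN_KEYS = {"seed", "volume_fold", "replicates", "noise_cv", "n_reps",
             "t_end", "free_params", "n_boot", "ci_level", "log_residuals",
             "fold"}

SECTIONS: dict[str, set] = {
    "feedback": {f.name for f in dataclasses.fields(FeedbackParams)},
    "evolution": {f.name for f in dataclasses.fields(EvolutionParams)
                  if f.name != "feedback"},
    "regime": {f.name for f in dataclasses.fields(PassageRegime)},
    "qpcr": {f.name for f in dataclasses.fields(QpcrAssay)},
    "run": _RUN_KEYS,
}


def load_config(path) -> dict:
    """Read and validate a YAML config; returns {section: {key: value}}."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping of sections")
    validate(raw)
    return raw


def validate(cfg: dict) -> None:
    unknown = []
    for section, body in cfg.items():
        if section not in SECTIONS:
            unknown.append(section)
            continue
        if body is None:
            continue
        if not isinstance(body, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        for key in body:
            if key not in SECTIONS[section]:
                unknown.append(f"{section}.{key}")
    if unknown:
        raise ConfigError("unknown config keys: " + ", ".join(sorted(unknown)))


def apply_overrides(cfg: dict, overrides) -> dict:
    """Apply ``section.key=value`` strings; values parsed as YAML scalars."""
    out = {k: dict(v or {}) for k, v in cfg.items()}
    for item in overrides or ():
        if "=" not in item or "." not in item.split("=", 1)[0]:
            raise ConfigError(
                f"override {item!r} must have the form section.key=value")
        dotted, value = item.split("=", 1)
        section, key = dotted.split(".", 1)
        out.setdefault(section, {})[key] = yaml.safe_load(value)
    validate(out)
    return out


def build_feedback(cfg: dict) -> FeedbackParams:
    return FeedbackParams(**cfg.get("feedback", {}) or {})


def build_evolution(cfg: dict, feedback: FeedbackParams | None = None,
                    seed=None) -> EvolutionParams:
    body = dict(cfg.get("evolution", {}) or {})
    if seed is not None:
        body["seed"] = seed
    return EvolutionParams(feedback=feedback or build_feedback(cfg), **body)


def build_regime(cfg: dict) -> PassageRegime:
    return PassageRegime(**cfg.get("regime", {}) or {})


def build_qpcr(cfg: dict) -> QpcrAssay:
    return QpcrAssay(**cfg.get("qpcr", {}) or {})
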