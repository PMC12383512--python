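"""YAML run configuration for the command-line workflow.

One file describes a full run; every field maps onto a
:class:`~icsdm.workflow.StudyConfig` entry or an output setting.  Parsing
is strict: unknown keys and out-of-range values raise :class:`ConfigError`
naming the offending field, and all seeds are explicit (no wall-clock
seeding anywhere).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .grid import GridSpec
from .synthetic import EffortModel
from .workflow import StudyConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "config_hash"]


class ConfigError(ValueError):
    """A run configuration is malformed; the message names the field."""


@dataclass(frozen=True)
class RunConfig:
    study: StudyConfig = StudyConfig()
    out_dir: str = "runs/latest"
    allow_overlap: bool = False  # training/prediction year overlap
    verbosity: str = "info"

    def validate(self) -> "RunConfig":
        s = self.study
        if not self.allow_overlap and s.predict_year in s.train_years:
            raise ConfigError(
                "predict_year: overlaps train_years (set allow_overlap: true to permit)"
            )
        if not 0 < s.train_fraction < 1:
            raise ConfigError("validation.train_fraction: must be in (0, 1)")
        if s.iterations < 1:
            raise ConfigError("validation.iterations: must be >= 1")
        if s.rule not in ("geometric_mean", "min", "product"):
            raise ConfigError(f"analysis.rule: unknown combiner {s.rule!r}")
        return self


def _build(section: str, cls, payload: dict):
    allowed = {f.name for f in fields(cls)}
    unknown = set(payload) - allowed
    if unknown:
        raise ConfigError(f"{section}.{sorted(unknown)[0]}: unknown field")
    try:
        return cls(**payload)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{section}: {exc}") from exc


def load_config(path, seed: int | None = None, out_dir: str | None = None) -> RunConfig:
    """Read and validate a YAML config; CLI-supplied seed/out take precedence."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root: expected a mapping")

    known = {"grid", "study", "effort_a", "effort_b", "out_dir", "allow_overlap", "verbosity"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{sorted(unknown)[0]}: unknown top-level field")

    study_payload = dict(raw.get("study", {}))
    for key in ("train_years", "months"):
        if key in study_payload:
            study_payload[key] = tuple(study_payload[key])
    if "grid" in raw:
        study_payload["grid"] = _build("grid", GridSpec, raw["grid"])
    if "effort_a" in raw:
        study_payload["effort_a"] = _build("effort_a", EffortModel, raw["effort_a"])
    if "effort_b" in raw:
        study_payload["effort_b"] = _build("effort_b", EffortModel, raw["effort_b"])
    study = _build("study", StudyConfig, study_payload)
    if seed is not None:
        study = replace(study, seed=int(seed))

    cfg = RunConfig(
        study=study,
        out_dir=out_dir if out_dir is not None else raw.get("out_dir", "runs/latest"),
        allow_overlap=bool(raw.get("allow_overlap", False)),
        verbosity=str(raw.get("verbosity", "info")),
    )
    return cfg.validate()


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of everything that determines a run's outputs."""
    payload = json.dumps(asdict(cfg.study), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
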