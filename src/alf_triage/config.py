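"""YAML configuration loading for threshold overrides.

All decision thresholds (laboratory cutoffs, interval windows, score
weights, death-call threshold) live in the two frozen config dataclasses;
a YAML file may override any subset::

    classification:
      pt_max_percent: 40
      inr_min: 1.5
      acute_max_days: 10
      subacute_max_days: 56
      lohf_max_days: 168
      no_coma_max_weeks: 8
      indeterminate_is_hepatitis: true
      unclassified_is_hepatitis: false
    prognosis:
      death_threshold: 5
      atrophy_max_subscore: 1

Unknown keys are rejected, and the dataclasses re-validate every override
against its documented range.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Any

import yaml

from .classification import ClassificationConfig
from .errors import ConfigError
from .prognosis import PrognosisConfig

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    classification: ClassificationConfig = ClassificationConfig()
    prognosis: PrognosisConfig = PrognosisConfig()


def _build(cls: type, overrides: dict[str, Any], section: str) -> Any:
    allowed = {f.name for f in fields(cls)} - {"bands"}
    unknown = set(overrides) - allowed
    if unknown:
        raise ConfigError(f"unknown {section} config keys: {sorted(unknown)} "
                          f"(allowed: {sorted(allowed)})")
    return cls(**overrides)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a RunConfig from YAML; ``None`` gives the published defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text(encoding="utf-8")
    payload = yaml.safe_load(text) or {}
    if not isinstance(payload, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(payload) - {"classification", "prognosis"}
    if unknown:
        raise ConfigError(f"{path}: unknown sections {sorted(unknown)}")
    return RunConfig(
        classification=_build(ClassificationConfig,
                              payload.get("classification") or {}, "classification"),
        prognosis=_build(PrognosisConfig,
                         payload.get("prognosis") or {}, "prognosis"),
    )
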