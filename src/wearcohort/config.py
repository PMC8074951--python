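"""Serializable pipeline configuration (YAML/JSON).

A run is fully determined by its config plus seed: the same pair reproduces
the same simulated cohort, the same valid-day verdicts and the same report.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml

from .compare import CompareConfig
from .synthcohort import CohortConfig, LockdownEffect
from .validday import ValidDayConfig

__all__ = ["PipelineConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything tunable in one place, with the shipped defaults."""

    validday: ValidDayConfig = field(default_factory=ValidDayConfig)
    compare: CompareConfig = field(default_factory=CompareConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    min_days: int = 1
    seed: int = 0

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=seed, cohort=replace(self.cohort, seed=seed))

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        eff = d["cohort"]["lockdown_effect"]
        if eff is not None:
            eff["window_start"] = eff["window_start"].isoformat()
            eff["window_end"] = eff["window_end"].isoformat()
        d["compare"]["test_overrides"] = dict(d["compare"]["test_overrides"])
        return d


def _build(section: Mapping[str, Any] | None, cls, **nested):
    data = dict(section or {})
    data.update(nested)
    return cls(**data)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a pipeline config from YAML or JSON; ``None`` gives defaults."""
    if path is None:
        return PipelineConfig()
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    raw = raw or {}

    cohort_raw = dict(raw.get("cohort", {}))
    eff_raw = cohort_raw.pop("lockdown_effect", "default")
    if eff_raw is None:
        effect: Optional[LockdownEffect] = None
    elif eff_raw == "default":
        effect = LockdownEffect()
    else:
        eff_raw = dict(eff_raw)
        for key in ("window_start", "window_end"):
            if key in eff_raw and isinstance(eff_raw[key], str):
                eff_raw[key] = dt.date.fromisoformat(eff_raw[key])
        effect = LockdownEffect(**eff_raw)

    config = PipelineConfig(
        validday=_build(raw.get("validday"), ValidDayConfig),
        compare=_build(raw.get("compare"), CompareConfig),
        cohort=_build(cohort_raw, CohortConfig, lockdown_effect=effect),
        min_days=int(raw.get("min_days", 1)),
        seed=int(raw.get("seed", 0)),
    )
    if "seed" in raw and "seed" not in cohort_raw:
        config = config.with_seed(int(raw["seed"]))
    return config


def dump_config(config: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    return path
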