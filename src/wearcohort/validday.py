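"""Valid-day classification and MVPA derivation.

Daily tracker summaries only enter averages on days with enough wear time.
Because not every provider reports wear time directly, each ecosystem gets
its own proxy rule:

* **step floor** (Apple, Fitbit, Google Fit, Oura, Withings): a day is valid
  when steps exceed a floor (default 150) — very low counts indicate an
  unworn device rather than an inactive wearer;
* **wear sum** (Garmin, Samsung): sleep + sedentary + LPA + MPA + VPA must
  exceed a threshold (default 600 min = 10 h) — the classic 10-hour
  wear-time criterion assembled from behaviour components;
* **nonwear cap** (Polar): reported nonwear time must stay below a cap
  (default 840 min = 14 h), i.e. at least 10 h worn.

All inequalities are strict by default; the step floor can be made inclusive
(``steps >= floor`` valid) via configuration, reflecting the ambiguity
between "more than 150" and "fewer than 150 excluded" readings of the same
criterion. A day whose rule inputs are missing cannot demonstrate wear and
is conservatively invalid, with a reason code rather than an exception.

MVPA (moderate-to-vigorous physical activity) is derived as MPA + VPA
minutes when both are present, absent otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .datamodel import DailyRecord, Provider
from .ingest import CanonicalDataset

logger = logging.getLogger(__name__)

__all__ = [
    "RuleKind",
    "ValidDayRule",
    "ValidDayConfig",
    "HarmonizedDay",
    "FilterResult",
    "rule_for",
    "compute_mvpa",
    "is_valid_day",
    "evaluate_day",
    "filter_valid",
    "write_exclusion_log",
]


class RuleKind(str, Enum):
    STEP_FLOOR = "step_floor"
    WEAR_SUM = "wear_sum"
    NONWEAR_CAP = "nonwear_cap"


@dataclass(frozen=True)
class ValidDayRule:
    """A provider's wear-time proxy: rule family + threshold.

    ``threshold`` is in steps for :attr:`RuleKind.STEP_FLOOR` and in minutes
    for the other two families. ``inclusive`` only affects the step floor
    (``>=`` instead of ``>``).
    """

    kind: RuleKind
    threshold: float
    inclusive: bool = False


@dataclass(frozen=True)
class ValidDayConfig:
    """Tunable thresholds for the three rule families (defaults as shipped)."""

    step_floor: float = 150.0
    step_floor_inclusive: bool = False
    wear_sum_min: float = 600.0  # 10 h
    nonwear_cap_min: float = 840.0  # 14 h


_RULE_FAMILY: dict[Provider, RuleKind] = {
    Provider.APPLE: RuleKind.STEP_FLOOR,
    Provider.FITBIT: RuleKind.STEP_FLOOR,
    Provider.GOOGLEFIT: RuleKind.STEP_FLOOR,
    Provider.OURA: RuleKind.STEP_FLOOR,
    Provider.WITHINGS: RuleKind.STEP_FLOOR,
    Provider.GARMIN: RuleKind.WEAR_SUM,
    Provider.SAMSUNG: RuleKind.WEAR_SUM,
    Provider.POLAR: RuleKind.NONWEAR_CAP,
}

_WEAR_COMPONENTS = ("sleep_min", "sedentary_min", "lpa_min", "mpa_min", "vpa_min")


def rule_for(provider: Provider | str, config: ValidDayConfig | None = None) -> ValidDayRule:
    """The valid-day rule a provider's data is judged by."""
    config = config or ValidDayConfig()
    family = _RULE_FAMILY[Provider.parse(provider)]
    if family is RuleKind.STEP_FLOOR:
        return ValidDayRule(family, config.step_floor, config.step_floor_inclusive)
    if family is RuleKind.WEAR_SUM:
        return ValidDayRule(family, config.wear_sum_min)
    return ValidDayRule(family, config.nonwear_cap_min)


def compute_mvpa(record: DailyRecord) -> Optional[float]:
    """MPA + VPA minutes; absent when either component is absent."""
    if record.mpa is None or record.vpa is None:
        return None
    return record.mpa + record.vpa


def evaluate_day(record: DailyRecord, rule: ValidDayRule) -> tuple[bool, Optional[str]]:
    """Classify one day; returns (valid, reason-code-if-invalid)."""
    if rule.kind is RuleKind.STEP_FLOOR:
        if record.steps is None:
            return False, "steps_missing"
        ok = record.steps >= rule.threshold if rule.inclusive else record.steps > rule.threshold
        return (True, None) if ok else (False, "steps_at_or_below_floor")
    if rule.kind is RuleKind.WEAR_SUM:
        components = (record.sleep, record.sedentary, record.lpa, record.mpa, record.vpa)
        if any(c is None for c in components):
            return False, "insufficient wear evidence"
        if sum(components) > rule.threshold:
            return True, None
        return False, "wear_sum_at_or_below_threshold"
    if rule.kind is RuleKind.NONWEAR_CAP:
        if record.nonwear is None:
            return False, "nonwear_missing"
        return ((True, None) if record.nonwear < rule.threshold else (False, "nonwear_at_or_above_cap"))
    raise ValueError(f"unknown rule kind {rule.kind!r}")


def is_valid_day(record: DailyRecord, rule: ValidDayRule) -> bool:
    return evaluate_day(record, rule)[0]


@dataclass(frozen=True)
class HarmonizedDay:
    """A daily record with derived MVPA and its valid-day verdict attached."""

    record: DailyRecord
    mvpa: Optional[float]
    valid: bool
    rule_applied: ValidDayRule
    reason: Optional[str] = None


@dataclass
class FilterResult:
    """Outcome of valid-day filtering over a dataset.

    ``valid_days`` carries the canonical columns plus ``mvpa_min``;
    ``exclusions`` is the reason-coded log of rejected days. The two
    partition the input: ``n_valid + n_excluded`` equals the input size.
    """

    valid_days: pd.DataFrame
    n_valid: int
    n_excluded: int
    exclusions: pd.DataFrame


def filter_valid(dataset: CanonicalDataset, config: ValidDayConfig | None = None) -> FilterResult:
    """Classify every participant-day by its provider's rule (vectorized)."""
    config = config or ValidDayConfig()
    frame = dataset.frame.copy()

    both = frame["mpa_min"].notna() & frame["vpa_min"].notna()
    frame["mvpa_min"] = np.where(both, frame["mpa_min"] + frame["vpa_min"], np.nan)

    valid = pd.Series(False, index=frame.index)
    reason = pd.Series(pd.NA, index=frame.index, dtype="object")
    rule_name = pd.Series(pd.NA, index=frame.index, dtype="object")

    for provider_name, group in frame.groupby("provider", sort=False):
        rule = rule_for(provider_name, config)
        idx = group.index
        rule_name.loc[idx] = rule.kind.value
        if rule.kind is RuleKind.STEP_FLOOR:
            steps = group["steps"]
            ok = steps >= rule.threshold if rule.inclusive else steps > rule.threshold
            ok = ok.fillna(False)
            reason.loc[idx[steps.isna()]] = "steps_missing"
            reason.loc[idx[~ok & steps.notna()]] = "steps_at_or_below_floor"
        elif rule.kind is RuleKind.WEAR_SUM:
            comp = group[list(_WEAR_COMPONENTS)]
            complete = comp.notna().all(axis=1)
            total = comp.sum(axis=1)
            ok = complete & (total > rule.threshold)
            reason.loc[idx[~complete]] = "insufficient wear evidence"
            reason.loc[idx[complete & ~ok]] = "wear_sum_at_or_below_threshold"
        else:
            nonwear = group["nonwear_min"]
            ok = (nonwear < rule.threshold).fillna(False)
            reason.loc[idx[nonwear.isna()]] = "nonwear_missing"
            reason.loc[idx[~ok & nonwear.notna()]] = "nonwear_at_or_above_cap"
        valid.loc[idx] = ok

    frame["valid"] = valid.astype(bool)
    exclusions = frame.loc[~frame["valid"], ["participant_id", "date", "provider"]].copy()
    exclusions["rule"] = rule_name[~frame["valid"]]
    exclusions["reason"] = reason[~frame["valid"]]
    valid_days = frame.loc[frame["valid"]].drop(columns="valid").reset_index(drop=True)

    result = FilterResult(
        valid_days=valid_days,
        n_valid=int(frame["valid"].sum()),
        n_excluded=int((~frame["valid"]).sum()),
        exclusions=exclusions.reset_index(drop=True),
    )
    logger.info(
        "valid-day filter: %d valid, %d excluded of %d records",
        result.n_valid, result.n_excluded, len(frame),
    )
    return result


def write_exclusion_log(result: FilterResult, path: str | Path) -> Path:
    """Write the reason-coded exclusion log as CSV."""
    path = Path(path)
    out = result.exclusions.copy()
    if len(out):
        out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
    return path
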