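"""Core domain types for consumer activity-tracker harmonization.

Consumer tracker ecosystems (Apple, Fitbit, Garmin, Google Fit, Oura, Polar,
Samsung, Withings) expose different subsets of daily activity variables
through their cloud APIs. Steps is the only variable every provider reports.
This module pins down those vocabularies — providers, variables, the
capability matrix mapping one to the other — plus the two calendar
abstractions the analysis needs: a single participant-day of measurements
(:class:`DailyRecord`) and a labeled calendar period (:class:`PeriodDefinition`),
including the split of March 2020 at the Norwegian COVID-19 lockdown date
(March 12).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional

__all__ = [
    "Provider",
    "Variable",
    "CAPABILITIES",
    "RULE_ONLY_FIELDS",
    "COLLECTION_START",
    "COLLECTION_END",
    "VARIABLE_COLUMNS",
    "CANONICAL_COLUMNS",
    "DailyRecord",
    "PeriodDefinition",
    "capabilities",
    "allowed_fields",
    "standard_periods",
    "month_period",
]


class Provider(str, Enum):
    """Activity-tracker ecosystem whose cloud supplies daily summaries."""

    APPLE = "apple"
    FITBIT = "fitbit"
    GARMIN = "garmin"
    GOOGLEFIT = "googlefit"
    OURA = "oura"
    POLAR = "polar"
    SAMSUNG = "samsung"
    WITHINGS = "withings"

    @classmethod
    def parse(cls, name: "Provider | str") -> "Provider":
        if isinstance(name, cls):
            return name
        try:
            return cls(str(name).strip().lower())
        except ValueError:
            known = ", ".join(p.value for p in cls)
            raise ValueError(f"unknown provider {name!r}; expected one of: {known}") from None


class Variable(str, Enum):
    """Daily summary variable.

    Units: ``steps`` is a count/day; ``tee``/``aee``/``ree`` are kcal/day
    (total, activity and resting energy expenditure); ``lpa``/``mpa``/``vpa``
    (light/moderate/vigorous physical activity), ``sedentary``, ``sleep`` and
    ``nonwear`` are minutes/day.
    """

    STEPS = "steps"
    TEE = "tee"
    AEE = "aee"
    REE = "ree"
    LPA = "lpa"
    MPA = "mpa"
    VPA = "vpa"
    SEDENTARY = "sedentary"
    SLEEP = "sleep"
    NONWEAR = "nonwear"


#: Variables reported in minutes/day (bounded by the length of a day).
MINUTE_VARIABLES = frozenset(
    {Variable.LPA, Variable.MPA, Variable.VPA, Variable.SEDENTARY, Variable.SLEEP, Variable.NONWEAR}
)

#: Which daily variables each provider's API exposes. Steps is universal.
CAPABILITIES: Mapping[Provider, frozenset[Variable]] = {
    Provider.APPLE: frozenset({Variable.STEPS, Variable.AEE, Variable.REE, Variable.SLEEP}),
    Provider.FITBIT: frozenset(
        {Variable.STEPS, Variable.TEE, Variable.AEE, Variable.LPA, Variable.MPA, Variable.VPA, Variable.SLEEP}
    ),
    Provider.GARMIN: frozenset({Variable.STEPS, Variable.TEE, Variable.AEE, Variable.MPA, Variable.VPA}),
    Provider.GOOGLEFIT: frozenset({Variable.STEPS, Variable.TEE}),
    Provider.OURA: frozenset(
        {
            Variable.STEPS,
            Variable.TEE,
            Variable.AEE,
            Variable.SEDENTARY,
            Variable.LPA,
            Variable.MPA,
            Variable.VPA,
            Variable.NONWEAR,
        }
    ),
    Provider.POLAR: frozenset(
        {
            Variable.STEPS,
            Variable.TEE,
            Variable.AEE,
            Variable.SEDENTARY,
            Variable.LPA,
            Variable.MPA,
            Variable.VPA,
            Variable.SLEEP,
        }
    ),
    Provider.SAMSUNG: frozenset({Variable.STEPS, Variable.AEE, Variable.SLEEP}),
    Provider.WITHINGS: frozenset(
        {Variable.STEPS, Variable.TEE, Variable.AEE, Variable.LPA, Variable.MPA, Variable.VPA, Variable.SLEEP}
    ),
}

#: Fields a provider's valid-day rule consumes although they are not analysis
#: variables for that provider (e.g. Samsung's wear-sum rule needs sedentary
#: and intensity minutes even though its API variable list is steps/AEE/sleep).
#: They may appear in exports and in canonical files without entering analyses.
RULE_ONLY_FIELDS: Mapping[Provider, frozenset[Variable]] = {
    Provider.APPLE: frozenset(),
    Provider.FITBIT: frozenset(),
    Provider.GARMIN: frozenset({Variable.SLEEP, Variable.SEDENTARY, Variable.LPA}),
    Provider.GOOGLEFIT: frozenset(),
    Provider.OURA: frozenset(),
    Provider.POLAR: frozenset({Variable.NONWEAR}),
    Provider.SAMSUNG: frozenset({Variable.SEDENTARY, Variable.LPA, Variable.MPA, Variable.VPA}),
    Provider.WITHINGS: frozenset(),
}

#: Study collection window: data outside it is rejected at ingest.
COLLECTION_START = dt.date(2019, 1, 1)
COLLECTION_END = dt.date(2020, 12, 31)

#: Canonical CSV column name for each variable.
VARIABLE_COLUMNS: Mapping[Variable, str] = {
    Variable.STEPS: "steps",
    Variable.TEE: "tee_kcal",
    Variable.AEE: "aee_kcal",
    Variable.REE: "ree_kcal",
    Variable.LPA: "lpa_min",
    Variable.MPA: "mpa_min",
    Variable.VPA: "vpa_min",
    Variable.SEDENTARY: "sedentary_min",
    Variable.SLEEP: "sleep_min",
    Variable.NONWEAR: "nonwear_min",
}

CANONICAL_COLUMNS = ("participant_id", "provider", "date") + tuple(VARIABLE_COLUMNS.values())


def capabilities(provider: Provider | str) -> frozenset[Variable]:
    """Return the immutable set of variables a provider's API supplies."""
    return CAPABILITIES[Provider.parse(provider)]


def allowed_fields(provider: Provider | str) -> frozenset[Variable]:
    """Capability set plus rule-only fields: everything an export may carry."""
    p = Provider.parse(provider)
    return CAPABILITIES[p] | RULE_ONLY_FIELDS[p]


@dataclass(frozen=True)
class DailyRecord:
    """One participant-day of raw provider measurements.

    Fields outside the provider's allowed set are ``None`` (absent), never
    zero-filled: a recorded 0 is a datum, a missing value is not.
    """

    participant_id: str
    provider: Provider
    date: dt.date
    steps: Optional[float] = None
    tee: Optional[float] = None
    aee: Optional[float] = None
    ree: Optional[float] = None
    lpa: Optional[float] = None
    mpa: Optional[float] = None
    vpa: Optional[float] = None
    sedentary: Optional[float] = None
    sleep: Optional[float] = None
    nonwear: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "provider", Provider.parse(self.provider))
        if isinstance(self.date, str):
            object.__setattr__(self, "date", dt.date.fromisoformat(self.date))
        for var in Variable:
            value = self.value(var)
            if value is None:
                continue
            if value < 0:
                raise ValueError(f"{var.value} must be >= 0, got {value}")
            if var in MINUTE_VARIABLES and value > 1440:
                raise ValueError(f"{var.value} exceeds 1440 min/day: {value}")

    def value(self, variable: Variable) -> Optional[float]:
        return getattr(self, variable.value)


@dataclass(frozen=True)
class PeriodDefinition:
    """A labeled calendar interval (or union of closed intervals).

    ``year_tag`` identifies which study year the period belongs to, so that
    e.g. "March" 2019 and "March" 2020 are distinct comparison endpoints.
    """

    label: str
    intervals: tuple[tuple[dt.date, dt.date], ...]
    year_tag: int

    def __post_init__(self) -> None:
        ivs = tuple(sorted(self.intervals))
        object.__setattr__(self, "intervals", ivs)
        if not ivs:
            raise ValueError("period needs at least one interval")
        for start, end in ivs:
            if start > end:
                raise ValueError(f"interval start {start} after end {end}")
            if start < COLLECTION_START or end > COLLECTION_END:
                raise ValueError(
                    f"interval [{start}, {end}] outside collection window "
                    f"[{COLLECTION_START}, {COLLECTION_END}]"
                )
        for (_, prev_end), (next_start, _) in zip(ivs, ivs[1:]):
            if next_start <= prev_end:
                raise ValueError("period intervals overlap")
        if self.year_tag not in (2019, 2020):
            raise ValueError(f"year_tag must be 2019 or 2020, got {self.year_tag}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.label, self.year_tag)

    def contains(self, date: dt.date) -> bool:
        return any(start <= date <= end for start, end in self.intervals)

    def n_days(self) -> int:
        return sum((end - start).days + 1 for start, end in self.intervals)


_MONTH_NAMES = [
    "January", "February", "March", "April", "May", "June",
    "July", "August", "September", "October", "November", "December",
]


def month_period(year: int, month: int) -> PeriodDefinition:
    """Whole calendar month as a period labeled with the month name."""
    start = dt.date(year, month, 1)
    end = (dt.date(year + 1, 1, 1) if month == 12 else dt.date(year, month + 1, 1)) - dt.timedelta(days=1)
    return PeriodDefinition(_MONTH_NAMES[month - 1], ((start, end),), year)


#: The pre/post lockdown sub-periods of March 2020 (boundary: March 12).
LOCKDOWN_SPLIT_DATE = dt.date(2020, 3, 12)


def standard_periods(scheme: str) -> list[PeriodDefinition]:
    """Built-in period schemes used by the comparison report.

    ``monthly_2019``
        Whole months March..December 2019.
    ``monthly_2020_split_march``
        March 1-12 and March 13-31 2020 as separate periods (the lockdown
        split), then whole months April..December 2020.
    ``yearly_mar_dec``
        One March 1 - December 31 span per year.
    """
    if scheme == "monthly_2019":
        return [month_period(2019, m) for m in range(3, 13)]
    if scheme == "monthly_2020_split_march":
        periods = [
            PeriodDefinition("March 1-12", ((dt.date(2020, 3, 1), LOCKDOWN_SPLIT_DATE),), 2020),
            PeriodDefinition("March 13-31", ((dt.date(2020, 3, 13), dt.date(2020, 3, 31)),), 2020),
        ]
        periods.extend(month_period(2020, m) for m in range(4, 13))
        return periods
    if scheme == "yearly_mar_dec":
        return [
            PeriodDefinition("March-December", ((dt.date(y, 3, 1), dt.date(y, 12, 31)),), y)
            for y in (2019, 2020)
        ]
    raise ValueError(
        f"unknown scheme {scheme!r}; expected monthly_2019, monthly_2020_split_march or yearly_mar_dec"
    )
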