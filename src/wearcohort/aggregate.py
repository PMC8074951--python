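"""Per-participant period means over valid days.

For each participant, calendar period and analysis variable (steps/day,
AEE kcal/day, MVPA min/day) this module computes the plain arithmetic mean
over the participant's valid days inside the period that carry the variable.
Days lacking a variable (e.g. MVPA underivable) contribute neither to that
variable's mean nor to its day count, so the same participant-period can
have different n across variables. Yearly spans are averaged over days, not
over months, which makes the valid-day-weighted recombination of sub-period
means exactly reproduce the whole-period mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .datamodel import PeriodDefinition

logger = logging.getLogger(__name__)

__all__ = ["ANALYSIS_VARIABLES", "ParticipantPeriodSummary", "summarize", "write_summaries"]

#: Analysis variable -> column of the harmonized valid-day frame.
ANALYSIS_VARIABLES = {"steps": "steps", "aee": "aee_kcal", "mvpa": "mvpa_min"}


@dataclass(frozen=True)
class ParticipantPeriodSummary:
    """Mean of one variable over one participant's valid days in one period."""

    participant_id: str
    period_label: str
    year: int
    variable: str
    mean_per_day: float
    n_valid_days: int


def _period_mask(dates: pd.Series, period: PeriodDefinition) -> pd.Series:
    mask = pd.Series(False, index=dates.index)
    for start, end in period.intervals:
        mask |= (dates >= pd.Timestamp(start)) & (dates <= pd.Timestamp(end))
    return mask


def summarize(
    valid_days: pd.DataFrame,
    periods: Sequence[PeriodDefinition],
    variable: str,
    min_days: int = 1,
) -> pd.DataFrame:
    """Per-participant period means for one variable.

    Parameters
    ----------
    valid_days
        Harmonized valid-day frame (output of valid-day filtering; must
        contain ``participant_id``, ``date`` and the variable's column).
    periods
        Periods to summarize over; a day contributes to every period whose
        intervals contain it (standard schemes are non-overlapping).
    variable
        One of ``steps``, ``aee``, ``mvpa``.
    min_days
        Minimum valid days (carrying the variable) for a summary to be
        emitted; participant-periods below it are absent, not zero.

    Returns
    -------
    DataFrame with columns participant_id, period_label, year, variable,
    mean_per_day, n_valid_days — one row per (participant, period) retained.
    """
    if variable not in ANALYSIS_VARIABLES:
        raise ValueError(f"variable must be one of {sorted(ANALYSIS_VARIABLES)}, got {variable!r}")
    if min_days < 1:
        raise ValueError("min_days must be >= 1")
    column = ANALYSIS_VARIABLES[variable]

    pieces = []
    usable = valid_days.loc[valid_days[column].notna(), ["participant_id", "date", column]]
    for period in periods:
        in_period = usable.loc[_period_mask(usable["date"], period)]
        if in_period.empty:
            continue
        grouped = in_period.groupby("participant_id")[column].agg(["mean", "size"])
        grouped = grouped[grouped["size"] >= min_days]
        if grouped.empty:
            continue
        piece = grouped.reset_index().rename(columns={"mean": "mean_per_day", "size": "n_valid_days"})
        piece.insert(1, "period_label", period.label)
        piece.insert(2, "year", period.year_tag)
        piece.insert(3, "variable", variable)
        pieces.append(piece)

    if not pieces:
        return pd.DataFrame(
            columns=["participant_id", "period_label", "year", "variable", "mean_per_day", "n_valid_days"]
        )
    out = pd.concat(pieces, ignore_index=True)
    out["n_valid_days"] = out["n_valid_days"].astype(int)
    return out


def write_summaries(summaries: pd.DataFrame, path: str | Path) -> Path:
    summaries.to_csv(Path(path), index=False, float_format="%.10g")
    return Path(path)
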