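"""End-to-end orchestration: filter -> summarize -> compare -> outputs.

This is the library face of the command-line pipeline; the CLI is a thin
wrapper. Outputs mirror the usual reporting shape for this kind of study:
a 13-contrast x 3-variable comparison table (rounded for reading, unrounded
in a machine-readable companion), monthly mean±SD series for steps and AEE
and median/IQR series for MVPA (bar-plot data), the reason-coded exclusion
log, and the per-participant period summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .aggregate import summarize, write_summaries
from .compare import full_report
from .config import PipelineConfig
from .datamodel import PeriodDefinition, standard_periods
from .ingest import CanonicalDataset
from .validday import FilterResult, filter_valid, write_exclusion_log

logger = logging.getLogger(__name__)

__all__ = ["AnalysisOutputs", "standard_summary_periods", "analyze_dataset", "write_outputs"]


def standard_summary_periods() -> list[PeriodDefinition]:
    """All periods the standard report draws on: monthly 2019, split-March
    monthly 2020, and the Mar-Dec yearly spans."""
    return (
        standard_periods("monthly_2019")
        + standard_periods("monthly_2020_split_march")
        + standard_periods("yearly_mar_dec")
    )


@dataclass
class AnalysisOutputs:
    filter_result: FilterResult
    summaries: pd.DataFrame
    report: pd.DataFrame
    monthly_series: dict[str, pd.DataFrame]


def _monthly_series(summaries: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Across-participant monthly distribution of period means (plot data)."""
    sub = summaries[
        (summaries["variable"] == variable) & (summaries["period_label"] != "March-December")
    ]
    if sub.empty:
        return pd.DataFrame(columns=["period_label", "year", "mean", "sd", "median", "q1", "q3", "n_participants"])
    rows = []
    for (label, year), group in sub.groupby(["period_label", "year"], sort=False):
        values = group["mean_per_day"].to_numpy(float)
        q1, med, q3 = np.percentile(values, [25, 50, 75])
        rows.append(
            {
                "period_label": label,
                "year": year,
                "mean": values.mean(),
                "sd": values.std(ddof=1) if len(values) > 1 else 0.0,
                "median": med,
                "q1": q1,
                "q3": q3,
                "n_participants": len(values),
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(["year", "period_label"], kind="stable").reset_index(drop=True)


def analyze_dataset(dataset: CanonicalDataset, config: PipelineConfig | None = None) -> AnalysisOutputs:
    """Run the full analysis on an in-memory canonical dataset."""
    config = config or PipelineConfig()
    logger.info("analysis input: %d daily records, %d participants",
                len(dataset), dataset.frame["participant_id"].nunique())
    filtered = filter_valid(dataset, config.validday)

    periods = standard_summary_periods()
    summaries = pd.concat(
        [summarize(filtered.valid_days, periods, var, config.min_days) for var in ("steps", "aee", "mvpa")],
        ignore_index=True,
    )
    logger.info("summaries: %d participant-period rows", len(summaries))
    report = full_report(summaries, config.compare)
    if report.empty:
        logger.warning("comparison report is empty (need periods from both study years)")
    monthly = {var: _monthly_series(summaries, var) for var in ("steps", "aee", "mvpa")}
    return AnalysisOutputs(filtered, summaries, report, monthly)


def _format_p(p: float) -> str:
    if not np.isfinite(p):
        return ""
    return f"{p:.2g}" if p >= 0.001 else "<.001"


def rounded_report(report: pd.DataFrame) -> pd.DataFrame:
    """Reader-facing rounding: integer steps/kcal/minutes, short p values."""
    if report.empty:
        return report.copy()
    out = report.copy()
    for col in ("estimate", "dispersion_low", "dispersion_high"):
        out[col] = out[col].round(0).astype("Int64")
    out["p"] = [_format_p(p) for p in out["p_two_sided"]]
    return out.drop(columns=["p_two_sided"])


def write_outputs(outputs: AnalysisOutputs, outdir: str | Path) -> dict[str, Path]:
    """Write all analysis artifacts as CSV; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["exclusions"] = write_exclusion_log(outputs.filter_result, outdir / "exclusions.csv")
    paths["summaries"] = write_summaries(outputs.summaries, outdir / "summaries.csv")

    full = outdir / "comparison_report_full.csv"
    outputs.report.to_csv(full, index=False, float_format="%.10g")
    paths["report_full"] = full

    pretty = outdir / "comparison_report.csv"
    rounded_report(outputs.report).to_csv(pretty, index=False)
    paths["report"] = pretty

    for var, series in outputs.monthly_series.items():
        p = outdir / f"monthly_{var}.csv"
        series.to_csv(p, index=False, float_format="%.10g")
        paths[f"monthly_{var}"] = p
    return paths
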