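"""Paired two-period contrasts of activity variables.

The study design compares each calendar period in 2020 against its
season-matched counterpart in 2019 (plus the within-March pre/post lockdown
contrast), participant by participant: only participants with a summary in
both periods enter, and every difference is later period minus earlier
period, so a lockdown-related drop appears as a negative estimate.

Two test families are used, matching how such data are conventionally
reported: a paired t test (mean difference with 95% CI) when the paired
differences look normal, and a Wilcoxon signed-rank test (median of the raw
differences with IQR) otherwise. The original analysis judged normality from
histograms; as a reproducible proxy this module uses a Shapiro–Wilk test on
the differences, and ships a per-variable override so that steps and AEE
default to the t test and MVPA to Wilcoxon — the assignment such data
almost always end up with. Two-sided p < alpha (default .05) is flagged
significant; no multiplicity correction is applied by default (a Holm
option exists).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import PeriodDefinition

logger = logging.getLogger(__name__)

__all__ = [
    "CompareConfig",
    "PairedSample",
    "TTestResult",
    "WilcoxonResult",
    "ComparisonResult",
    "build_pairs",
    "assess_normality",
    "paired_t",
    "wilcoxon_signed_rank",
    "run_comparison",
    "full_report",
    "standard_comparisons",
]


@dataclass(frozen=True)
class CompareConfig:
    """Testing options.

    ``test_overrides`` maps a variable to ``"paired_t"`` or ``"wilcoxon"``;
    a variable not listed (or mapped to ``None``) falls back to the
    Shapiro–Wilk decision at ``normality_alpha``. The shipped default pins
    steps and AEE to the t test and MVPA to Wilcoxon.
    """

    alpha: float = 0.05
    normality_alpha: float = 0.05
    test_overrides: Mapping[str, Optional[str]] = field(
        default_factory=lambda: {"steps": "paired_t", "aee": "paired_t", "mvpa": "wilcoxon"}
    )
    wilcoxon_zero_method: str = "wilcox"  # or "pratt"
    holm: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.normality_alpha < 1:
            raise ValueError("alpha levels must be in (0, 1)")
        if self.wilcoxon_zero_method not in ("wilcox", "pratt"):
            raise ValueError("wilcoxon_zero_method must be 'wilcox' or 'pratt'")
        for v in self.test_overrides.values():
            if v not in (None, "paired_t", "wilcoxon"):
                raise ValueError(f"unknown test override {v!r}")


@dataclass(frozen=True)
class PairedSample:
    """Participants observed in both periods, with later-minus-earlier diffs."""

    variable: str
    period_a: tuple[str, int]
    period_b: tuple[str, int]
    participant_ids: tuple[str, ...]
    mean_a: np.ndarray
    mean_b: np.ndarray

    @property
    def diffs(self) -> np.ndarray:
        return self.mean_b - self.mean_a

    @property
    def n(self) -> int:
        return len(self.participant_ids)


@dataclass(frozen=True)
class TTestResult:
    mean_diff: float
    ci_low: float
    ci_high: float
    statistic: float
    df: int
    p_two_sided: float
    degenerate: bool = False


@dataclass(frozen=True)
class WilcoxonResult:
    median_diff: float
    iqr_low: float
    iqr_high: float
    statistic: float
    n_effective: int
    p_two_sided: float
    degenerate: bool = False


@dataclass(frozen=True)
class ComparisonResult:
    variable: str
    comparison_label: str
    n_pairs: int
    test: str
    estimate: float
    dispersion_low: float
    dispersion_high: float
    p_two_sided: float
    significant: bool
    degenerate: bool = False


def _period_key(period: PeriodDefinition | tuple[str, int]) -> tuple[str, int]:
    if isinstance(period, PeriodDefinition):
        return period.key
    label, year = period
    return (str(label), int(year))


def build_pairs(
    summaries: pd.DataFrame,
    variable: str,
    period_a: PeriodDefinition | tuple[str, int],
    period_b: PeriodDefinition | tuple[str, int],
) -> PairedSample:
    """Intersect the two periods' participants and form paired differences.

    ``summaries`` is the long summary frame from :mod:`wearcohort.aggregate`.
    Raises ``ValueError`` when fewer than two participants have data in both
    periods ("insufficient pairs").
    """
    key_a, key_b = _period_key(period_a), _period_key(period_b)
    sub = summaries[summaries["variable"] == variable]

    def _means(key: tuple[str, int]) -> pd.Series:
        rows = sub[(sub["period_label"] == key[0]) & (sub["year"] == key[1])]
        return rows.set_index("participant_id")["mean_per_day"]

    a, b = _means(key_a), _means(key_b)
    common = a.index.intersection(b.index).sort_values()
    if len(common) < 2:
        raise ValueError(
            f"insufficient pairs for {variable} {key_a} vs {key_b}: {len(common)} participant(s) in both"
        )
    return PairedSample(
        variable=variable,
        period_a=key_a,
        period_b=key_b,
        participant_ids=tuple(common),
        mean_a=a.loc[common].to_numpy(float),
        mean_b=b.loc[common].to_numpy(float),
    )


def assess_normality(diffs: np.ndarray, alpha: float = 0.05) -> bool:
    """Shapiro–Wilk proxy for the visual normality check on differences.

    Returns True when normality is not rejected (so a paired t test will be
    used). Zero-variance differences cannot be assessed and return False
    (they are handled as degenerate downstream). Requires n >= 3.
    """
    diffs = np.asarray(diffs, float)
    if diffs.size < 3:
        raise ValueError(f"normality assessment requires n >= 3, got {diffs.size}")
    if np.ptp(diffs) == 0:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns for n > 5000; harmless here
        return bool(stats.shapiro(diffs).pvalue > alpha)


def paired_t(diffs: np.ndarray, ci_level: float = 0.95) -> TTestResult:
    """One-sample t test of the paired differences against zero.

    CI is the classical equal-tailed t interval, mean ± t_{1-α/2, n-1}·SE.
    Zero-variance input yields a degenerate result with undefined p.
    """
    diffs = np.asarray(diffs, float)
    n = diffs.size
    if n < 2:
        raise ValueError(f"paired t test requires n >= 2, got {n}")
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    if sd == 0:
        return TTestResult(mean, mean, mean, np.nan, n - 1, np.nan, degenerate=True)
    se = sd / np.sqrt(n)
    tcrit = float(stats.t.ppf(0.5 + ci_level / 2, n - 1))
    res = stats.ttest_1samp(diffs, 0.0)
    return TTestResult(
        mean_diff=mean,
        ci_low=mean - tcrit * se,
        ci_high=mean + tcrit * se,
        statistic=float(res.statistic),
        df=n - 1,
        p_two_sided=float(res.pvalue),
    )


def wilcoxon_signed_rank(diffs: np.ndarray, zero_method: str = "wilcox") -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on the paired differences.

    Zeros are dropped by default (classical convention; ``pratt`` keeps them
    in the ranking), ties are mid-ranked. The exact null distribution is
    used for effective n <= 25 with untied magnitudes, a normal
    approximation with tie correction otherwise. The location estimate is
    the median of the *raw* differences with their IQR (zeros included),
    matching how such contrasts are printed in reports.
    """
    diffs = np.asarray(diffs, float)
    if diffs.size < 2:
        raise ValueError(f"wilcoxon requires n >= 2, got {diffs.size}")
    median = float(np.median(diffs))
    q1, q3 = (float(q) for q in np.percentile(diffs, [25, 75]))

    nonzero = diffs[diffs != 0]
    kept = diffs if zero_method == "pratt" else nonzero
    if nonzero.size == 0:
        return WilcoxonResult(median, q1, q3, np.nan, 0, np.nan, degenerate=True)

    has_ties = len(np.unique(np.abs(nonzero))) < nonzero.size
    use_exact = nonzero.size <= 25 and not has_ties and not (zero_method == "pratt" and nonzero.size < diffs.size)
    method = "exact" if use_exact else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(kept, zero_method=zero_method, alternative="two-sided", method=method)
    return WilcoxonResult(
        median_diff=median,
        iqr_low=q1,
        iqr_high=q3,
        statistic=float(res.statistic),
        n_effective=int(nonzero.size),
        p_two_sided=float(res.pvalue),
    )


def run_comparison(
    summaries: pd.DataFrame,
    variable: str,
    period_a: PeriodDefinition | tuple[str, int],
    period_b: PeriodDefinition | tuple[str, int],
    config: CompareConfig | None = None,
    label: Optional[str] = None,
) -> ComparisonResult:
    """Build pairs, pick the test (override or normality), run it."""
    config = config or CompareConfig()
    sample = build_pairs(summaries, variable, period_a, period_b)
    diffs = sample.diffs

    choice = config.test_overrides.get(variable)
    if choice is None:
        choice = "paired_t" if (diffs.size >= 3 and assess_normality(diffs, config.normality_alpha)) else "wilcoxon"

    if label is None:
        label = f"{sample.period_a[0]} {sample.period_a[1]} vs {sample.period_b[0]} {sample.period_b[1]}"

    if choice == "paired_t":
        t = paired_t(diffs)
        return ComparisonResult(
            variable=variable,
            comparison_label=label,
            n_pairs=sample.n,
            test="paired_t",
            estimate=t.mean_diff,
            dispersion_low=t.ci_low,
            dispersion_high=t.ci_high,
            p_two_sided=t.p_two_sided,
            significant=bool(t.p_two_sided < config.alpha) if not t.degenerate else False,
            degenerate=t.degenerate,
        )
    w = wilcoxon_signed_rank(diffs, config.wilcoxon_zero_method)
    return ComparisonResult(
        variable=variable,
        comparison_label=label,
        n_pairs=sample.n,
        test="wilcoxon_signed_rank",
        estimate=w.median_diff,
        dispersion_low=w.iqr_low,
        dispersion_high=w.iqr_high,
        p_two_sided=w.p_two_sided,
        significant=bool(w.p_two_sided < config.alpha) if not w.degenerate else False,
        degenerate=w.degenerate,
    )


def standard_comparisons() -> list[tuple[str, tuple[str, int], tuple[str, int]]]:
    """The 13 standard contrasts: yearly Mar–Dec, the two lockdown-split
    contrasts against March 2019, month-matched April..December, and the
    within-March pre/post lockdown contrast."""
    months = ["April", "May", "June", "July", "August", "September", "October", "November", "December"]
    rows: list[tuple[str, tuple[str, int], tuple[str, int]]] = [
        ("March-December", ("March-December", 2019), ("March-December", 2020)),
        ("March 1-12", ("March", 2019), ("March 1-12", 2020)),
        ("March 13-31", ("March", 2019), ("March 13-31", 2020)),
    ]
    rows.extend((m, (m, 2019), (m, 2020)) for m in months)
    rows.append(("March 1-12 vs March 13-31", ("March 1-12", 2020), ("March 13-31", 2020)))
    return rows


def full_report(
    summaries: pd.DataFrame,
    config: CompareConfig | None = None,
    variables: Sequence[str] = ("steps", "aee", "mvpa"),
) -> pd.DataFrame:
    """Run every standard contrast for every variable.

    Returns a long DataFrame (comparison_label, variable, n_pairs, test,
    estimate, dispersion_low, dispersion_high, p_two_sided, significant,
    degenerate); contrasts whose periods are missing from the summaries are
    omitted with a warning. With ``config.holm`` the p values are
    Holm–Bonferroni adjusted across all emitted cells before the
    significance flags are set.
    """
    config = config or CompareConfig()
    rows = []
    for label, key_a, key_b in standard_comparisons():
        for variable in variables:
            try:
                rows.append(run_comparison(summaries, variable, key_a, key_b, config, label=label))
            except ValueError as exc:
                logger.warning("omitting %s / %s: %s", label, variable, exc)
    columns = [
        "variable", "comparison_label", "n_pairs", "test", "estimate",
        "dispersion_low", "dispersion_high", "p_two_sided", "significant", "degenerate",
    ]
    report = pd.DataFrame([r.__dict__ for r in rows], columns=columns)
    if report.empty:
        logger.warning("no comparisons could be formed from the provided summaries")
        return report

    if config.holm:
        finite = report["p_two_sided"].notna()
        from statsmodels.stats.multitest import multipletests  # optional path only

        adj = multipletests(report.loc[finite, "p_two_sided"], alpha=config.alpha, method="holm")
        report.loc[finite, "p_two_sided"] = adj[1]
        report.loc[finite, "significant"] = adj[0]
    return report
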