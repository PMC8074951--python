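"""Synthetic multi-provider activity-tracker cohorts.

Real consumer-tracker cohorts of this kind are anonymous and not shareable,
so every pipeline stage is exercised on simulated data with the same
structure: ~113 participants (39 Fitbit, 74 Garmin by default), one daily
summary per worn day from Jan 1 2019 to Dec 31 2020, per-participant
baseline step levels (lognormal, median 8000, geometric SD 1.4), a single
annual sinusoid of seasonal variation (±15%, peaking July 1), heavy daily
noise (SD 2500 steps), occasional nonwear days (low steps, high nonwear
minutes, low wear-component sums — so both rule families exclude them),
missing days, and an injectable step/AEE reduction over the lockdown window
Mar 13–31 2020 (defaults −800 steps/day, −75 kcal/day, near the magnitudes
such studies report).

AEE tracks steps at 0.04 kcal/step plus noise (SD 40 kcal); TEE adds a
per-participant resting expenditure. MVPA is drawn as round(max(0,
N(35, 20))) min/day and split into moderate and vigorous minutes. Records
carry only the fields the provider's API exposes plus the fields its
valid-day rule consumes. Generation is fully vectorized and deterministic
given the seed.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .datamodel import (
    CANONICAL_COLUMNS,
    COLLECTION_END,
    COLLECTION_START,
    VARIABLE_COLUMNS,
    Provider,
    allowed_fields,
)
from .ingest import CanonicalDataset

logger = logging.getLogger(__name__)

__all__ = ["LockdownEffect", "CohortConfig", "generate", "inject_effect"]


@dataclass(frozen=True)
class LockdownEffect:
    """Additive shift applied inside a calendar window."""

    window_start: dt.date = dt.date(2020, 3, 13)
    window_end: dt.date = dt.date(2020, 3, 31)
    delta_steps: float = -800.0
    delta_aee_kcal: float = -75.0


@dataclass(frozen=True)
class CohortConfig:
    """Generator parameters; defaults are the shipped study conditions."""

    n_participants: int = 113
    provider_mix: dict[str, int] = field(default_factory=lambda: {"fitbit": 39, "garmin": 74})
    baseline_steps_median: float = 8000.0
    baseline_steps_gsd: float = 1.4
    daily_noise_sd: float = 2500.0
    seasonal_amplitude: float = 0.15  # fraction of baseline, sinusoid peaking Jul 1
    lockdown_effect: Optional[LockdownEffect] = field(default_factory=LockdownEffect)
    aee_kcal_per_step: float = 0.04
    aee_noise_sd: float = 40.0
    mvpa_mean: float = 35.0
    mvpa_sd: float = 20.0
    nonwear_day_prob: float = 0.05
    missing_day_prob: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        mix_total = sum(self.provider_mix.values())
        if mix_total != self.n_participants:
            raise ValueError(
                f"provider_mix totals {mix_total}, expected n_participants={self.n_participants}"
            )
        for name in self.provider_mix:
            Provider.parse(name)
        for prob in (self.nonwear_day_prob, self.missing_day_prob):
            if not 0 <= prob <= 1:
                raise ValueError(f"probabilities must be in [0, 1], got {prob}")
        for sd in (self.daily_noise_sd, self.aee_noise_sd, self.mvpa_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if self.baseline_steps_gsd < 1:
            raise ValueError("geometric SD must be >= 1")
        if self.lockdown_effect is not None:
            eff = self.lockdown_effect
            if not (COLLECTION_START <= eff.window_start <= eff.window_end <= COLLECTION_END):
                raise ValueError("lockdown window must lie within the collection span")


#: Seasonal peak: July 1 2019, expressed as day offset from the span start.
_PEAK_OFFSET = (dt.date(2019, 7, 1) - COLLECTION_START).days
_YEAR_DAYS = 365.25


def _seasonal_factor(day_offsets: np.ndarray, amplitude: float) -> np.ndarray:
    return 1.0 + amplitude * np.cos(2 * np.pi * (day_offsets - _PEAK_OFFSET) / _YEAR_DAYS)


def generate(config: CohortConfig | None = None) -> CanonicalDataset:
    """Simulate a cohort as a canonical dataset (deterministic given seed)."""
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)

    n = config.n_participants
    dates = pd.date_range(COLLECTION_START, COLLECTION_END, freq="D")
    n_days = len(dates)
    day_offsets = np.arange(n_days, dtype=float)

    ids = np.array([f"S{i + 1:04d}" for i in range(n)])
    providers = np.concatenate(
        [np.full(count, Provider.parse(name).value) for name, count in config.provider_mix.items()]
    )

    baseline = rng.lognormal(np.log(config.baseline_steps_median), np.log(config.baseline_steps_gsd), n)
    ree = np.clip(rng.normal(1550.0, 150.0, n), 1100.0, None)

    shape = (n, n_days)
    seasonal = _seasonal_factor(day_offsets, config.seasonal_amplitude)
    steps = baseline[:, None] * seasonal[None, :] + rng.normal(0.0, config.daily_noise_sd, shape)
    steps = np.round(np.clip(steps, 0.0, None))

    mvpa = np.round(np.clip(rng.normal(config.mvpa_mean, config.mvpa_sd, shape), 0.0, None))
    vpa = np.round(mvpa * 0.3)
    mpa = mvpa - vpa
    lpa = np.clip(rng.normal(210.0, 60.0, shape), 0.0, 600.0)
    sleep = np.clip(rng.normal(430.0, 50.0, shape), 180.0, 720.0)
    wear_target = rng.uniform(550.0, 1000.0, shape)
    sedentary = np.clip(wear_target - sleep - lpa - mpa - vpa, 0.0, None)
    nonwear = np.clip(rng.normal(60.0, 40.0, shape), 0.0, 300.0)

    # Nonwear days: too few steps for the step-floor rules, too little summed
    # wear for the wear-sum rules, too much nonwear for the nonwear cap.
    nonwear_day = rng.random(shape) < config.nonwear_day_prob
    steps_unworn = rng.integers(0, 150, shape).astype(float)
    wear_total_unworn = rng.uniform(100.0, 500.0, shape)
    steps = np.where(nonwear_day, steps_unworn, steps)
    sleep = np.where(nonwear_day, wear_total_unworn * 0.8, sleep)
    sedentary = np.where(nonwear_day, wear_total_unworn * 0.2, sedentary)
    lpa = np.where(nonwear_day, 0.0, lpa)
    mpa = np.where(nonwear_day, 0.0, mpa)
    vpa = np.where(nonwear_day, 0.0, vpa)
    mvpa = mpa + vpa
    nonwear = np.where(nonwear_day, rng.uniform(900.0, 1440.0, shape), nonwear)

    aee = np.clip(config.aee_kcal_per_step * steps + rng.normal(0.0, config.aee_noise_sd, shape), 0.0, None)
    tee = ree[:, None] + aee

    missing = rng.random(shape) < config.missing_day_prob

    frame = pd.DataFrame(
        {
            "participant_id": np.repeat(ids, n_days),
            "provider": np.repeat(providers, n_days),
            "date": np.tile(dates.to_numpy(), n),
            "steps": steps.ravel(),
            "tee_kcal": tee.ravel(),
            "aee_kcal": aee.ravel(),
            "ree_kcal": np.repeat(ree, n_days),
            "lpa_min": np.round(lpa.ravel(), 1),
            "mpa_min": mpa.ravel(),
            "vpa_min": vpa.ravel(),
            "sedentary_min": np.round(sedentary.ravel(), 1),
            "sleep_min": np.round(sleep.ravel(), 1),
            "nonwear_min": np.round(nonwear.ravel(), 1),
        },
        columns=list(CANONICAL_COLUMNS),
    )
    frame = frame.loc[~missing.ravel()].reset_index(drop=True)

    # Restrict each record to its provider's capability + rule-only fields.
    for provider_name in set(providers):
        allowed_cols = {VARIABLE_COLUMNS[v] for v in allowed_fields(provider_name)}
        drop_cols = [c for c in VARIABLE_COLUMNS.values() if c not in allowed_cols]
        mask = frame["provider"] == provider_name
        frame.loc[mask, drop_cols] = np.nan

    dataset = CanonicalDataset(frame, provenance=[f"synthetic cohort (seed={config.seed})"])
    if config.lockdown_effect is not None:
        eff = config.lockdown_effect
        dataset = inject_effect(
            dataset, (eff.window_start, eff.window_end), eff.delta_steps, eff.delta_aee_kcal
        )
    logger.info(
        "generated synthetic cohort: %d participants, %d daily records (seed=%d)",
        n, len(dataset), config.seed,
    )
    return dataset


def inject_effect(
    dataset: CanonicalDataset,
    window: tuple[dt.date, dt.date],
    delta_steps: float,
    delta_aee: float,
) -> CanonicalDataset:
    """Additively shift steps and AEE inside a calendar window (floored at 0)."""
    start, end = window
    if start > end:  # empty window: identity
        return CanonicalDataset(dataset.frame.copy(), provenance=list(dataset.provenance))
    if not (COLLECTION_START <= start and end <= COLLECTION_END):
        raise ValueError("effect window must lie within the collection span")
    frame = dataset.frame.copy()
    mask = (frame["date"] >= pd.Timestamp(start)) & (frame["date"] <= pd.Timestamp(end))
    frame.loc[mask, "steps"] = np.clip(frame.loc[mask, "steps"] + delta_steps, 0.0, None)
    frame.loc[mask, "aee_kcal"] = np.clip(frame.loc[mask, "aee_kcal"] + delta_aee, 0.0, None)
    has_tee = mask & frame["tee_kcal"].notna() & frame["aee_kcal"].notna()
    frame.loc[has_tee, "tee_kcal"] = np.clip(frame.loc[has_tee, "tee_kcal"] + delta_aee, 0.0, None)
    return CanonicalDataset(
        frame,
        provenance=list(dataset.provenance)
        + [f"injected effect {delta_steps:+g} steps, {delta_aee:+g} kcal over [{start}, {end}]"],
    )
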