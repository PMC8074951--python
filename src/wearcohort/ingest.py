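"""Reading, writing and anonymizing canonical daily-record files.

The canonical on-disk format is one long CSV, one participant-day per row::

    participant_id,provider,date,steps,tee_kcal,aee_kcal,ree_kcal,
    lpa_min,mpa_min,vpa_min,sedentary_min,sleep_min,nonwear_min

Empty cells mean "not reported", never zero. In memory a dataset is a pandas
DataFrame with those columns (``date`` as datetime64), wrapped in
:class:`CanonicalDataset` together with provenance. Provider-specific export
dialects (differing field names, JSON vs CSV) are mapped onto the canonical
schema by a small config-driven renamer, and participant identifiers can be
replaced by fresh opaque ids with the identifier map destroyed afterwards —
mirroring token deletion in the original data collection.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .datamodel import (
    CANONICAL_COLUMNS,
    COLLECTION_END,
    COLLECTION_START,
    MINUTE_VARIABLES,
    VARIABLE_COLUMNS,
    DailyRecord,
    Provider,
    allowed_fields,
)

logger = logging.getLogger(__name__)

__all__ = [
    "IngestError",
    "CanonicalDataset",
    "TokenMap",
    "read_canonical",
    "write_canonical",
    "map_provider_export",
    "anonymize",
    "frame_from_records",
]

_NUMERIC_COLUMNS = tuple(VARIABLE_COLUMNS.values())
_COLUMN_TO_VARIABLE = {col: var for var, col in VARIABLE_COLUMNS.items()}


class IngestError(ValueError):
    """Raised when an input file violates the canonical schema."""


@dataclass
class CanonicalDataset:
    """A validated in-memory dataset of daily records plus provenance."""

    frame: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frame = _validate_frame(self.frame)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CanonicalDataset):
            return NotImplemented
        a = self.frame.sort_values(["participant_id", "date"]).reset_index(drop=True)
        b = other.frame.sort_values(["participant_id", "date"]).reset_index(drop=True)
        try:
            pd.testing.assert_frame_equal(a, b, check_exact=False, rtol=1e-9, atol=1e-12)
        except AssertionError:
            return False
        return True

    def to_records(self) -> list[DailyRecord]:
        """Materialize rows as :class:`DailyRecord` objects (small data only)."""
        out = []
        for row in self.frame.itertuples(index=False):
            kwargs = {
                var.value: (None if pd.isna(getattr(row, col)) else float(getattr(row, col)))
                for col, var in _COLUMN_TO_VARIABLE.items()
            }
            out.append(
                DailyRecord(
                    participant_id=row.participant_id,
                    provider=Provider(row.provider),
                    date=row.date.date() if hasattr(row.date, "date") else row.date,
                    **kwargs,
                )
            )
        return out


class TokenMap(dict):
    """participant_id <-> external token pairs; emptied by :func:`anonymize`."""

    def destroy(self) -> None:
        self.clear()


def _validate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    missing = set(CANONICAL_COLUMNS) - set(frame.columns)
    extra = set(frame.columns) - set(CANONICAL_COLUMNS)
    if missing or extra:
        raise IngestError(
            f"malformed header: missing columns {sorted(missing)}, unexpected {sorted(extra)}"
        )
    frame = frame.loc[:, list(CANONICAL_COLUMNS)].copy()

    frame["participant_id"] = frame["participant_id"].astype(str)
    try:
        provider_map = {name: Provider.parse(name).value for name in frame["provider"].unique()}
    except ValueError as exc:
        raise IngestError(str(exc)) from None
    frame["provider"] = frame["provider"].map(provider_map)

    dates = pd.to_datetime(frame["date"], format="ISO8601", errors="coerce")
    bad = dates.isna()
    if bad.any():
        raise IngestError(f"missing or unparseable date at row {int(np.flatnonzero(bad)[0]) + 1}")
    frame["date"] = dates.dt.normalize()

    out_of_window = (frame["date"] < pd.Timestamp(COLLECTION_START)) | (
        frame["date"] > pd.Timestamp(COLLECTION_END)
    )
    if out_of_window.any():
        row = int(np.flatnonzero(out_of_window)[0]) + 1
        raise IngestError(
            f"row {row}: date {frame['date'].iloc[row - 1].date()} outside collection window "
            f"[{COLLECTION_START}, {COLLECTION_END}]"
        )

    for col in _NUMERIC_COLUMNS:
        try:
            frame[col] = pd.to_numeric(frame[col], errors="raise").astype(float)
        except (ValueError, TypeError):
            coerced = pd.to_numeric(frame[col], errors="coerce")
            bad_row = int(np.flatnonzero(coerced.isna() & frame[col].notna())[0]) + 1
            raise IngestError(f"row {bad_row}: non-numeric value in column {col!r}") from None
        negative = frame[col] < 0
        if negative.any():
            raise IngestError(
                f"row {int(np.flatnonzero(negative)[0]) + 1}: negative value in column {col!r}"
            )
        if _COLUMN_TO_VARIABLE[col] in MINUTE_VARIABLES:
            over = frame[col] > 1440
            if over.any():
                raise IngestError(
                    f"row {int(np.flatnonzero(over)[0]) + 1}: {col!r} exceeds 1440 min/day"
                )

    dup = frame.duplicated(subset=["participant_id", "date"])
    if dup.any():
        row = int(np.flatnonzero(dup)[0]) + 1
        key = frame.loc[frame.index[row - 1], ["participant_id", "date"]]
        raise IngestError(
            f"row {row}: duplicate (participant, date) = ({key['participant_id']}, {key['date'].date()})"
        )

    # Values outside the provider's allowed set (capabilities + rule-only
    # fields) are dropped, not zero-filled, so they can never enter analyses.
    for provider, group in frame.groupby("provider", sort=False):
        allowed_cols = {VARIABLE_COLUMNS[v] for v in allowed_fields(provider)}
        for col in _NUMERIC_COLUMNS:
            if col in allowed_cols:
                continue
            present = group[col].notna()
            if present.any():
                logger.warning(
                    "dropping %d %s value(s) not supported by provider %s",
                    int(present.sum()), col, provider,
                )
                frame.loc[group.index[present], col] = np.nan

    return frame.reset_index(drop=True)


def frame_from_records(records: Iterable[DailyRecord]) -> pd.DataFrame:
    """Assemble a canonical frame from :class:`DailyRecord` objects."""
    rows = []
    for rec in records:
        row = {"participant_id": rec.participant_id, "provider": rec.provider.value, "date": rec.date}
        for var, col in VARIABLE_COLUMNS.items():
            value = rec.value(var)
            row[col] = np.nan if value is None else float(value)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
    frame["date"] = pd.to_datetime(frame["date"])
    return frame


def read_canonical(path: str | Path) -> CanonicalDataset:
    """Load a canonical CSV, validating every row.

    Raises :class:`IngestError` (with the 1-based data row number) on a
    malformed header, non-numeric or negative values, duplicate
    (participant, date) keys, or dates outside the collection window.
    An empty data section with a valid header yields an empty dataset.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype={"participant_id": str, "provider": str})
    dataset = CanonicalDataset(frame, provenance=[f"{path.name} read {dt.datetime.now().isoformat()}"])
    logger.info("read %d daily records from %s", len(dataset), path)
    return dataset


def write_canonical(dataset: CanonicalDataset, path: str | Path) -> Path:
    """Write a dataset to canonical CSV (lossless round-trip with read)."""
    path = Path(path)
    out = dataset.frame.copy()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format="%.10g")
    return path


def map_provider_export(
    path: str | Path,
    provider: Provider | str,
    mapping: Mapping[str, Mapping[str, str]],
) -> CanonicalDataset:
    """Map a provider-dialect export (CSV or JSON records) onto the canonical schema.

    ``mapping`` is the field-mapping config: provider name -> {external field
    name -> canonical column name}. ``participant_id`` and ``date`` must be
    mapped (or already canonical); an export with no steps mapping is
    rejected since steps is the one universally required variable. Columns
    outside the provider's allowed set are dropped with a warning.
    """
    provider = Provider.parse(provider)
    path = Path(path)
    if provider.value not in mapping:
        raise IngestError(f"no field-mapping config entry for provider {provider.value!r}")
    renames = dict(mapping[provider.value])

    if path.suffix.lower() == ".json":
        raw = pd.DataFrame(json.loads(path.read_text()))
    else:
        raw = pd.read_csv(path)
    raw = raw.rename(columns=renames)

    for required in ("participant_id", "date"):
        if required not in raw.columns:
            raise IngestError(f"export lacks a {required!r} field after mapping")
    if "steps" not in raw.columns:
        raise IngestError("export lacks a mapped 'steps' field (mandatory variable)")

    allowed_cols = {VARIABLE_COLUMNS[v] for v in allowed_fields(provider)}
    keep = ["participant_id", "date"] + [c for c in _NUMERIC_COLUMNS if c in raw.columns and c in allowed_cols]
    dropped = [c for c in raw.columns if c not in keep]
    if dropped:
        logger.warning("provider %s export: dropping unmapped/unsupported columns %s", provider.value, dropped)
    frame = raw.loc[:, keep].copy()
    frame["provider"] = provider.value
    for col in _NUMERIC_COLUMNS:
        if col not in frame.columns:
            frame[col] = np.nan
    dataset = CanonicalDataset(
        frame, provenance=[f"{path.name} ({provider.value} dialect) read {dt.datetime.now().isoformat()}"]
    )
    logger.info("mapped %d %s-dialect records from %s", len(dataset), provider.value, path)
    return dataset


def anonymize(dataset: CanonicalDataset, token_map: TokenMap) -> CanonicalDataset:
    """Replace participant ids with fresh opaque ids and destroy the token map.

    The relabeling is bijective (one fresh id per original id, in order of
    first appearance) and preserves every measurement; only the link between
    records and external identities is severed. The mapping is not returned
    and not persisted.
    """
    frame = dataset.frame.copy()
    originals = frame["participant_id"].drop_duplicates().tolist()
    fresh = {orig: f"P{i + 1:04d}" for i, orig in enumerate(originals)}
    frame["participant_id"] = frame["participant_id"].map(fresh)
    token_map.destroy()
    logger.info("anonymized %d participants; token map destroyed", len(originals))
    return CanonicalDataset(frame, provenance=dataset.provenance + ["anonymized"])
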