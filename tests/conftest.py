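import numpy as np
import pandas as pd
import pytest

from wearcohort.datamodel import CANONICAL_COLUMNS
from wearcohort.ingest import CanonicalDataset
from wearcohort.synthcohort import CohortConfig, generate


def make_frame(rows):
    """Build a canonical frame from sparse row dicts (absent cells -> NaN)."""
    frame = pd.DataFrame(
        [{**{c: np.nan for c in CANONICAL_COLUMNS}, **row} for row in rows],
        columns=list(CANONICAL_COLUMNS),
    )
    frame["date"] = pd.to_datetime(frame["date"])
    return frame


def make_dataset(rows):
    return CanonicalDataset(make_frame(rows))


@pytest.fixture(scope="session")
def small_null_cohort():
    """12-participant mixed-provider cohort with no injected effect."""
    config = CohortConfig(
        n_participants=12,
        provider_mix={"fitbit": 5, "garmin": 7},
        lockdown_effect=None,
        seed=7,
    )
    return generate(config)


@pytest.fixture(scope="session")
def small_lockdown_cohort():
    """12-participant cohort with the default lockdown effect injected."""
    config = CohortConfig(n_participants=12, provider_mix={"fitbit": 5, "garmin": 7}, seed=7)
    return generate(config)
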