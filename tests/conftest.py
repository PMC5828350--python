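import numpy as np
import pandas as pd
import pytest

import wearcohort as wc
from wearcohort import ingest


def make_steps(rows) -> pd.DataFrame:
    """Step-interval frame from (timestamp, steps) tuples."""
    return pd.DataFrame(
        {"start": pd.to_datetime([r[0] for r in rows]), "steps": [int(r[1]) for r in rows]}
    )


def make_hr(rows) -> pd.DataFrame:
    """HR frame from (timestamp, bpm, confidence) tuples."""
    return pd.DataFrame(
        {
            "timestamp": pd.to_datetime([r[0] for r in rows]),
            "hr_bpm": [float(r[1]) for r in rows],
            "confidence": [int(r[2]) for r in rows],
        }
    )


def make_sleep(rows) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "start": pd.to_datetime([r[0] for r in rows]),
            "end": pd.to_datetime([r[1] for r in rows]),
        }
    )


def full_day(date: str, *, steps_per_bin: int = 50, hr: float = 70.0,
             conf: int = 2) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One complete day: 96 step bins and hourly valid HR readings."""
    day = pd.Timestamp(date)
    steps = pd.DataFrame(
        {"start": pd.date_range(day, periods=96, freq="15min"),
         "steps": np.full(96, steps_per_bin)}
    )
    hrf = pd.DataFrame(
        {
            "timestamp": pd.date_range(day, periods=24, freq="h"),
            "hr_bpm": np.full(24, hr),
            "confidence": np.full(24, conf),
        }
    )
    return steps, hrf


def ledger_for(hr: pd.DataFrame, steps: pd.DataFrame) -> pd.DataFrame:
    timeline = ingest.merge_by_time(hr, steps)
    return ingest.build_day_ledger(timeline, steps)


@pytest.fixture(scope="session")
def small_cohort() -> wc.synth.SynthCohort:
    """A small default-condition cohort reused across read-only tests."""
    return wc.generate_cohort(wc.SynthConfig(n_subjects=30, seed=0))
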