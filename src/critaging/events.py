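"""Event tables: per-animal death/censoring records.

An event table is a :class:`pandas.DataFrame` with columns

- ``time_days`` (float): death or censoring time, days post-L4/adult molt,
- ``event`` (int): 1 = observed death, 0 = right-censored,
- ``group`` (str): cohort label.

All survival estimators in :mod:`critaging.survival` consume this shape.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

COLUMNS = ["time_days", "event", "group"]


def event_table(times, events, group: str = "cohort") -> pd.DataFrame:
    """Assemble an event table from parallel arrays."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if np.any(times < 0) or not np.all(np.isfinite(times)):
        raise ValueError("times must be finite and non-negative")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("events must be 0 (censored) or 1 (death)")
    return pd.DataFrame(
        {"time_days": times, "event": events, "group": group}
    )


def validate_event_table(events: pd.DataFrame) -> pd.DataFrame:
    if events is None or len(events) == 0:
        raise ValueError("empty event table")
    missing = [c for c in COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    return events


def write_event_table(events: pd.DataFrame, path) -> None:
    validate_event_table(events)
    events.loc[:, COLUMNS].to_csv(path, index=False)


def read_event_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_event_table(df)
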