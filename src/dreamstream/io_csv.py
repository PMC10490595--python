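"""CSV dialect for recorded sessions.

One row per sample: a ``time_s`` column, the 24 channel columns in µV, and a
``trigger`` column (0 = none, 1 = eyes-open onset, 2 = eyes-closed onset) --
26 columns in all.  Values are written with six decimal places so a round
trip is exact to well under 1e-4 µV.  The strict reader validates the header
and the uniform time grid; a permissive mode tolerates extra metadata
columns.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .recording import EYES_CLOSED, EYES_OPEN, Recording

TRIGGER_CODES = {0: None, 1: EYES_OPEN, 2: EYES_CLOSED}
CONDITION_CODES = {EYES_OPEN: 1, EYES_CLOSED: 2}

#: sampling rates snapped during read (device-supported values)
KNOWN_RATES = (500.0, 250.0, 500.0 / 3.0)


class DialectError(ValueError):
    """The file does not follow the session CSV dialect."""


def write_csv(recording: Recording, path: str | Path) -> None:
    """Write a Recording in the session dialect."""
    trigger = np.zeros(recording.n_samples, dtype=int)
    for idx, cond in recording.events:
        trigger[idx] = CONDITION_CODES[cond]
    df = pd.DataFrame({"time_s": recording.times()})
    for lab, row in zip(recording.labels, recording.data):
        df[lab] = row
    df["trigger"] = trigger
    df.to_csv(path, index=False, float_format="%.6f")


def read_csv(path: str | Path, strict: bool = True) -> Recording:
    """Read a session CSV; infers and validates the sampling rate.

    With ``strict`` (default) the column layout must be exactly
    ``time_s``, 24 channel labels, ``trigger``; otherwise extra columns are
    ignored as metadata.
    """
    df = pd.read_csv(path)
    cols = list(df.columns)
    if "time_s" not in cols or "trigger" not in cols:
        raise DialectError("missing required 'time_s'/'trigger' columns")
    channels = [c for c in cols if c not in ("time_s", "trigger")]
    if strict:
        if len(cols) != 26:
            raise DialectError(f"expected 26 columns, found {len(cols)}")
        if cols[0] != "time_s" or cols[-1] != "trigger":
            raise DialectError("column order must be time_s, channels, trigger")
    if len(df) < 2:
        raise DialectError("need at least two samples")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if dt.min() <= 0 or (dt.max() - dt.min()) > 1e-3 * dt.mean():
        raise DialectError("time column is not a uniform monotone grid")
    fs = 1.0 / dt.mean()
    for known in KNOWN_RATES:
        if abs(fs - known) < 0.5:
            fs = known
            break
    data = df[channels].to_numpy(dtype=float).T
    trigger = df["trigger"].to_numpy(dtype=int)
    events = [(int(i), TRIGGER_CODES[int(code)])
              for i, code in zip(np.flatnonzero(trigger), trigger[trigger != 0])
              if int(code) in (1, 2)]
    return Recording(fs, tuple(channels), data, events)
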