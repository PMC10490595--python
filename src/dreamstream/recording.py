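"""The in-memory container for a labelled multichannel EEG time series."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EYES_OPEN = "eyes_open"
EYES_CLOSED = "eyes_closed"
CONDITIONS = (EYES_OPEN, EYES_CLOSED)


@dataclass
class Recording:
    """A multichannel µV time series with condition-onset events.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz (may be non-integer, e.g. 500/3).
    labels : tuple of str
        Channel labels, one per data row.
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    events : list of (int, str)
        Condition onsets as (sample_index, condition) with condition one of
        ``eyes_open`` / ``eyes_closed``.  Indices strictly increasing; if any
        events are present the first must be at sample 0.
    """

    fs: float
    labels: tuple[str, ...]
    data: np.ndarray
    events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.labels):
            raise ValueError(
                f"data must be (n_channels, n_samples) with "
                f"{len(self.labels)} rows, got {self.data.shape}"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        prev = -1
        for idx, cond in self.events:
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r}")
            if not prev < idx < self.n_samples or (prev < 0 and idx != 0):
                raise ValueError("event indices must start at 0, increase "
                                 "strictly and stay in range")
            prev = idx

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def blocks(self) -> list[tuple[int, int, str]]:
        """Condition blocks as (start, stop, condition), stop exclusive."""
        out = []
        for k, (idx, cond) in enumerate(self.events):
            stop = self.events[k + 1][0] if k + 1 < len(self.events) else self.n_samples
            out.append((idx, stop, cond))
        return out

    def pick(self, labels: list[str] | tuple[str, ...]) -> "Recording":
        idx = [self.labels.index(l) for l in labels]
        return Recording(self.fs, tuple(labels), self.data[idx], list(self.events))

    def copy(self) -> "Recording":
        return Recording(self.fs, self.labels, self.data.copy(), list(self.events))
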