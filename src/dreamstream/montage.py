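"""Electrode montage: the 24-channel 10-20 layout, 2D head positions, adjacency.

The device records from 24 scalp electrodes in a fixed order.  Positions are
expressed on a unit head circle (x to the right, y toward the nose) using the
conventional azimuthal projection of the 10-20 system; they are used for the
neighbour graph of the cluster-based permutation test and for topographic
plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Recording order of the 24 channels (prefrontal to occipital rows).
CHANNEL_LABELS: tuple[str, ...] = (
    "FP1", "FPZ", "FP2", "F7", "F3", "FZ", "F4", "F8",
    "M1", "T7", "C3", "CZ", "C4", "T8", "M2", "P7",
    "P3", "PZ", "P4", "P8", "POZ", "O1", "OZ", "O2",
)

N_CHANNELS = len(CHANNEL_LABELS)

# Outer 10-20 ring at radius 0.8; angles measured clockwise from the nose (+y).
_RING_DEG = {
    "FPZ": 0, "FP2": 18, "F8": 54, "T8": 90, "P8": 126, "O2": 162,
    "OZ": 180, "O1": 198, "P7": 234, "T7": 270, "F7": 306, "FP1": 342,
}
_INNER_XY = {
    "FZ": (0.0, 0.40), "CZ": (0.0, 0.0), "PZ": (0.0, -0.40), "POZ": (0.0, -0.60),
    "F3": (-0.335, 0.41), "F4": (0.335, 0.41),
    "C3": (-0.40, 0.0), "C4": (0.40, 0.0),
    "P3": (-0.335, -0.41), "P4": (0.335, -0.41),
    # Mastoids sit low behind the ears, near the head rim.
    "M1": (-0.92, -0.33), "M2": (0.92, -0.33),
}

# Mastoids are spatially isolated; force their physiologically sensible links.
_FORCED_EDGES = (("M1", "T7"), ("M1", "P7"), ("M2", "T8"), ("M2", "P8"))

#: Neighbour rule: channels closer than this multiple of the median
#: nearest-neighbour distance are adjacent.
ADJACENCY_FACTOR = 1.3


def channel_positions() -> np.ndarray:
    """2D positions, shape (24, 2), in recording order."""
    xy = np.empty((N_CHANNELS, 2))
    for i, lab in enumerate(CHANNEL_LABELS):
        if lab in _RING_DEG:
            th = np.deg2rad(_RING_DEG[lab])
            xy[i] = 0.8 * np.sin(th), 0.8 * np.cos(th)
        else:
            xy[i] = _INNER_XY[lab]
    return xy


@dataclass(frozen=True)
class Montage:
    """Channel labels, scalp positions and the symmetric neighbour graph."""

    labels: tuple[str, ...]
    positions: np.ndarray
    adjacency: np.ndarray = field(repr=False)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def neighbors(self, label: str) -> list[str]:
        i = self.index(label)
        return [self.labels[j] for j in np.flatnonzero(self.adjacency[i])]

    def subset(self, labels: list[str] | tuple[str, ...]) -> "Montage":
        """Montage restricted to ``labels`` (keeping their given order)."""
        idx = [self.index(l) for l in labels]
        return Montage(tuple(labels), self.positions[idx],
                       self.adjacency[np.ix_(idx, idx)])


def default_montage() -> Montage:
    """The 24-channel device montage with distance-rule adjacency."""
    pos = channel_positions()
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    thresh = ADJACENCY_FACTOR * np.median(d.min(axis=1))
    adj = d <= thresh
    for a, b in _FORCED_EDGES:
        i, j = CHANNEL_LABELS.index(a), CHANNEL_LABELS.index(b)
        adj[i, j] = adj[j, i] = True
    np.fill_diagonal(adj, False)
    return Montage(CHANNEL_LABELS, pos, adj)
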