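"""Adaptive closed-loop delta (DPCM) codec with per-channel bit shifts.

Each transmitted channel value is the difference between the current sample
and the last *encoded* value, divided by a per-channel power-of-two shift,
rounded half away from zero and clipped to the configured signed bit length
(10, 14 or 16).  Because the encoder updates its reference from its own
quantized output, encoder and decoder reconstructions are bit-identical on a
lossless stream and quantization error cannot accumulate.

The shift adapts once per second: an exponential moving average of the
absolute raw difference tracks the signal's volatility, and the smallest
shift whose representable range covers ``headroom`` times that average is
selected (a 4-bit code, 0-15).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .frontend import COUNT_MAX, COUNT_MIN

ALLOWED_BIT_LENGTHS = (10, 14, 16)
N_CHANNELS = 24
MAX_SHIFT = 15


@dataclass
class CodecConfig:
    """Codec parameters.

    ``ema_lambda`` defaults to 1/fs_out, giving the volatility tracker a
    time constant of about one second -- the same cadence at which the shift
    table is re-evaluated.  ``headroom`` is the safety factor between the
    average difference magnitude and the edge of the representable range.
    """

    bit_length: int = 10
    fs_out: float = 250.0
    ema_lambda: float | None = None
    headroom: float = 8.0

    def __post_init__(self) -> None:
        if self.bit_length not in ALLOWED_BIT_LENGTHS:
            raise ValueError(f"bit length must be one of {ALLOWED_BIT_LENGTHS}")
        if self.ema_lambda is None:
            self.ema_lambda = 1.0 / self.fs_out
        if not 0.0 < self.ema_lambda <= 1.0:
            raise ValueError("ema_lambda must lie in (0, 1]")
        if self.headroom < 1.0:
            raise ValueError("headroom must be >= 1")

    @property
    def q_max(self) -> int:
        return (1 << (self.bit_length - 1)) - 1

    @property
    def q_min(self) -> int:
        return -(1 << (self.bit_length - 1))

    @property
    def shift_interval(self) -> int:
        """Frames between shift-table updates (~1 s of samples)."""
        return int(round(self.fs_out))


@dataclass
class EncoderState:
    """Per-channel reconstruction, volatility average and active shift."""

    r: np.ndarray = field(default_factory=lambda: np.zeros(N_CHANNELS, np.int64))
    avg: np.ndarray = field(default_factory=lambda: np.zeros(N_CHANNELS))
    shift: np.ndarray = field(default_factory=lambda: np.zeros(N_CHANNELS, np.int64))
    samples_since_shift_update: int = 0
    packet_id: int = 0
    dropped_since_last: int = 0


@dataclass
class DecoderState:
    """Mirror of the encoder's reconstruction; tracks loss bookkeeping."""

    r: np.ndarray = field(default_factory=lambda: np.zeros(N_CHANNELS, np.int64))
    shift: np.ndarray = field(default_factory=lambda: np.zeros(N_CHANNELS, np.int64))
    synchronized: bool = False
    last_packet_id: int | None = None
    cumulative_dropped: int = 0


class UnsynchronizedError(RuntimeError):
    """Decoding was attempted before any shift table was received."""


def reset_encoder() -> EncoderState:
    """Fresh encoder state: reconstruction, average and shifts all zero."""
    return EncoderState()


def reset_decoder() -> DecoderState:
    return DecoderState()


def _round_shift(d: np.ndarray, shift: np.ndarray) -> np.ndarray:
    """round_half_away_from_zero(d / 2^shift) in exact integer arithmetic."""
    half = (np.int64(1) << shift) >> 1
    mag = (np.abs(d) + half) >> shift
    return np.sign(d) * mag


def encode_frame(state: EncoderState, counts: np.ndarray, config: CodecConfig
                 ) -> np.ndarray:
    """Encode one 24-channel frame in place; returns the quantized deltas.

    Per channel: ``d = counts - r``; ``q = clip(round(d / 2^s))`` to the
    signed bit length; the reference advances by the *decodable* amount
    ``q * 2^s`` so the loop stays closed.  The volatility average is updated
    with the raw ``|d|``.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if counts.shape != state.r.shape:
        raise ValueError("frame must have one value per channel")
    if counts.max() > COUNT_MAX or counts.min() < COUNT_MIN:
        raise ValueError("frame counts exceed the 24-bit signed range")
    d = counts - state.r
    q = np.clip(_round_shift(d, state.shift), config.q_min, config.q_max)
    state.r = state.r + (q << state.shift)
    lam = config.ema_lambda
    state.avg = (1.0 - lam) * state.avg + lam * np.abs(d)
    state.samples_since_shift_update += 1
    return q


def update_shift(avg: float | np.ndarray, bit_length: int,
                 headroom: float = 8.0) -> np.ndarray | int:
    """Shift code(s) for a volatility average.

    ``s = clip(bitlength(ceil(avg * headroom)) - (bit_length - 1), 0, 15)``:
    the smallest shift for which the representable span ``2^s * 2^(n-1)``
    exceeds ``headroom`` times the average difference magnitude.
    """
    if bit_length not in ALLOWED_BIT_LENGTHS:
        raise ValueError(f"bit length must be one of {ALLOWED_BIT_LENGTHS}")
    scalar = np.isscalar(avg)
    a = np.atleast_1d(np.asarray(avg, dtype=float))
    if np.any(a < 0):
        raise ValueError("average magnitude must be non-negative")
    targets = np.ceil(a * headroom).astype(np.int64)
    s = np.array([max(0, min(MAX_SHIFT, int(t).bit_length() - (bit_length - 1)))
                  for t in targets], dtype=np.int64)
    return int(s[0]) if scalar else s


def refresh_shifts(state: EncoderState, config: CodecConfig) -> np.ndarray:
    """Recompute the shift table from the current averages (1 Hz cadence)."""
    state.shift = np.asarray(
        update_shift(state.avg, config.bit_length, config.headroom))
    state.samples_since_shift_update = 0
    return state.shift.copy()


def decode_frame(state: DecoderState, deltas: np.ndarray, config: CodecConfig
                 ) -> np.ndarray:
    """Apply one frame of quantized deltas; returns the reconstruction.

    Raises :class:`UnsynchronizedError` until a shift table has been applied
    via :func:`apply_shift_table`.
    """
    if not state.synchronized:
        raise UnsynchronizedError("no shift table received yet")
    q = np.asarray(deltas, dtype=np.int64)
    if q.shape != state.r.shape:
        raise ValueError("frame must have one value per channel")
    if q.max() > config.q_max or q.min() < config.q_min:
        raise ValueError("delta outside the configured bit length")
    state.r = state.r + (q << state.shift)
    return state.r.copy()


def apply_shift_table(state: DecoderState, shifts: np.ndarray) -> None:
    shifts = np.asarray(shifts, dtype=np.int64)
    if shifts.shape != state.shift.shape or shifts.min() < 0 or shifts.max() > MAX_SHIFT:
        raise ValueError("shift table must hold per-channel codes in [0, 15]")
    state.shift = shifts.copy()
    state.synchronized = True


def _encode_span(counts, r, avg, shift, lam, qmin, qmax, out):
    """Sequential DPCM recursion over one constant-shift span (in place)."""
    nch, m = counts.shape
    for i in range(m):
        for c in range(nch):
            d = counts[c, i] - r[c]
            s = shift[c]
            half = (1 << s) >> 1
            if d >= 0:
                q = (d + half) >> s
                ad = d
            else:
                q = -((-d + half) >> s)
                ad = -d
            if q > qmax:
                q = qmax
            elif q < qmin:
                q = qmin
            out[c, i] = q
            r[c] += q << s
            avg[c] = (1.0 - lam) * avg[c] + lam * ad


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    _encode_span_fast = njit(cache=False)(_encode_span)
except Exception:  # pragma: no cover
    _encode_span_fast = _encode_span


def encode_stream(counts: np.ndarray, config: CodecConfig
                  ) -> tuple[np.ndarray, list[tuple[int, np.ndarray]]]:
    """Encode a whole (n_channels, n) counts array.

    Returns ``(deltas, shift_schedule)`` where ``deltas`` has the same shape
    as the input and ``shift_schedule`` lists ``(frame_index, shifts)``
    entries, one per shift-table refresh (the first at frame 0).  The table
    computed at a refresh takes effect at that same frame.
    """
    counts = np.asarray(counts, dtype=np.int64)
    nch, n = counts.shape
    if nch != N_CHANNELS:
        raise ValueError(f"expected {N_CHANNELS} channels")
    if counts.max(initial=0) > COUNT_MAX or counts.min(initial=0) < COUNT_MIN:
        raise ValueError("counts exceed the 24-bit signed range")
    state = reset_encoder()
    deltas = np.empty_like(counts)
    schedule: list[tuple[int, np.ndarray]] = []
    interval = config.shift_interval
    for start in range(0, n, interval):
        schedule.append((start, refresh_shifts(state, config)))
        stop = min(start + interval, n)
        span = np.ascontiguousarray(counts[:, start:stop])
        out = np.empty_like(span)
        _encode_span_fast(span, state.r, state.avg, state.shift,
                          config.ema_lambda, config.q_min, config.q_max, out)
        deltas[:, start:stop] = out
        state.samples_since_shift_update = stop - start
    return deltas, schedule


def decode_stream(deltas: np.ndarray, schedule: list[tuple[int, np.ndarray]],
                  config: CodecConfig) -> np.ndarray:
    """Inverse of :func:`encode_stream` (lossless path, vectorized).

    Within each constant-shift span the reconstruction is a plain cumulative
    sum of ``q * 2^s``, so the whole stream decodes in a few array passes.
    """
    deltas = np.asarray(deltas, dtype=np.int64)
    if not schedule or schedule[0][0] != 0:
        raise UnsynchronizedError("shift schedule must start at frame 0")
    n = deltas.shape[1]
    steps = np.empty_like(deltas)
    bounds = [idx for idx, _ in schedule] + [n]
    for (start, shifts), stop in zip(schedule, bounds[1:]):
        steps[:, start:stop] = deltas[:, start:stop] << shifts[:, None]
    return np.cumsum(steps, axis=1)
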