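"""Firmware-side signal chain: IIR filtering, block-average downsampling,
high-pass, and 24-bit quantization.

The chain mirrors the on-device pipeline: a Butterworth low-pass and a
Butterworth band-stop notch run at the internal 500 Hz rate; non-overlapping
block averaging then drops the rate to 250 Hz (factor 2) or 500/3 Hz
(factor 3, reported as 167 Hz); a first-order high-pass removes the residual
offset; finally the signal is scaled by the programmable gain and quantized
to 24-bit signed ADC counts against the 2.5 V reference.

Filters run causally from zero initial conditions, as firmware must; the
processor is stateful so chunked streaming gives bit-identical output to
one-shot processing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .recording import Recording

INTERNAL_FS = 500.0
VREF = 2.5  # volts, ADC reference
ADC_BITS = 24
COUNT_MIN = -(1 << (ADC_BITS - 1))
COUNT_MAX = (1 << (ADC_BITS - 1)) - 1
ALLOWED_GAINS = (1, 2, 4, 8)
ALLOWED_FACTORS = (2, 3)


@dataclass
class FilterConfig:
    """Front-end configuration (device defaults)."""

    lowpass_cutoff: float = 60.0
    lowpass_order: int = 6
    notch_band: tuple[float, float] = (46.0, 54.0)
    notch_order: int = 4
    highpass_cutoff: float = 0.5
    downsample_factor: int = 2
    gain: int = 8

    def __post_init__(self) -> None:
        if self.downsample_factor not in ALLOWED_FACTORS:
            raise ValueError("downsample factor must be 2 or 3")
        if self.gain not in ALLOWED_GAINS:
            raise ValueError(f"gain must be one of {ALLOWED_GAINS}")


def output_rate(factor: int, exact: bool = False) -> float | int:
    """Output sampling rate for a downsampling factor.

    With ``exact`` the true rational rate (e.g. 500/3) is returned; otherwise
    the conventional rounded figure (250 or 167 Hz) used in reporting.
    """
    if factor not in ALLOWED_FACTORS:
        raise ValueError("downsample factor must be 2 or 3")
    rate = INTERNAL_FS / factor
    return rate if exact else int(round(rate))


def design_filters(config: FilterConfig, fs: float = INTERNAL_FS) -> dict:
    """Design the three IIR stages; returns second-order sections.

    The low-pass and notch run at ``fs``; the first-order high-pass runs at
    the downsampled rate.  All stages are Butterworth and verified stable
    (poles strictly inside the unit circle).
    """
    nyq = fs / 2
    if config.lowpass_cutoff >= nyq:
        raise ValueError("low-pass cutoff must be below Nyquist")
    if config.notch_band[1] >= nyq or config.notch_band[0] <= 0:
        raise ValueError("notch band must lie inside (0, Nyquist)")
    fs_out = fs / config.downsample_factor
    if config.highpass_cutoff >= fs_out / 2:
        raise ValueError("high-pass cutoff must be below the output Nyquist")
    lp = signal.butter(config.lowpass_order, config.lowpass_cutoff,
                       btype="lowpass", fs=fs, output="sos")
    notch = signal.butter(config.notch_order, list(config.notch_band),
                          btype="bandstop", fs=fs, output="sos")
    hp = signal.butter(1, config.highpass_cutoff, btype="highpass",
                       fs=fs_out, output="sos")
    filters = {"lowpass": lp, "notch": notch, "highpass": hp, "fs": fs,
               "fs_out": fs_out}
    for name in ("lowpass", "notch", "highpass"):
        _, poles, _ = signal.sos2zpk(filters[name])
        if np.any(np.abs(poles) >= 1.0):
            raise RuntimeError(f"{name} filter is unstable")  # pragma: no cover
    return filters


def downsample_avg(x: np.ndarray, factor: int) -> np.ndarray:
    """Non-overlapping block average along the last axis.

    ``output[k]`` is the mean of input block ``k``; a trailing partial block
    is dropped, so the output length is ``floor(n / factor)``.
    """
    if factor not in ALLOWED_FACTORS:
        raise ValueError("downsample factor must be 2 or 3")
    x = np.asarray(x)
    n = x.shape[-1]
    if n < factor:
        raise ValueError("input shorter than one averaging block")
    m = n // factor
    trimmed = x[..., : m * factor]
    return trimmed.reshape(*x.shape[:-1], m, factor).mean(axis=-1)


def quantize(volts: np.ndarray, gain: int) -> np.ndarray:
    """Scale by the gain and convert volts to 24-bit signed counts.

    counts = round(v * gain * 2^23 / Vref), clipped to the signed 24-bit
    range (clipping is the defined overflow behaviour).
    """
    if gain not in ALLOWED_GAINS:
        raise ValueError(f"gain must be one of {ALLOWED_GAINS}")
    scaled = np.asarray(volts, dtype=float) * gain * (1 << (ADC_BITS - 1)) / VREF
    counts = np.rint(scaled)
    return np.clip(counts, COUNT_MIN, COUNT_MAX).astype(np.int64)


def dequantize(counts: np.ndarray, gain: int) -> np.ndarray:
    """Counts back to volts (inverse of :func:`quantize` up to half an LSB)."""
    if gain not in ALLOWED_GAINS:
        raise ValueError(f"gain must be one of {ALLOWED_GAINS}")
    return np.asarray(counts, dtype=float) * VREF / (gain * (1 << (ADC_BITS - 1)))


class FrontendProcessor:
    """Stateful streaming implementation of the front-end chain.

    Feed µV chunks of shape (n_channels, n) through :meth:`process`; the
    concatenated output equals one-shot processing exactly.
    """

    def __init__(self, n_channels: int, config: FilterConfig | None = None,
                 fs: float = INTERNAL_FS):
        self.config = config or FilterConfig()
        self.filters = design_filters(self.config, fs)
        self.fs_out = self.filters["fs_out"]
        nch = n_channels
        self._zi_lp = np.zeros((self.filters["lowpass"].shape[0], nch, 2))
        self._zi_notch = np.zeros((self.filters["notch"].shape[0], nch, 2))
        self._zi_hp = np.zeros((self.filters["highpass"].shape[0], nch, 2))
        self._carry = np.empty((nch, 0))

    def process(self, chunk_uV: np.ndarray) -> np.ndarray:
        """Process one chunk; returns int64 counts, shape (n_channels, m)."""
        x = np.asarray(chunk_uV, dtype=float)
        if x.size == 0:
            return np.empty((x.shape[0], 0), dtype=np.int64)
        y, self._zi_lp = signal.sosfilt(self.filters["lowpass"], x, axis=-1,
                                        zi=self._zi_lp)
        y, self._zi_notch = signal.sosfilt(self.filters["notch"], y, axis=-1,
                                           zi=self._zi_notch)
        y = np.concatenate([self._carry, y], axis=-1)
        factor = self.config.downsample_factor
        m = y.shape[-1] // factor
        self._carry = y[..., m * factor:]
        if m == 0:
            return np.empty((x.shape[0], 0), dtype=np.int64)
        d = y[..., : m * factor].reshape(y.shape[0], m, factor).mean(axis=-1)
        d, self._zi_hp = signal.sosfilt(self.filters["highpass"], d, axis=-1,
                                        zi=self._zi_hp)
        return quantize(d * 1e-6, self.config.gain)


def run_frontend(recording: Recording, config: FilterConfig | None = None
                 ) -> tuple[np.ndarray, float]:
    """One-shot front end: Recording (µV at 500 Hz) -> (counts, fs_out).

    Returns the full chain output as int64 counts of shape
    (n_channels, n_out) plus the exact output rate in Hz.
    """
    if abs(recording.fs - INTERNAL_FS) > 1e-9:
        raise ValueError("front end expects a 500 Hz recording")
    proc = FrontendProcessor(recording.n_channels, config)
    counts = proc.process(recording.data)
    return counts, proc.fs_out


def map_events(events: list[tuple[int, str]], factor: int) -> list[tuple[int, str]]:
    """Translate event sample indices from 500 Hz to the downsampled rate."""
    return [(idx // factor, cond) for idx, cond in events]
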