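"""Seeded synthetic resting-state EEG sessions.

Emulates the structure of an alternating eyes-open / eyes-closed recording on
the 24-channel montage: waxing-and-waning ~10 Hz alpha over occipital sites
while the eyes are closed, elevated 1.5-3.5 Hz delta over prefrontal/frontal
sites while they are open, blink and saccade transients dominant on the
prefrontal row, a common 50 Hz mains component, and per-channel 1/f
background noise.  Everything is driven by one ``numpy`` generator so a seed
fully determines the output.

The generator produces scalp potential in microvolts at the device's internal
500 Hz rate; the firmware front-end (``dreamstream.frontend``) is a separate,
downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .montage import CHANNEL_LABELS
from .recording import EYES_CLOSED, EYES_OPEN, Recording

#: Channels carrying the eyes-closed alpha rhythm.
ALPHA_CHANNELS = ("O1", "O2", "OZ", "POZ")
#: Channels with boosted delta while the eyes are open.
DELTA_CHANNELS = ("FP1", "FPZ", "FP2", "F7", "F3", "FZ", "F4", "F8")
#: Blink topography: full weight on the prefrontal row, partial spread to
#: the frontal row (no volume-conduction model, just a fixed weighting).
BLINK_WEIGHTS = {"FP1": 1.0, "FPZ": 1.0, "FP2": 1.0,
                 "F7": 0.3, "F3": 0.3, "FZ": 0.3, "F4": 0.3, "F8": 0.3}
SACCADE_WEIGHTS = {"F7": 1.0, "F8": 1.0, "FP1": 0.7, "FPZ": 0.7, "FP2": 0.7}

INTERNAL_FS = 500.0


@dataclass
class SessionConfig:
    """Parameters of one synthetic session.

    Amplitudes are in microvolts.  ``alpha_amp_uV`` is the mean peak
    amplitude of the alpha carrier, ``delta_amp_uV`` the equivalent
    sinusoidal peak of the band-limited delta process (its RMS is
    ``delta_amp_uV / sqrt(2)``), ``blink_amp_uV`` the peak of the blink
    transient and ``noise_rms_uV`` the RMS of the 1/f background.
    """

    duration_s: float = 1200.0
    block_s: float = 120.0
    fs_internal: float = INTERNAL_FS
    channel_labels: tuple[str, ...] = CHANNEL_LABELS
    seed: int = 0
    alpha_freq: float = 10.0
    alpha_amp_uV: float = 20.0
    delta_band: tuple[float, float] = (1.5, 3.5)
    delta_amp_uV: float = 15.0
    blink_rate_hz: float = 0.25
    blink_amp_uV: float = 120.0
    blink_duration_s: float = 0.35
    line_freq: float = 50.0
    line_amp_uV: float = 5.0
    noise_rms_uV: float = 10.0
    #: depth of the slow (tau ~ 1 s) alpha amplitude modulation
    alpha_mod_depth: float = 0.5

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)
        if self.fs_internal != INTERNAL_FS:
            raise ValueError("internal sampling rate is fixed at 500 Hz")
        if self.block_s <= 0 or self.duration_s <= 0:
            raise ValueError("durations must be positive")
        n_blocks = self.duration_s / self.block_s
        if abs(n_blocks - round(n_blocks)) > 1e-9:
            raise ValueError("duration_s must be a positive multiple of block_s")
        if len(self.channel_labels) != 24:
            raise ValueError("exactly 24 channel labels required")
        unknown = set(self.channel_labels) - set(CHANNEL_LABELS)
        if unknown:
            raise ValueError(f"unknown channel labels: {sorted(unknown)}")
        for name in ("alpha_amp_uV", "delta_amp_uV", "blink_amp_uV",
                     "line_amp_uV", "noise_rms_uV", "blink_rate_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_blocks(self) -> int:
        return int(round(self.duration_s / self.block_s))


def generate_blink(fs: float, duration_s: float, amp_uV: float) -> np.ndarray:
    """One blink transient: sharp positive lobe plus shallow broad undershoot.

    The waveform is biphasic and zero-mean (the undershoot area cancels the
    main lobe) with peak magnitude ``amp_uV``.  Durations between 0.3 and
    0.5 s are accepted, matching typical blink artifact widths.
    """
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    if not 0.3 <= duration_s <= 0.5:
        raise ValueError("blink duration must lie in [0.3, 0.5] s")
    n = int(round(fs * duration_s))
    t = (np.arange(n) + 0.5) / fs
    T = duration_s
    main = np.exp(-0.5 * ((t - 0.30 * T) / (0.06 * T)) ** 2)
    under = np.exp(-0.5 * ((t - 0.62 * T) / (0.22 * T)) ** 2)
    w = main - under * (main.sum() / under.sum())  # exact zero mean
    peak = np.abs(w).max()
    if peak > 0:
        w = w * (amp_uV / peak)
    return w


def _saccade(fs: float, amp_uV: float, rng: np.random.Generator) -> np.ndarray:
    """Brief high-frequency eye-movement oscillation (~25 Hz, damped)."""
    dur = 0.12
    n = int(round(fs * dur))
    t = np.arange(n) / fs
    w = np.sin(2 * np.pi * 25.0 * t + rng.uniform(0, 2 * np.pi))
    w *= np.exp(-t / 0.04)
    return amp_uV * w


def _one_over_f_noise(n: int, fs: float, rms: float, rng: np.random.Generator,
                      f_knee: float = 1.0) -> np.ndarray:
    """Gaussian noise with power spectral density ~ 1/f above ``f_knee``."""
    white = rng.standard_normal(n)
    if rms == 0:
        return np.zeros(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = 1.0 / np.sqrt(np.maximum(f, f_knee))
    shape[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shape, n)
    return x * (rms / np.sqrt(np.mean(x**2)))


def _smooth_envelope(n: int, fs: float, tau_s: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian-smoothed noise (correlation time ~ tau_s)."""
    z = rng.standard_normal(n)
    m = int(round(6 * tau_s * fs)) | 1
    t = (np.arange(m) - m // 2) / fs
    k = np.exp(-0.5 * (t / tau_s) ** 2)
    k /= k.sum()
    e = signal.fftconvolve(z, k, mode="same")
    sd = e.std()
    return e / sd if sd > 0 else e


def _block_slices(cfg: SessionConfig) -> list[tuple[int, int, str]]:
    spb = int(round(cfg.block_s * cfg.fs_internal))
    out = []
    for b in range(cfg.n_blocks):
        cond = EYES_CLOSED if b % 2 == 0 else EYES_OPEN
        out.append((b * spb, (b + 1) * spb, cond))
    return out


def generate_session(config: SessionConfig) -> Recording:
    """Simulate one alternating eyes-closed / eyes-open session.

    The first block is eyes-closed.  Identical configs (including the seed)
    produce bitwise-identical recordings.
    """
    cfg = config
    fs = cfg.fs_internal
    n = int(round(cfg.duration_s * fs))
    labels = cfg.channel_labels
    ch = {lab: i for i, lab in enumerate(labels)}
    rng = np.random.default_rng(cfg.seed)
    data = np.zeros((len(labels), n))
    t = np.arange(n) / fs
    blocks = _block_slices(cfg)

    # 1/f background, independent per channel
    for i in range(len(labels)):
        data[i] += _one_over_f_noise(n, fs, cfg.noise_rms_uV, rng)

    # common-mode mains interference
    if cfg.line_amp_uV > 0:
        line = cfg.line_amp_uV * np.sin(2 * np.pi * cfg.line_freq * t
                                        + rng.uniform(0, 2 * np.pi))
        data += line

    # occipital alpha with slow amplitude modulation, eyes-closed only
    carrier = np.sin(2 * np.pi * cfg.alpha_freq * t + rng.uniform(0, 2 * np.pi))
    env = 1.0 + cfg.alpha_mod_depth * _smooth_envelope(n, fs, 1.0, rng)
    alpha = cfg.alpha_amp_uV * np.clip(env, 0.0, None) * carrier
    closed_mask = np.zeros(n, dtype=bool)
    for a, b, cond in blocks:
        if cond == EYES_CLOSED:
            closed_mask[a:b] = True
    for lab in ALPHA_CHANNELS:
        data[ch[lab]] += alpha * closed_mask

    # frontal delta, eyes-open only: band-limited Gaussian noise at the
    # stated RMS, an independent realization per channel
    lo, hi = cfg.delta_band
    if cfg.delta_amp_uV > 0:
        sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        open_mask = ~closed_mask
        target_rms = cfg.delta_amp_uV / np.sqrt(2.0)
        for lab in DELTA_CHANNELS:
            d = signal.sosfiltfilt(sos, rng.standard_normal(n))
            d *= target_rms / np.sqrt(np.mean(d**2))
            data[ch[lab]] += d * open_mask

    # blinks (Poisson within eyes-open blocks) and one saccade per onset
    blink = generate_blink(fs, cfg.blink_duration_s, cfg.blink_amp_uV)
    for a, b, cond in blocks:
        if cond != EYES_OPEN:
            continue
        block_dur = (b - a) / fs
        if cfg.blink_amp_uV > 0 and block_dur > len(blink) / fs:
            n_blinks = rng.poisson(cfg.blink_rate_hz * block_dur)
            starts = np.sort(rng.uniform(0, block_dur - len(blink) / fs,
                                         size=n_blinks))
            for s in starts:
                i0 = a + int(round(s * fs))
                seg = data[:, i0:i0 + len(blink)]
                for lab, w in BLINK_WEIGHTS.items():
                    seg[ch[lab]] += w * blink[: seg.shape[1]]
        if cfg.blink_amp_uV > 0:
            sac = _saccade(fs, 0.5 * cfg.blink_amp_uV, rng)
            i0 = a + int(round(rng.uniform(0.0, 1.0 - len(sac) / fs) * fs))
            seg = data[:, i0:i0 + len(sac)]
            for lab, w in SACCADE_WEIGHTS.items():
                seg[ch[lab]] += w * sac[: seg.shape[1]]

    events = [(a, cond) for a, _, cond in blocks]
    return Recording(fs, labels, data, events)
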