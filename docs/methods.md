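# Methods

This document records the signal model, the telemetry arithmetic, the
statistical procedures, and the reasoning behind the package defaults.
Units are given for every parameter; all randomness flows from a single
`numpy.random.default_rng(seed)` per generated session.

## 1. Synthetic session model (`synthgen`)

A session is a sequence of alternating condition blocks (default 120 s,
starting with eyes-closed) at an internal rate of 500 Hz, 24 channels in
device order (`FP1 … O2`, including mastoids `M1`/`M2`).

Components, summed in microvolts:

- **Occipital alpha** (eyes-closed only, channels `O1 O2 OZ POZ`):
  a sinusoidal carrier at `alpha_freq` (default 10 Hz) with envelope
  `1 + alpha_mod_depth · z(t)`, where `z` is Gaussian noise smoothed by a
  1 s moving-average kernel and rescaled to unit RMS, clipped at 0. With
  15 s epochs the carrier sits exactly on a PSD bin (10 = 150 · (1/15) Hz),
  so the spectral peak location is a sharp end-to-end observable rather
  than a leakage-dependent one. Default amplitude 20 µV.
- **Frontal delta** (eyes-open only, the 8 frontal channels): Gaussian
  noise band-passed to `delta_band` (default 1.5–3.5 Hz), scaled so its
  RMS equals `delta_amp_uV / √2` (default 15 µV nominal amplitude) —
  the RMS a sinusoid of that amplitude would have.
- **Blinks** (eyes-open only): a Poisson process at `blink_rate_hz`
  (default 0.25 s⁻¹). Each blink is a fixed template of duration
  `blink_duration_s` ∈ [0.3, 0.5] s: a sharp positive Gaussian lobe
  (σ = 0.06 T, centered at 0.30 T) minus a broad undershoot (σ = 0.22 T at
  0.62 T), rebalanced to exact zero mean and normalized so the peak equals
  `blink_amp_uV` (default 120 µV). Spatial weights: 1.0 on `FP1 FPZ FP2`,
  0.3 on `F7 F3 FZ F4 F8`. The template is resolution-invariant: the same
  shape at any sampling rate.
- **Saccades** (eyes-open): one damped 25 Hz oscillation burst within 1 s
  of each eyes-open block onset, frontal-lateral weighting.
- **Line interference**: a common-phase 50 Hz sinusoid on all channels
  (default 5 µV) — common-mode, as referenced hardware would see it.
- **Background**: per-channel 1/f noise (power-law spectrum with a 1 Hz
  knee to keep DC finite), RMS `noise_rms_uV` (default 10 µV).

Realism limits: no inter-channel correlation structure beyond the
component topographies, no alpha harmonics, no electrode drift or motion
artifacts, stationary noise floor. These omissions are deliberate — each
component exists to exercise a specific downstream claim (spectral peak,
band contrast, artifact rejection), not to fool a clinician.

## 2. Firmware front end (`frontend`)

Processing order, all causal with zero initial conditions, applied at
500 Hz then at the output rate:

1. 6th-order Butterworth low-pass, cutoff 60 Hz (anti-aliasing).
2. 4th-order Butterworth band-stop, 46–54 Hz (mains notch).
3. Non-overlapping block-average downsampling by factor 2 (→ 250 Hz) or
   3 (→ 500/3 Hz, reported as the integer 167). Output length is
   `⌊n / factor⌋`; a streaming remainder buffer makes chunked processing
   bit-identical to one-shot (filter state is carried as `sosfilt` `zi`).
4. First-order Butterworth high-pass at 0.5 Hz, at the output rate
   (DC/drift removal after decimation, as the firmware applies it).
5. Quantization to ADC counts: `round(v · gain · 2²³ / 2.5)` clipped to
   signed 24-bit, with `gain ∈ {1, 2, 4, 8}` (default 8) and a 2.5 V
   reference. Inputs are µV; the chain converts to volts internally.

Filters are designed as second-order sections and checked for pole
stability at design time.

## 3. Adaptive delta codec (`codec`)

Per channel, with reference `r` (decoder-reproducible) and shift `s`:

```
d = counts − r
q = clip( round_half_away_from_zero(d / 2^s),  −2^(n−1),  2^(n−1)−1 )
r ← r + q · 2^s
```

for bit length `n ∈ {10, 14, 16}`. Because `r` advances by the *quantized*
step on both sides, quantization error never accumulates: when no clipping
occurs, `|counts − r| ≤ 2^(s−1)` after every frame (0 when `s = 0`).
Clipping produces a transient undershoot that subsequent frames absorb.

Shift adaptation: an exponential moving average `A` of `|d|` with
`λ = 1 / fs_out` (≈ 1 s time constant), then

```
s = max(0, min(15, bitlength(⌈A · headroom⌉) − (n − 1)))
```

with `headroom = 8`, so the representable range `±2^(n−1)·2^s` covers about
eight times the average step. Shifts are frozen between refreshes, which
occur every `round(fs_out)` frames (once per second) and are transmitted as
shift-update messages *before* the first frame they govern. Encoder and
decoder are bit-identical on lossless streams; the decoder raises
`UnsynchronizedError` until it has a shift table. A sequential kernel does
the closed-loop loop; numba JIT-compiles it when available, with a pure
Python/numpy fallback producing identical output.

## 4. Wire format (`framing`)

| message        | size | layout |
|----------------|------|--------|
| data (10-bit)  | 31 B | header + 24 × 10 bits = 240 bits = 30 B |
| data (14-bit)  | 43 B | header + 24 × 14 bits = 336 bits = 42 B |
| data (16-bit)  | 49 B | header + 24 × 16 bits = 384 bits = 48 B |
| shift update   | 14 B | ref packet id, flags, 24 × 4-bit shifts (even channel in the high nibble) |
| config readback| 8 B  | gain code, rate code, bit-length code, filter mask, battery mV (big-endian u16), 2 reserved |

Data header byte: `(packet_id << 4) | dropped` — a 4-bit rolling id and a
4-bit saturating count of packets dropped since the last delivered one.
Values are packed MSB-first, two's complement, contiguously; the final
partial byte is padded in the low bits. `write_stream`/`read_stream` wrap
messages in a 1-byte-tag container for files.

## 5. Receiver pipeline (`pipeline`)

`encode_recording` emits one config message, then per second one shift
update (referencing the id of the next data packet) followed by that
second's data packets. `StreamDecoder` applies a pending shift table when
the referenced packet id arrives, counts losses from id gaps and the
header's dropped field, and exposes reconstructed counts;
`decode_messages` additionally restores µV via the inverse quantizer.
`roundtrip` chains generator output through front end, codec, framing, and
decoding.

## 6. Analysis (`analysis`)

- **Preprocess**: zero-phase (`sosfiltfilt`) 4th-order Butterworth 1–30 Hz
  band-pass, per-channel mean subtraction, bad-channel rejection (robust
  SD via 1.4826 · MAD across channels; a channel is bad if its SD is more
  than 5× the channel median or ~0).
- **Epoching**: 15 s non-overlapping epochs cut strictly within condition
  blocks (a 120 s block yields 8). Blocks shorter than one epoch warn and
  contribute nothing.
- **Epoch rejection** (`reject_bad_epochs`): drop epochs whose
  peak-to-peak amplitude exceeds a threshold (conventional 150 µV) on any
  channel. This is an *optional, explicit* step: the standard condition
  contrast chain (`condition_band_powers` and the CLI default) runs
  without it unless a threshold is supplied, because with the default
  generator settings blink amplitudes (120 µV peak, roughly doubled at
  frontopolar sites by summation with background) would reject nearly all
  eyes-open epochs and the contrast is robust to artifacts through the
  cluster statistics anyway. Pass `ptp_threshold_uV` (or
  `--ptp-threshold`) to enable it.
- **PSD**: per-epoch Hanning-window periodogram (`scipy.signal.periodogram`,
  density scaling, no detrending — the band-pass already removed DC).
  A DPSS multitaper option (`taper="dpss"`, NW = 4) is provided for
  smoother spectra.
- **Band power**: trapezoidal integral of the PSD over `[low, high)`
  (delta 1–4, theta 4–8, alpha 8–12, beta 12–30 Hz), per epoch and channel.
- **Cluster-based permutation test**: two-sample pooled-variance t on
  log₁₀ band power per channel; channels with `|t|` above the two-sided
  `α = 0.05` critical value form sign-specific connected components over
  the montage adjacency (distance ≤ 1.3× the median nearest-neighbour
  distance, plus forced mastoid–temporal edges); cluster mass = Σt; the
  null is the maximum `|mass|` over `n_perm` random relabelings (computed
  vectorized via group-membership matrix products); p-value
  `(1 + #{null ≥ |observed|}) / (1 + n_perm)`. A variance floor of 10⁻²⁴
  guards degenerate inputs.

## 7. Numerical and design decisions

- Counts and deltas are int64 throughout the codec; bit packing uses an
  arbitrary-precision integer accumulator, so no intermediate overflow is
  possible.
- `round_half_away_from_zero` (not banker's rounding) keeps the codec
  symmetric in the sign of the difference; clipping at the signed rails is
  necessarily asymmetric (−2^(n−1) vs 2^(n−1)−1).
- Factor-3 output rate is reported as the integer 167 Hz for the wire
  format and user display, while internal timing uses the exact 500/3 Hz.
- CSV I/O is strict by default (column names, order, uniform time grid
  within 10⁻³ samples) and snaps the inferred rate to the known set
  {500, 250, 500/3} to avoid drift from 6-decimal timestamps.
- Tests avoid mirroring implementation arithmetic: filters are checked
  against frequency-response oracles, the PSD against `mne`, the codec
  against an independent scalar reference, and the permutation test
  against its nominal type-I error rate (500 null simulations).

## 8. Problem sizes and runtime

The end-to-end suite pushes ten full default sessions (20 min, 24 ch,
500 Hz ≈ 14.4 M samples each) through the complete chain in a shared
fixture (~3 minutes total with the JIT kernel; the pure-Python fallback is
slower but identical). `scripts/acceptance.py` runs one such session plus
structural size checks in ~20 s.

## 9. Limitations

- The generator's artifact model is schematic; real blink topographies and
  ocular source geometry are richer.
- The codec has no error-correction or retransmission model beyond the
  dropped-packet counter; `simulate_loss` models erasures only.
- The permutation test assumes exchangeability of epochs across
  conditions; slow nonstationarities within a session violate this mildly.
- 167 Hz telemetry narrows the analyzable band (Nyquist ≈ 83 Hz before
  firmware filtering) but all default analyses stay below 30 Hz.
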