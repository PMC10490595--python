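"""End-to-end plumbing: recording -> telemetry stream -> decoded recording.

The encoder runs the firmware front end, delta-encodes the resulting ADC
counts, and emits the wire messages in transmission order: one config
message, then once per second a shift update immediately followed by the
data packets it governs (one packet per multichannel sample, packet IDs
incrementing mod 16).  The decoder is stateful and loss-tolerant: it applies
shift tables as they arrive and integrates deltas, so after a dropped packet
the reconstruction carries a bounded offset until the high-pass-filtered
signal re-centres it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import codec, framing
from .frontend import FilterConfig, dequantize, map_events, run_frontend
from .recording import Recording


def encode_recording(recording: Recording, filter_config: FilterConfig | None = None,
                     bit_length: int = 10, battery_mV: int = 3700
                     ) -> list[framing.Message]:
    """Front-end + codec + framing for a 500 Hz µV recording."""
    fcfg = filter_config or FilterConfig()
    counts, fs_out = run_frontend(recording, fcfg)
    ccfg = codec.CodecConfig(bit_length=bit_length, fs_out=fs_out)
    deltas, schedule = codec.encode_stream(counts, ccfg)
    messages: list[framing.Message] = [framing.ConfigMessage(
        gain=fcfg.gain, rate_hz=int(round(fs_out)), bit_length=bit_length,
        battery_mV=battery_mV)]
    sched = dict(schedule)
    n = deltas.shape[1]
    for i in range(n):
        pid = i % 16
        if i in sched:
            messages.append(framing.ShiftUpdate(pid, sched[i]))
        messages.append(framing.DataPacket(pid, 0, deltas[:, i], bit_length))
    return messages


@dataclass
class StreamDecoder:
    """Replays a message sequence into reconstructed ADC counts."""

    state: codec.DecoderState = field(default_factory=codec.reset_decoder)
    config_msg: framing.ConfigMessage | None = None
    _codec_cfg: codec.CodecConfig | None = None
    _pending_shifts: tuple[int, np.ndarray] | None = None
    frames: list[np.ndarray] = field(default_factory=list)

    def feed(self, message: framing.Message) -> None:
        if isinstance(message, framing.ConfigMessage):
            self.config_msg = message
            fs_out = 250.0 if message.rate_hz == 250 else 500.0 / 3.0
            self._codec_cfg = codec.CodecConfig(bit_length=message.bit_length,
                                                fs_out=fs_out)
        elif isinstance(message, framing.ShiftUpdate):
            self._pending_shifts = (message.ref_packet_id, message.shifts)
        elif isinstance(message, framing.DataPacket):
            if self._codec_cfg is None:
                raise framing.MalformedPacketError(
                    "data packet before any config message")
            if self._pending_shifts is not None:
                ref, shifts = self._pending_shifts
                if message.packet_id == ref:
                    codec.apply_shift_table(self.state, shifts)
                    self._pending_shifts = None
            st = self.state
            if st.last_packet_id is not None:
                lost = (message.packet_id - st.last_packet_id - 1) % 16
                st.cumulative_dropped += max(lost, message.dropped)
            st.last_packet_id = message.packet_id
            self.frames.append(
                codec.decode_frame(st, message.values, self._codec_cfg))
        else:  # pragma: no cover
            raise TypeError(f"cannot decode {type(message).__name__}")

    def counts(self) -> np.ndarray:
        if not self.frames:
            return np.empty((codec.N_CHANNELS, 0), dtype=np.int64)
        return np.stack(self.frames, axis=1)


def decode_messages(messages: list[framing.Message],
                    labels: tuple[str, ...],
                    events: list[tuple[int, str]] | None = None
                    ) -> Recording:
    """Decode a message sequence to a µV Recording at the telemetry rate.

    ``events`` are condition onsets already expressed at the output rate
    (see :func:`dreamstream.frontend.map_events`).
    """
    dec = StreamDecoder()
    for m in messages:
        dec.feed(m)
    if dec.config_msg is None:
        raise framing.MalformedPacketError("stream contains no config message")
    counts = dec.counts()
    volts = dequantize(counts, dec.config_msg.gain)
    fs = 250.0 if dec.config_msg.rate_hz == 250 else 500.0 / 3.0
    return Recording(fs, labels, volts * 1e6, list(events or []))


def roundtrip(recording: Recording, filter_config: FilterConfig | None = None,
              bit_length: int = 10) -> Recording:
    """Full telemetry round trip of a 500 Hz recording (lossless link)."""
    fcfg = filter_config or FilterConfig()
    messages = encode_recording(recording, fcfg, bit_length)
    events = map_events(recording.events, fcfg.downsample_factor)
    return decode_messages(messages, recording.labels, events)
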