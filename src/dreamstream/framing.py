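"""Bit-exact wire format: data packets, shift updates, config readback.

Three message kinds travel between device and host:

* **Data packet** -- a 1-byte header (packet ID in the high nibble, count of
  internally dropped packets in the low nibble) followed by 24 signed channel
  values of 10, 14 or 16 bits, packed contiguously MSB-first with no padding
  between values, so values span byte boundaries.  Total size 31, 43 or 49
  bytes.
* **Shift update** -- 14 bytes: reference packet ID, a reserved flags byte,
  then the 24 per-channel 4-bit shift codes two per byte (even channel in the
  high nibble).
* **Config message** -- 8 bytes: gain code, rate code, bit-length code,
  filter mask, battery millivolts (big-endian u16) and two reserved bytes.

A byte-stream container for offline files tags each message with one type
byte (0x60/0x61/0x62 for data at 10/14/16 bits, 0xDE for shift updates,
0xC0 for config).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ALLOWED_BIT_LENGTHS = (10, 14, 16)
N_CHANNELS = 24
SHIFT_UPDATE_SIZE = 14
CONFIG_SIZE = 8

GAIN_CODES = {0: 1, 1: 2, 2: 4, 3: 8}
RATE_CODES = {0: 250, 1: 167}
BITLEN_CODES = {0: 10, 1: 14, 2: 16}

#: container type tags
TAG_DATA = {10: 0x60, 14: 0x61, 16: 0x62}
TAG_SHIFT = 0xDE
TAG_CONFIG = 0xC0


def data_packet_size(bit_length: int) -> int:
    """Header byte plus the packed payload: 1 + ceil(24 n / 8) bytes."""
    if bit_length not in ALLOWED_BIT_LENGTHS:
        raise ValueError(f"bit length must be one of {ALLOWED_BIT_LENGTHS}")
    return 1 + (N_CHANNELS * bit_length + 7) // 8


class MalformedPacketError(ValueError):
    """Raised when bytes cannot be parsed as the expected message."""


@dataclass
class DataPacket:
    packet_id: int
    dropped: int
    values: np.ndarray
    bit_length: int = 10

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.bit_length not in ALLOWED_BIT_LENGTHS:
            raise ValueError(f"bit length must be one of {ALLOWED_BIT_LENGTHS}")
        if not 0 <= self.packet_id <= 15 or not 0 <= self.dropped <= 15:
            raise ValueError("packet_id and dropped are 4-bit fields")
        if self.values.shape != (N_CHANNELS,):
            raise ValueError(f"expected {N_CHANNELS} channel values")


@dataclass
class ShiftUpdate:
    ref_packet_id: int
    shifts: np.ndarray
    flags: int = 0

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=np.int64)
        if not 0 <= self.ref_packet_id <= 15:
            raise ValueError("ref_packet_id is a 4-bit field")
        if not 0 <= self.flags <= 255:
            raise ValueError("flags is one byte")
        if (self.shifts.shape != (N_CHANNELS,) or self.shifts.min() < 0
                or self.shifts.max() > 15):
            raise ValueError("24 shift codes in [0, 15] required")


@dataclass
class ConfigMessage:
    gain: int = 8
    rate_hz: int = 250
    bit_length: int = 10
    filter_mask: int = 0
    battery_mV: int = 3700

    _GAIN_TO_CODE = {v: k for k, v in GAIN_CODES.items()}
    _RATE_TO_CODE = {v: k for k, v in RATE_CODES.items()}
    _BITLEN_TO_CODE = {v: k for k, v in BITLEN_CODES.items()}

    def __post_init__(self) -> None:
        if self.gain not in self._GAIN_TO_CODE:
            raise ValueError("gain must be 1, 2, 4 or 8")
        if self.rate_hz not in self._RATE_TO_CODE:
            raise ValueError("rate must be 250 or 167 Hz")
        if self.bit_length not in self._BITLEN_TO_CODE:
            raise ValueError(f"bit length must be one of {ALLOWED_BIT_LENGTHS}")
        if not 0 <= self.filter_mask <= 255:
            raise ValueError("filter_mask is one byte")
        if not 0 <= self.battery_mV <= 0xFFFF:
            raise ValueError("battery_mV is an unsigned 16-bit value")


def pack_data_packet(packet: DataPacket) -> bytes:
    """Serialize a data packet (header byte + contiguous MSB-first payload)."""
    n = packet.bit_length
    lo, hi = -(1 << (n - 1)), (1 << (n - 1)) - 1
    v = packet.values
    if v.min() < lo or v.max() > hi:
        raise ValueError(f"values outside signed {n}-bit range")
    header = (packet.packet_id << 4) | min(packet.dropped, 15)
    mask = (1 << n) - 1
    acc = 0
    for x in v.tolist():  # two's complement, MSB-first, no spacing
        acc = (acc << n) | (int(x) & mask)
    total_bits = N_CHANNELS * n
    pad = (-total_bits) % 8
    acc <<= pad  # zero-fill the low bits of a trailing partial byte
    payload = acc.to_bytes((total_bits + pad) // 8, "big")
    return bytes([header]) + payload


def unpack_data_packet(data: bytes, bit_length: int) -> DataPacket:
    """Exact inverse of :func:`pack_data_packet`, with sign extension."""
    expected = data_packet_size(bit_length)
    if len(data) != expected:
        raise MalformedPacketError(
            f"expected {expected} bytes for {bit_length}-bit packet, "
            f"got {len(data)}")
    header = data[0]
    packet_id, dropped = header >> 4, header & 0x0F
    n = bit_length
    acc = int.from_bytes(data[1:], "big")
    total_bits = N_CHANNELS * n
    acc >>= ((len(data) - 1) * 8 - total_bits)  # drop padding bits
    mask = (1 << n) - 1
    sign = 1 << (n - 1)
    values = np.empty(N_CHANNELS, dtype=np.int64)
    for i in range(N_CHANNELS - 1, -1, -1):
        x = acc & mask
        values[i] = x - (1 << n) if x & sign else x
        acc >>= n
    return DataPacket(packet_id, dropped, values, bit_length)


def pack_shift_update(update: ShiftUpdate) -> bytes:
    out = bytearray([update.ref_packet_id, update.flags])
    s = update.shifts.tolist()
    for k in range(0, N_CHANNELS, 2):  # even channel in the high nibble
        out.append((int(s[k]) << 4) | int(s[k + 1]))
    return bytes(out)


def parse_shift_update(data: bytes) -> ShiftUpdate:
    if len(data) != SHIFT_UPDATE_SIZE:
        raise MalformedPacketError(
            f"shift update must be {SHIFT_UPDATE_SIZE} bytes, got {len(data)}")
    if data[0] > 15:
        raise MalformedPacketError("reference packet ID exceeds 4 bits")
    shifts = np.empty(N_CHANNELS, dtype=np.int64)
    for k, b in enumerate(data[2:]):
        shifts[2 * k] = b >> 4
        shifts[2 * k + 1] = b & 0x0F
    return ShiftUpdate(data[0], shifts, flags=data[1])


def pack_config(msg: ConfigMessage) -> bytes:
    return bytes([
        msg._GAIN_TO_CODE[msg.gain],
        msg._RATE_TO_CODE[msg.rate_hz],
        msg._BITLEN_TO_CODE[msg.bit_length],
        msg.filter_mask,
        msg.battery_mV >> 8, msg.battery_mV & 0xFF,
        0, 0,
    ])


def parse_config(data: bytes) -> ConfigMessage:
    if len(data) != CONFIG_SIZE:
        raise MalformedPacketError(
            f"config message must be {CONFIG_SIZE} bytes, got {len(data)}")
    gain_code, rate_code, bitlen_code, filter_mask = data[:4]
    for code, table, what in ((gain_code, GAIN_CODES, "gain"),
                              (rate_code, RATE_CODES, "rate"),
                              (bitlen_code, BITLEN_CODES, "bit-length")):
        if code not in table:
            raise MalformedPacketError(f"unknown {what} code {code}")
    battery = (data[4] << 8) | data[5]
    return ConfigMessage(GAIN_CODES[gain_code], RATE_CODES[rate_code],
                         BITLEN_CODES[bitlen_code], filter_mask, battery)


def simulate_loss(packets: list[DataPacket],
                  drop_pattern: list[bool] | np.ndarray
                  ) -> tuple[list[DataPacket], list[int]]:
    """Drop the flagged packets and fix up the dropped-count headers.

    Each delivered packet reports how many packets were lost since the
    previous delivery, saturated at 15 (the 4-bit header field).  Returns the
    delivered packets and the indices of the lost ones.
    """
    drop = list(drop_pattern)
    if len(drop) != len(packets):
        raise ValueError("drop pattern must match the packet stream length")
    delivered: list[DataPacket] = []
    lost_idx: list[int] = []
    pending = 0
    for i, (p, d) in enumerate(zip(packets, drop)):
        if d:
            pending += 1
            lost_idx.append(i)
        else:
            delivered.append(DataPacket(p.packet_id, min(pending, 15),
                                        p.values.copy(), p.bit_length))
            pending = 0
    return delivered, lost_idx


# ---------------------------------------------------------------------------
# offline stream container

Message = DataPacket | ShiftUpdate | ConfigMessage


def write_stream(messages: list[Message]) -> bytes:
    """Serialize a message sequence as [type tag][message bytes] records."""
    out = bytearray()
    for m in messages:
        if isinstance(m, DataPacket):
            out.append(TAG_DATA[m.bit_length])
            out += pack_data_packet(m)
        elif isinstance(m, ShiftUpdate):
            out.append(TAG_SHIFT)
            out += pack_shift_update(m)
        elif isinstance(m, ConfigMessage):
            out.append(TAG_CONFIG)
            out += pack_config(m)
        else:
            raise TypeError(f"cannot serialize {type(m).__name__}")
    return bytes(out)


def read_stream(blob: bytes) -> list[Message]:
    """Parse a container produced by :func:`write_stream`."""
    tag_to_bits = {v: k for k, v in TAG_DATA.items()}
    messages: list[Message] = []
    pos = 0
    while pos < len(blob):
        tag = blob[pos]
        pos += 1
        if tag in tag_to_bits:
            bits = tag_to_bits[tag]
            size = data_packet_size(bits)
            messages.append(unpack_data_packet(blob[pos:pos + size], bits))
        elif tag == TAG_SHIFT:
            size = SHIFT_UPDATE_SIZE
            messages.append(parse_shift_update(blob[pos:pos + size]))
        elif tag == TAG_CONFIG:
            size = CONFIG_SIZE
            messages.append(parse_config(blob[pos:pos + size]))
        else:
            raise MalformedPacketError(f"unknown message tag 0x{tag:02X}")
        pos += size
    return messages
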