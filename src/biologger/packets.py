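"""The device's serial memory format: self-contained 32-bit packets.

Each packet is one 32-bit word: the top 8 bits are a type code, the low
24 bits the payload (a 24-bit two's-complement sample, an unsigned
vitals reading, a time marker, ...).  Words are big-endian on disk.
The NAND module erases to all-ones, so 0xFFFFFFFF acts as the
end-of-data sentinel when parsing a raw memory dump.

High-rate samples carry no timestamp of their own; an absolute-time
marker packet is interleaved periodically and samples after it are
timed by counting at the nominal sampling rate.

The type-code table is this package's own (the wire format fixes only
the 8/24-bit split, not the codes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "Packet",
    "PacketType",
    "REGISTRY",
    "MemoryImage",
    "DeviceState",
    "DecodedStreams",
    "encode_packet",
    "decode_packet",
    "packet_to_bytes",
    "packets_to_bytes",
    "append_packet",
    "record_vitals",
    "parse_dump",
    "ERASED_WORD",
    "LOW_VOLTAGE_CUTOFF_V",
]

ERASED_WORD = 0xFFFFFFFF
LOW_VOLTAGE_CUTOFF_V = 2.4
PAYLOAD_MAX = 2**24 - 1

#: Default NAND capacity: 2 Gbit / 32-bit words.
DEFAULT_CAPACITY_PACKETS = (2 * 2**30) // 32


def _to_signed24(payload: int) -> int:
    return payload - 2**24 if payload >= 2**23 else payload


def _from_signed24(value: int) -> int:
    if not -(2**23) <= value < 2**23:
        raise OverflowError("value outside signed 24-bit range")
    return value & PAYLOAD_MAX


@dataclass(frozen=True)
class PacketType:
    code: int
    name: str
    signed: bool = False
    #: nominal sampling rate for stream types (None = aperiodic)
    nominal_fs: Optional[float] = None

    def decode(self, payload: int) -> int:
        return _to_signed24(payload) if self.signed else payload

    def encode(self, value: int) -> int:
        if self.signed:
            return _from_signed24(int(value))
        value = int(value)
        if not 0 <= value <= PAYLOAD_MAX:
            raise OverflowError("value outside unsigned 24-bit range")
        return value


# EEG samples are signed 24-bit front-end codes; axy samples signed raw
# counts; vitals are unsigned mV / centi-degC; the time marker carries
# whole seconds since the device epoch.
_TYPES = [
    PacketType(0x01, "eeg_ch0", signed=True, nominal_fs=125.0),
    PacketType(0x02, "eeg_ch1", signed=True, nominal_fs=125.0),
    PacketType(0x03, "eeg_ch2", signed=True, nominal_fs=125.0),
    PacketType(0x04, "eeg_ch3", signed=True, nominal_fs=125.0),
    PacketType(0x10, "axy_x", signed=True, nominal_fs=1.0),
    PacketType(0x11, "axy_y", signed=True, nominal_fs=1.0),
    PacketType(0x12, "axy_z", signed=True, nominal_fs=1.0),
    PacketType(0x20, "vitals_voltage_mv"),
    PacketType(0x21, "vitals_temperature_cdegc", signed=True),
    PacketType(0x30, "time_s"),
    PacketType(0x40, "event"),
]

REGISTRY: dict[int, PacketType] = {t.code: t for t in _TYPES}
TYPE_BY_NAME: dict[str, PacketType] = {t.name: t for t in _TYPES}


@dataclass(frozen=True)
class Packet:
    """One typed 32-bit packet: 8-bit type code, 24-bit payload."""

    type_code: int
    payload: int

    def __post_init__(self) -> None:
        if not 0 <= self.type_code <= 0xFF:
            raise OverflowError(f"type_code {self.type_code} outside 8 bits")
        if not 0 <= self.payload <= PAYLOAD_MAX:
            raise OverflowError(f"payload {self.payload} outside 24 bits")

    @classmethod
    def make(cls, name: str, value: int) -> "Packet":
        """Build a packet of a registered type from its semantic value."""
        ptype = TYPE_BY_NAME[name]
        return cls(type_code=ptype.code, payload=ptype.encode(value))

    @property
    def value(self) -> int:
        """Semantic payload value (signed where the type says so)."""
        ptype = REGISTRY.get(self.type_code)
        return ptype.decode(self.payload) if ptype else self.payload


def encode_packet(p: Packet) -> int:
    """Pack into one 32-bit word: ``(type_code << 24) | payload``."""
    return (p.type_code << 24) | p.payload


def decode_packet(word: int) -> Packet:
    if not 0 <= word <= 0xFFFFFFFF:
        raise OverflowError("word outside 32 bits")
    return Packet(type_code=word >> 24, payload=word & PAYLOAD_MAX)


def packet_to_bytes(p: Packet) -> bytes:
    return encode_packet(p).to_bytes(4, "big")


def packets_to_bytes(packets) -> bytes:
    return b"".join(packet_to_bytes(p) for p in packets)


@dataclass
class MemoryImage:
    """Append-only model of the serial NAND packet store."""

    capacity_packets: int = DEFAULT_CAPACITY_PACKETS
    packets: list[Packet] = field(default_factory=list)

    @property
    def write_address(self) -> int:
        return len(self.packets)

    @property
    def full(self) -> bool:
        return self.write_address >= self.capacity_packets

    def to_bytes(self) -> bytes:
        return packets_to_bytes(self.packets)


_DEFAULT_SETTINGS: dict = {"advertising_interval_ms": 500, "duty_cycle": 1.0}


@dataclass
class DeviceState:
    """Battery, clock and settings of the running device.

    Below 2.4 V the device resets its settings to defaults and halts all
    memory writes; the halt latches until an explicit reset, regardless
    of later battery readings.
    """

    battery_v: float = 3.0
    time: float = 0.0
    settings: dict = field(default_factory=lambda: dict(_DEFAULT_SETTINGS))
    halted: bool = False

    def check_voltage(self) -> None:
        if self.battery_v < LOW_VOLTAGE_CUTOFF_V and not self.halted:
            self.halted = True
            self.settings = dict(_DEFAULT_SETTINGS)

    def reset(self) -> None:
        self.halted = False
        self.settings = dict(_DEFAULT_SETTINGS)


def append_packet(image: MemoryImage, p: Packet, state: DeviceState) -> str:
    """Write one packet, honoring the low-voltage and memory-full guards.

    Returns ``"written"``, ``"rejected_halted"`` or ``"rejected_full"``.
    Rejections are statuses, not errors.
    """
    state.check_voltage()
    if state.halted:
        return "rejected_halted"
    if image.full:
        return "rejected_full"
    image.packets.append(p)
    return "written"


def record_vitals(
    image: MemoryImage,
    state: DeviceState,
    session_clock,
    battery_profile: Optional[Callable[[float], float]] = None,
    temperature_c: float = 25.0,
    event_times=(),
) -> list[Packet]:
    """Log vitals triplets at every 60-s boundary of a session clock.

    ``session_clock`` is the monotonic sequence of 1-s timer ticks
    (seconds).  At each whole minute the device appends one time, one
    voltage and one temperature packet; a time packet is also logged at
    each ``event_times`` entry (settings/mode changes).  A
    ``battery_profile(t)`` callable lets the battery sag during the
    session, exercising the low-voltage guard mid-run.  Returns the
    packets actually written.
    """
    ticks = np.asarray(list(session_clock), dtype=float)
    if ticks.size and np.any(np.diff(ticks) < 0):
        raise ValueError("session_clock must be monotonic")
    events = sorted(float(t) for t in event_times)
    written: list[Packet] = []

    def _append(p: Packet) -> bool:
        if append_packet(image, p, state) == "written":
            written.append(p)
            return True
        return False

    for t in ticks:
        state.time = t
        if battery_profile is not None:
            state.battery_v = battery_profile(t)
        while events and events[0] <= t:
            events.pop(0)
            _append(Packet.make("time_s", int(t)))
        if t > 0 and t % 60.0 == 0:
            # time marker first so the readings that follow are stamped
            _append(Packet.make("time_s", int(t)))
            _append(Packet.make("vitals_voltage_mv", int(round(state.battery_v * 1000))))
            _append(Packet.make("vitals_temperature_cdegc", int(round(temperature_c * 100))))
    return written


@dataclass
class DecodedStreams:
    """Result of parsing a raw memory dump.

    ``series`` maps type names to (times, values) arrays; samples are
    timestamped by counting at the type's nominal rate from the
    preceding absolute-time marker (NaN before the first marker).
    Unknown type codes are preserved and counted, never fatal.
    """

    series: dict
    unknown: list  # (word_index, word) pairs
    n_decoded: int
    n_unknown: int
    sentinel_found: bool
    n_words_after_sentinel: int
    trailing_bytes: int
    file_size: int

    @property
    def n_unknown_count(self) -> int:
        return len(self.unknown)

    def byte_accounting_ok(self) -> bool:
        """Exact byte accounting: every input byte is classified once."""
        words = (
            self.n_decoded
            + self.n_unknown
            + (1 if self.sentinel_found else 0)
            + self.n_words_after_sentinel
        )
        return 4 * words + self.trailing_bytes == self.file_size

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {
            name: pd.DataFrame({"time_s": ts, "value": vs})
            for name, (ts, vs) in self.series.items()
        }


def parse_dump(
    raw: bytes,
    eeg_fs: float = 125.0,
    axy_fs: float = 1.0,
) -> DecodedStreams:
    """Parse arbitrary bytes as a memory dump.  Total: never raises.

    Reads big-endian 32-bit words until the erased-NAND sentinel
    (0xFFFFFFFF) or end of input; known types are decoded into typed,
    timestamped series, unknown codes logged and skipped, and a
    truncated trailing word reported.
    """
    raw = bytes(raw)
    n_words = len(raw) // 4
    trailing = len(raw) % 4
    words = np.frombuffer(raw[: 4 * n_words], dtype=">u4")

    sentinel_idx = np.flatnonzero(words == ERASED_WORD)
    if sentinel_idx.size:
        stop = int(sentinel_idx[0])
        sentinel_found = True
        after = n_words - stop - 1
    else:
        stop = n_words
        sentinel_found = False
        after = 0

    rates = {name: t.nominal_fs for name, t in TYPE_BY_NAME.items()}
    rates.update({f"eeg_ch{i}": eeg_fs for i in range(4)})
    rates.update({k: axy_fs for k in ("axy_x", "axy_y", "axy_z")})

    times: dict[str, list] = {}
    values: dict[str, list] = {}
    unknown: list[tuple[int, int]] = []
    current_time: float = float("nan")
    counters: dict[str, int] = {}
    n_decoded = 0

    for i in range(stop):
        word = int(words[i])
        code = word >> 24
        payload = word & PAYLOAD_MAX
        ptype = REGISTRY.get(code)
        if ptype is None:
            unknown.append((i, word))
            continue
        n_decoded += 1
        value = ptype.decode(payload)
        if ptype.name == "time_s":
            current_time = float(value)
            counters = {}  # re-reference every stream to the new marker
        fs = rates.get(ptype.name)
        if fs:
            k = counters.get(ptype.name, 0)
            t = current_time + k / fs if np.isfinite(current_time) else float("nan")
            counters[ptype.name] = k + 1
        else:
            t = current_time
        times.setdefault(ptype.name, []).append(t)
        values.setdefault(ptype.name, []).append(value)

    series = {
        name: (np.asarray(times[name]), np.asarray(values[name]))
        for name in times
    }
    return DecodedStreams(
        series=series,
        unknown=unknown,
        n_decoded=n_decoded,
        n_unknown=len(unknown),
        sentinel_found=sentinel_found,
        n_words_after_sentinel=after,
        trailing_bytes=trailing,
        file_size=len(raw),
    )
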