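"""Bluetooth heart-rate-measurement packet codec.

The chest-strap sensors this pipeline targets transmit the standard GATT
Heart Rate Measurement characteristic at roughly 1 Hz: a flags byte, an
8- or 16-bit heart-rate field, an optional 16-bit energy-expended field,
and zero or more 16-bit little-endian R-R intervals expressed in units of
1/1024 s.  :func:`decode_packet` turns one payload into millisecond R-R
values; :class:`PacketStreamDecoder` additionally accumulates the beat
clock (cumulative R-R sum) across a stream so every interval carries its
position in beat time.  :func:`encode_packets` is the inverse, used to
replay synthetic tachograms through the exact wire path a sensor would use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import MalformedPacketError

# Flag bits of the heart-rate-measurement characteristic.
_FLAG_HR_16BIT = 0x01
_FLAG_ENERGY_PRESENT = 0x08
_FLAG_RR_PRESENT = 0x10

#: milliseconds represented by one raw R-R unit (1/1024 s)
RR_UNIT_MS = 1000.0 / 1024.0

#: worst-case absolute quantization error of an encode/decode round trip
QUANTIZATION_BOUND_MS = 1000.0 / 2048.0


@dataclass(frozen=True)
class RawPacket:
    """One heart-rate-measurement frame as received from the transport.

    Parameters
    ----------
    payload
        Raw characteristic value, at least two bytes (flags + 8-bit HR).
    arrival_time
        Seconds since the start of the stream, monotone non-decreasing.
        Retained only as an eviction fallback; the physiological clock is
        the cumulative R-R sum.
    """

    payload: bytes
    arrival_time: float = 0.0

    def __post_init__(self) -> None:
        if len(self.payload) < 2:
            raise MalformedPacketError(
                f"payload has {len(self.payload)} bytes; need >= 2 (flags + HR)"
            )


@dataclass(frozen=True)
class RRSample:
    """A single inter-beat interval placed on the beat clock.

    ``beat_time_s`` is the cumulative sum of all preceding ``rr_ms`` values
    (including this one) divided by 1000 -- i.e. the time of the beat that
    *closes* the interval, in seconds since the first beat of the stream.
    """

    rr_ms: float
    beat_time_s: float

    def __post_init__(self) -> None:
        if not self.rr_ms > 0:
            raise ValueError(f"rr_ms must be positive, got {self.rr_ms}")


@dataclass(frozen=True)
class DecodedPacket:
    """Result of decoding one frame: the HR reading plus raw RR values."""

    hr_bpm: int
    rr_ms: tuple[float, ...]


def decode_packet(packet: RawPacket | bytes) -> DecodedPacket:
    """Decode one heart-rate-measurement payload.

    Returns the heart-rate reading and the R-R intervals converted to
    milliseconds (raw value x 1000/1024), in wire order.  An unset RR flag
    yields an empty tuple -- that is a valid packet, not an error.

    Raises
    ------
    MalformedPacketError
        If the payload is shorter than its flags demand, or the RR region
        length is not a positive multiple of two.
    """
    payload = packet.payload if isinstance(packet, RawPacket) else bytes(packet)
    if len(payload) < 2:
        raise MalformedPacketError("payload shorter than flags + HR")
    flags = payload[0]
    pos = 1
    if flags & _FLAG_HR_16BIT:
        if len(payload) < pos + 2:
            raise MalformedPacketError("flags promise 16-bit HR but payload is short")
        hr = int.from_bytes(payload[pos : pos + 2], "little")
        pos += 2
    else:
        hr = payload[pos]
        pos += 1
    if flags & _FLAG_ENERGY_PRESENT:
        if len(payload) < pos + 2:
            raise MalformedPacketError("flags promise energy-expended field but payload is short")
        pos += 2
    if not flags & _FLAG_RR_PRESENT:
        return DecodedPacket(hr_bpm=hr, rr_ms=())
    rr_region = payload[pos:]
    if len(rr_region) == 0 or len(rr_region) % 2:
        raise MalformedPacketError(
            f"RR flag set but RR region has {len(rr_region)} bytes "
            "(need a positive multiple of 2)"
        )
    rr_ms = tuple(
        int.from_bytes(rr_region[i : i + 2], "little") * RR_UNIT_MS
        for i in range(0, len(rr_region), 2)
    )
    return DecodedPacket(hr_bpm=hr, rr_ms=rr_ms)


class PacketStreamDecoder:
    """Accumulate RR samples across packets, assigning beat times.

    The k-th interval of the stream gets ``beat_time_s`` equal to the exact
    cumulative sum of the first k ``rr_ms`` values divided by 1000; packet
    boundaries are invisible to the beat clock.
    """

    def __init__(self) -> None:
        self._cum_ms = 0.0
        self.last_hr_bpm: int | None = None

    def feed(self, packet: RawPacket | bytes) -> list[RRSample]:
        """Decode one packet and return its RR intervals as placed samples."""
        decoded = decode_packet(packet)
        self.last_hr_bpm = decoded.hr_bpm
        out = []
        for rr in decoded.rr_ms:
            self._cum_ms += rr
            out.append(RRSample(rr_ms=rr, beat_time_s=self._cum_ms / 1000.0))
        return out

    def feed_all(self, packets: Iterable[RawPacket | bytes]) -> list[RRSample]:
        samples: list[RRSample] = []
        for p in packets:
            samples.extend(self.feed(p))
        return samples


def rr_to_samples(rr_ms: Sequence[float]) -> list[RRSample]:
    """Place bare millisecond intervals on the beat clock (cumulative sums)."""
    out = []
    cum = 0.0
    for rr in rr_ms:
        cum += rr
        out.append(RRSample(rr_ms=float(rr), beat_time_s=cum / 1000.0))
    return out


def encode_packets(
    rr_ms: Sequence[float], packet_rate_hz: float = 1.0
) -> list[RawPacket]:
    """Encode millisecond R-R intervals as heart-rate-measurement frames.

    Intervals are quantized to 1/1024-s units (round-half-to-even via
    ``round``), grouped into packets so that each packet spans roughly
    ``1/packet_rate_hz`` seconds of beat time, and stamped with an HR field
    equal to the rounded mean instantaneous rate of the packet's beats.
    Round-tripping through :func:`decode_packet` recovers the input to
    within ``QUANTIZATION_BOUND_MS`` per sample.

    Raises
    ------
    ValueError
        If any interval is not strictly positive or the rate is not positive.
    """
    if packet_rate_hz <= 0:
        raise ValueError("packet_rate_hz must be positive")
    rr_list = [float(v) for v in rr_ms]
    for v in rr_list:
        if not v > 0:
            raise ValueError(f"RR intervals must be positive, got {v}")
    if not math.isfinite(packet_rate_hz):
        raise ValueError("packet_rate_hz must be finite")

    span_ms = 1000.0 / packet_rate_hz
    packets: list[RawPacket] = []
    group: list[float] = []
    group_ms = 0.0
    cum_ms = 0.0

    def flush() -> None:
        nonlocal group, group_ms
        if not group:
            return
        hr = int(round(60000.0 / (sum(group) / len(group))))
        hr = max(0, min(255, hr))
        body = bytearray([_FLAG_RR_PRESENT, hr])
        for v in group:
            raw = int(round(v / RR_UNIT_MS))
            if not 0 < raw <= 0xFFFF:
                raise ValueError(f"RR interval {v} ms out of encodable range")
            body += raw.to_bytes(2, "little")
        packets.append(RawPacket(payload=bytes(body), arrival_time=cum_ms / 1000.0))
        group = []
        group_ms = 0.0

    for v in rr_list:
        group.append(v)
        group_ms += v
        cum_ms += v
        if group_ms >= span_ms:
            flush()
    flush()
    return packets
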