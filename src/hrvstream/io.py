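"""Replay readers and writers.

Two on-disk stream formats:

* plain-text RR files -- one interval in milliseconds per line, blank lines
  and ``#`` comments ignored;
* binary packet logs -- length-prefixed heart-rate-measurement frames
  (1 unsigned byte frame length, then the payload), for bit-faithful replay
  of a sensor session.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator, Sequence

from .errors import MalformedPacketError
from .packets import PacketStreamDecoder, RawPacket, RRSample


def read_rr_text(path: str | Path) -> list[float]:
    """Read a plain-text RR file into a list of millisecond values."""
    out: list[float] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        body = line.split("#", 1)[0].strip()
        if not body:
            continue
        try:
            out.append(float(body))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: not a number: {body!r}") from exc
    return out


def write_rr_text(path: str | Path, rr_ms: Sequence[float]) -> None:
    Path(path).write_text("".join(f"{v:.6g}\n" for v in rr_ms))


def write_packet_log(path: str | Path, packets: Sequence[RawPacket]) -> None:
    """Write frames as ``<len:uint8><payload>`` records."""
    with open(path, "wb") as fh:
        for p in packets:
            if len(p.payload) > 0xFF:
                raise MalformedPacketError("frame longer than 255 bytes")
            fh.write(bytes([len(p.payload)]))
            fh.write(p.payload)


def read_packet_log(path: str | Path) -> Iterator[RawPacket]:
    """Yield frames from a length-prefixed packet log."""
    data = Path(path).read_bytes()
    pos = 0
    while pos < len(data):
        n = data[pos]
        pos += 1
        if pos + n > len(data):
            raise MalformedPacketError(f"truncated frame at byte {pos - 1} of {path}")
        yield RawPacket(payload=data[pos : pos + n])
        pos += n


def decode_packet_log(path: str | Path) -> list[RRSample]:
    """Decode a packet log into beat-time-placed RR samples."""
    return PacketStreamDecoder().feed_all(read_packet_log(path))
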