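"""The JSON HRV record: the unit stored and served by the API.

A record carries the five published markers (HR, RMSSD, SDNN, pNN50,
LF/HF) plus provenance (NN count, timestamp, monotone id).  Metrics
withheld by a gate -- fewer than 10 NN intervals, or HF power at or below
the floor -- are serialized as nulls; the record itself is always emitted
so the update cadence stays observable.
"""

from __future__ import annotations

from datetime import datetime, timezone

from pydantic import BaseModel, ConfigDict, Field, field_validator


def iso_utc(dt: datetime) -> str:
    return dt.astimezone(timezone.utc).isoformat().replace("+00:00", "Z")


def parse_iso(ts: str) -> datetime:
    dt = datetime.fromisoformat(ts.replace("Z", "+00:00"))
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt


class HRVPayload(BaseModel):
    """Client-submitted record body (the server assigns ``record_id``)."""

    model_config = ConfigDict(extra="forbid")

    timestamp: str | None = None
    hr: float | None = Field(default=None, ge=0)
    rmssd: float | None = Field(default=None, ge=0)
    sdnn: float | None = Field(default=None, ge=0)
    pnn50: float | None = Field(default=None, ge=0, le=100)
    lf_hf: float | None = Field(default=None, ge=0)
    lf_power: float | None = Field(default=None, ge=0)
    hf_power: float | None = Field(default=None, ge=0)
    n_nn: int = Field(ge=0)

    @field_validator("timestamp")
    @classmethod
    def _parseable(cls, v: str | None) -> str | None:
        if v is not None:
            parse_iso(v)  # raises ValueError on garbage
        return v


class HRVRecord(HRVPayload):
    """A stored record: payload plus server-assigned identity."""

    record_id: int = Field(ge=0)
    timestamp: str

    @property
    def time(self) -> datetime:
        return parse_iso(self.timestamp)

    def to_json_dict(self) -> dict:
        return self.model_dump(mode="json")
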