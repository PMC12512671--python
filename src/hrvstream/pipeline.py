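"""End-to-end streaming pipeline: RR samples in, HRV records out.

:func:`compute_metrics` cleans one analysis window and computes both metric
families; :func:`stream_records` replays an RR stream through the rolling
60-s buffer, emitting one record every ``update_period_s`` seconds of beat
time (default 5 s).  Records carry wall-clock ISO-8601 UTC timestamps
anchored at a caller-supplied session start, so replays are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta, timezone
from typing import Iterable, Iterator

from .freq_domain import FrequencyDomainMetrics, SpectralConfig, frequency_domain
from .packets import RRSample
from .preprocess import NNSeries, PreprocessConfig, RollingBuffer, clean
from .records import HRVRecord, iso_utc
from .time_domain import TimeDomainMetrics, time_domain

#: seconds between successive record emissions
DEFAULT_UPDATE_PERIOD_S = 5.0


@dataclass(frozen=True)
class WindowMetrics:
    """Both metric families for one analysis window (either may be withheld)."""

    nn: NNSeries
    time: TimeDomainMetrics | None
    freq: FrequencyDomainMetrics | None


def compute_metrics(
    rr_ms: Iterable[float],
    pre_config: PreprocessConfig = PreprocessConfig(),
    spec_config: SpectralConfig = SpectralConfig(),
) -> WindowMetrics:
    """Clean one window and compute time- and frequency-domain metrics.

    Frequency metrics need enough resampled points for a Welch estimate;
    when the window is too short they are withheld (``None``) rather than
    raising, in line with the gating philosophy.
    """
    nn = clean(list(rr_ms), pre_config)
    tmetrics = time_domain(nn, pre_config)
    fmetrics: FrequencyDomainMetrics | None
    try:
        fmetrics = frequency_domain(nn, spec_config) if tmetrics is not None else None
    except Exception:
        fmetrics = None
    return WindowMetrics(nn=nn, time=tmetrics, freq=fmetrics)


def build_record(
    record_id: int,
    timestamp: str,
    metrics: WindowMetrics,
) -> HRVRecord:
    t, f = metrics.time, metrics.freq
    return HRVRecord(
        record_id=record_id,
        timestamp=timestamp,
        hr=None if t is None else t.hr_bpm,
        rmssd=None if t is None else t.rmssd_ms,
        sdnn=None if t is None else t.sdnn_ms,
        pnn50=None if t is None else t.pnn50_pct,
        lf_hf=None if f is None else f.lf_hf,
        lf_power=None if f is None else f.lf_power_ms2,
        hf_power=None if f is None else f.hf_power_ms2,
        n_nn=metrics.nn.n,
    )


def stream_records(
    samples: Iterable[RRSample],
    pre_config: PreprocessConfig = PreprocessConfig(),
    spec_config: SpectralConfig = SpectralConfig(),
    update_period_s: float = DEFAULT_UPDATE_PERIOD_S,
    start_time: datetime | None = None,
    first_record_id: int = 0,
) -> Iterator[HRVRecord]:
    """Replay an RR stream and yield one record per update period.

    The buffer is topped up sample by sample; whenever the beat clock
    crosses the next multiple of ``update_period_s`` the current buffer
    contents are cleaned and turned into a record.  A 60-s replay at the
    default 5-s cadence therefore yields 12 records.  If the stream ends
    between ticks, a final record is flushed from whatever the buffer holds.
    """
    if update_period_s <= 0:
        raise ValueError("update_period_s must be positive")
    if start_time is None:
        start_time = datetime(2000, 1, 1, tzinfo=timezone.utc)
    buffer = RollingBuffer(horizon_s=pre_config.buffer_horizon_s)
    next_tick = update_period_s
    rid = first_record_id
    emitted_at_tick = False
    last_beat = 0.0

    def make(at_s: float) -> HRVRecord:
        nonlocal rid
        metrics = compute_metrics(buffer.rr_ms, pre_config, spec_config)
        rec = build_record(rid, iso_utc(start_time + timedelta(seconds=at_s)), metrics)
        rid += 1
        return rec

    for s in samples:
        buffer.push(s)
        last_beat = s.beat_time_s
        emitted_at_tick = False
        while s.beat_time_s >= next_tick:
            yield make(next_tick)
            emitted_at_tick = s.beat_time_s == next_tick
            next_tick += update_period_s
    if len(buffer) and not emitted_at_tick:
        yield make(last_beat)
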