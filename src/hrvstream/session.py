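"""Session-level analysis: descriptive statistics and condition comparison.

Descriptive statistics summarize each HRV marker (HR, RMSSD, SDNN, pNN50,
LF/HF) across the records computed while the latest 200 R-R intervals were
acquired: minimum, maximum, mean, median, standard deviation (sample, N-1),
interquartile range, coefficient of variation (SD/mean), Fisher skewness
(third standardized moment), excess kurtosis, and range.  On a constant
series the SD-normalized shape statistics are undefined and reported as
such rather than as NaN surprises.

The two-condition comparison places a low-arousal and a high-arousal
snapshot side by side, metric by metric, with signed differences and
percent change -- the computational core of a cognitive-load contrast.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sstats

from .errors import InsufficientDataError
from .packets import RRSample, rr_to_samples
from .pipeline import stream_records
from .preprocess import PreprocessConfig
from .freq_domain import SpectralConfig
from .records import HRVRecord

#: fixed marker order used in tables and comparisons
METRIC_ORDER: tuple[str, ...] = ("hr", "sdnn", "rmssd", "pnn50", "lf_hf")

STAT_ORDER: tuple[str, ...] = (
    "min", "max", "mean", "median", "sd", "iqr", "cv", "skewness", "kurtosis", "range",
)


@dataclass(frozen=True)
class MetricStats:
    """The ten descriptive statistics of one marker (None = undefined)."""

    n: int
    min: float
    max: float
    mean: float
    median: float
    sd: float
    iqr: float
    cv: float | None
    skewness: float | None
    kurtosis: float | None
    range: float

    def as_dict(self) -> dict[str, float | None]:
        return {k: getattr(self, k) for k in STAT_ORDER}


def describe(values: Sequence[float]) -> MetricStats:
    """Descriptive statistics of one value series.

    Requires at least 3 values (below that skewness/kurtosis are
    meaningless).  Skewness and excess kurtosis are reported as ``None``
    for a constant series; CV is ``None`` when the mean is zero.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise InsufficientDataError(f"need >= 3 values, got {x.size}")
    sd = float(np.std(x, ddof=1))
    mean = float(np.mean(x))
    q1, q3 = np.percentile(x, [25.0, 75.0])
    degenerate = sd == 0.0
    return MetricStats(
        n=int(x.size),
        min=float(np.min(x)),
        max=float(np.max(x)),
        mean=mean,
        median=float(np.median(x)),
        sd=sd,
        iqr=float(q3 - q1),
        cv=None if mean == 0.0 else sd / mean,
        skewness=None if degenerate else float(sstats.skew(x, bias=True)),
        kurtosis=None if degenerate else float(sstats.kurtosis(x, fisher=True, bias=True)),
        range=float(np.max(x) - np.min(x)),
    )


def descriptive_stats(
    records: Sequence[HRVRecord | Mapping[str, object]],
) -> dict[str, MetricStats | None]:
    """Per-marker descriptive statistics across a window of records.

    Null (withheld) metric values are dropped per marker; a marker left
    with fewer than 3 values is reported as ``None`` (undefined) rather
    than aborting the whole table.
    """
    table: dict[str, MetricStats | None] = {}
    for metric in METRIC_ORDER:
        vals = []
        for rec in records:
            v = rec.get(metric) if isinstance(rec, Mapping) else getattr(rec, metric)
            if v is not None:
                vals.append(float(v))
        try:
            table[metric] = describe(vals)
        except InsufficientDataError:
            table[metric] = None
    return table


def latest_window_records(
    rr_ms: Sequence[float],
    last_n: int = 200,
    pre_config: PreprocessConfig = PreprocessConfig(),
    spec_config: SpectralConfig = SpectralConfig(),
    update_period_s: float = 5.0,
) -> list[HRVRecord]:
    """Rolling records computed inside the latest ``last_n`` R-R intervals.

    The count-based window is taken on the raw decoded stream; the cleaning
    cascade runs inside it (on each rolling buffer), so the statistics
    describe exactly what the live pipeline would have published while
    those beats arrived.
    """
    window = list(rr_ms)[-last_n:]
    samples: list[RRSample] = rr_to_samples(window)
    return list(stream_records(samples, pre_config, spec_config, update_period_s))


@dataclass(frozen=True)
class ConditionSnapshot:
    """One labelled capture of the live record, e.g. after a task response."""

    label: str  # "low_arousal" | "high_arousal"
    record: HRVRecord

    def __post_init__(self) -> None:
        if self.label not in ("low_arousal", "high_arousal"):
            raise ValueError(f"unknown condition label: {self.label!r}")


@dataclass(frozen=True)
class MetricComparison:
    metric: str
    value_a: float | None
    value_b: float | None
    difference: float | None  # b - a; None when either side is withheld
    percent_change: float | None  # 100*(b-a)/a


def compare_conditions(
    a: ConditionSnapshot, b: ConditionSnapshot
) -> list[MetricComparison]:
    """Metric-by-metric contrast of two snapshots, in the fixed order.

    A marker withheld in either snapshot yields an unavailable (``None``)
    difference row, not an error: the gates propagate.
    """
    rows = []
    for metric in METRIC_ORDER:
        va = getattr(a.record, metric)
        vb = getattr(b.record, metric)
        if va is None or vb is None:
            rows.append(MetricComparison(metric, va, vb, None, None))
            continue
        diff = vb - va
        pct = None if va == 0 else 100.0 * diff / va
        rows.append(MetricComparison(metric, va, vb, diff, pct))
    return rows


# ---------------------------------------------------------------------------
# prompt-ready rendering: deterministic, parseable text blocks


def _fmt(v: float | int | None) -> str:
    if v is None:
        return "withheld"
    if isinstance(v, int):
        return str(v)
    return repr(float(v))


def render_record(record: HRVRecord) -> str:
    lines = ["[hrv_record]"]
    for key in ("record_id", "timestamp", "n_nn"):
        lines.append(f"{key}: {getattr(record, key)}")
    for metric in METRIC_ORDER:
        lines.append(f"{metric}: {_fmt(getattr(record, metric))}")
    return "\n".join(lines) + "\n"


def render_stats(table: Mapping[str, MetricStats | None]) -> str:
    lines = ["[descriptive_stats]"]
    for metric in METRIC_ORDER:
        ms = table.get(metric)
        if ms is None:
            lines.append(f"{metric}: withheld")
            continue
        parts = ", ".join(f"{k}={_fmt(getattr(ms, k))}" for k in STAT_ORDER)
        lines.append(f"{metric}: n={ms.n}, {parts}")
    return "\n".join(lines) + "\n"


def render_comparison(rows: Sequence[MetricComparison]) -> str:
    lines = ["[condition_comparison]"]
    for r in rows:
        lines.append(
            f"{r.metric}: a={_fmt(r.value_a)}, b={_fmt(r.value_b)}, "
            f"diff={_fmt(r.difference)}, pct={_fmt(r.percent_change)}"
        )
    return "\n".join(lines) + "\n"


def parse_record(text: str) -> HRVRecord:
    """Inverse of :func:`render_record` (round-trip identity on records)."""
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    if lines[0] != "[hrv_record]":
        raise ValueError("not a rendered hrv_record block")
    fields: dict[str, object] = {}
    for ln in lines[1:]:
        key, _, raw = ln.partition(":")
        raw = raw.strip()
        key = key.strip()
        if key == "timestamp":
            fields[key] = raw
        elif raw == "withheld":
            fields[key] = None
        elif key in ("record_id", "n_nn"):
            fields[key] = int(raw)
        else:
            fields[key] = float(raw)
    return HRVRecord(**fields)  # type: ignore[arg-type]
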