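"""Artifact rejection and the rolling analysis buffer.

The cleaning cascade runs three stages, in order, over the R-R intervals of
the current analysis window:

1. physiological plausibility -- keep values in [300, 2000] ms (inclusive);
2. a 3-sample median filter -- suppresses isolated spikes, length-preserving
   with edge replication;
3. an interquartile-range fence -- keep values in
   [Q1 - 1.5*IQR, Q3 + 1.5*IQR], quartiles by the linear-interpolation
   percentile convention.

Intervals that survive are "NN" (normal-to-normal) intervals; every
downstream metric is defined on them.  The cascade removes, it never
corrects: no interpolation or beat replacement is performed.

The fence is applied per analysis window (the rolling buffer contents), not
over a whole session, matching a pipeline whose every metric update is
computed from a rolling 60-s buffer.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import OrderingError
from .packets import RRSample


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunables of the cleaning cascade and rolling buffer.

    Defaults are the pipeline's operating point: 300-2000 ms plausibility
    bounds, width-3 median filter, 1.5x IQR fence, 60-s buffer horizon and
    a 10-NN minimum before time-domain metrics are emitted.
    """

    rr_min_ms: float = 300.0
    rr_max_ms: float = 2000.0
    median_width: int = 3
    iqr_k: float = 1.5
    buffer_horizon_s: float = 60.0
    min_nn: int = 10

    def __post_init__(self) -> None:
        if not self.rr_min_ms < self.rr_max_ms:
            raise ValueError("rr_min_ms must be < rr_max_ms")
        if self.median_width < 1 or self.median_width % 2 == 0:
            raise ValueError("median_width must be odd and >= 1")
        if self.iqr_k <= 0:
            raise ValueError("iqr_k must be positive")
        if self.buffer_horizon_s <= 0:
            raise ValueError("buffer_horizon_s must be positive")
        if self.min_nn < 2:
            raise ValueError("min_nn must be >= 2")


@dataclass(frozen=True)
class NNSeries:
    """Ordered NN intervals surviving the cascade for one analysis window."""

    nn_ms: tuple[float, ...]

    @property
    def n(self) -> int:
        return len(self.nn_ms)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.nn_ms, dtype=float)


def plausibility_filter(
    rr_ms: Sequence[float], config: PreprocessConfig = PreprocessConfig()
) -> list[float]:
    """Keep only values within the physiological bounds, order preserved.

    Bounds are inclusive: 300 ms and 2000 ms themselves survive.
    """
    lo, hi = config.rr_min_ms, config.rr_max_ms
    return [float(v) for v in rr_ms if lo <= v <= hi]


def median3_filter(rr_ms: Sequence[float]) -> list[float]:
    """Width-3 running median with edge replication; length-preserving.

    ``out[i] = median(x[i-1], x[i], x[i+1])`` for interior points; the first
    and last windows replicate the edge sample.  Series of length < 3 pass
    through unchanged.
    """
    x = [float(v) for v in rr_ms]
    n = len(x)
    if n < 3:
        return x
    padded = [x[0]] + x + [x[-1]]
    return [sorted(padded[i : i + 3])[1] for i in range(n)]


def iqr_fences(
    rr_ms: Sequence[float], config: PreprocessConfig = PreprocessConfig()
) -> tuple[float, float]:
    """Outlier fences [Q1 - k*IQR, Q3 + k*IQR] of the input.

    Quartiles use the linear-interpolation percentile convention
    (numpy's default).
    """
    x = np.asarray(rr_ms, dtype=float)
    if x.size == 0:
        raise ValueError("cannot compute fences of an empty series")
    q1, q3 = np.percentile(x, [25.0, 75.0])
    iqr = q3 - q1
    return float(q1 - config.iqr_k * iqr), float(q3 + config.iqr_k * iqr)


def iqr_filter(
    rr_ms: Sequence[float], config: PreprocessConfig = PreprocessConfig()
) -> list[float]:
    """Keep values inside the IQR fences of the input window, order preserved."""
    x = [float(v) for v in rr_ms]
    if not x:
        return x
    lo, hi = iqr_fences(x, config)
    return [v for v in x if lo <= v <= hi]


def clean(
    rr_ms: Sequence[float], config: PreprocessConfig = PreprocessConfig()
) -> NNSeries:
    """Run the full cascade (plausibility -> median -> IQR) on one window."""
    stage1 = plausibility_filter(rr_ms, config)
    stage2 = median3_filter(stage1)
    stage3 = iqr_filter(stage2, config)
    return NNSeries(nn_ms=tuple(stage3))


@dataclass
class RollingBuffer:
    """Time-horizon-bounded ordered store of RR samples.

    Retains the samples whose beat time lies in the half-open window
    ``(newest_beat_time - horizon, newest_beat_time]``; pushes evict only
    the oldest samples and never reorder.  With the default 60-s horizon,
    a steady 1-beat-per-second stream settles at 60 retained samples
    (span 59 s).
    """

    horizon_s: float = 60.0
    _samples: deque[RRSample] = field(default_factory=deque, repr=False)

    def __len__(self) -> int:
        return len(self._samples)

    @property
    def samples(self) -> tuple[RRSample, ...]:
        return tuple(self._samples)

    @property
    def rr_ms(self) -> list[float]:
        return [s.rr_ms for s in self._samples]

    @property
    def span_s(self) -> float:
        if len(self._samples) < 2:
            return 0.0
        return self._samples[-1].beat_time_s - self._samples[0].beat_time_s

    def push(self, samples: RRSample | Iterable[RRSample]) -> list[RRSample]:
        """Append samples in beat-time order; return the evicted ones.

        Raises
        ------
        OrderingError
            If an incoming beat time does not exceed the newest retained one.
        """
        if isinstance(samples, RRSample):
            samples = [samples]
        evicted: list[RRSample] = []
        for s in samples:
            if self._samples and s.beat_time_s <= self._samples[-1].beat_time_s:
                raise OrderingError(
                    f"beat_time {s.beat_time_s} s not after newest "
                    f"{self._samples[-1].beat_time_s} s"
                )
            self._samples.append(s)
            cutoff = s.beat_time_s - self.horizon_s
            while self._samples[0].beat_time_s <= cutoff:
                evicted.append(self._samples.popleft())
        return evicted

    def clear(self) -> None:
        self._samples.clear()
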