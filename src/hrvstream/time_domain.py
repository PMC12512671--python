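"""Time-domain HRV metrics on an NN series.

Definitions (N = number of NN intervals in the window):

* ``RMSSD = sqrt( (1/(N-1)) * sum_{i=1}^{N-1} (NN_{i+1} - NN_i)^2 )`` --
  short-term, vagally mediated variability;
* ``SDNN``  -- sample standard deviation of the NN intervals (N-1
  denominator) -- global variability;
* ``pNN50 = 100 * #{ i : |NN_{i+1} - NN_i| > 50 ms } / (N-1)`` -- the
  difference must strictly exceed 50 ms;
* ``HR = 60000 / mean(NN)`` beats/min over the window.

Metrics are emitted only when the window holds at least ``min_nn`` (default
10) NN intervals after artifact rejection; below that :func:`time_domain`
returns ``None`` -- a first-class "withheld" outcome serialized downstream
as nulls, never an exception, so the record cadence stays observable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InsufficientDataError
from .preprocess import NNSeries, PreprocessConfig

#: successive-difference threshold of pNN50, milliseconds (strict)
PNN_THRESHOLD_MS = 50.0


@dataclass(frozen=True)
class TimeDomainMetrics:
    hr_bpm: float
    sdnn_ms: float
    rmssd_ms: float
    pnn50_pct: float
    n_nn: int
    window_end_time_s: float | None = None


def _values(nn: NNSeries | Sequence[float]) -> np.ndarray:
    if isinstance(nn, NNSeries):
        return nn.as_array()
    return np.asarray(nn, dtype=float)


def rmssd(nn: NNSeries | Sequence[float]) -> float:
    """Root mean square of successive NN differences, ms."""
    x = _values(nn)
    if x.size < 2:
        raise InsufficientDataError("RMSSD needs at least 2 NN intervals")
    d = np.diff(x)
    return float(np.sqrt(np.mean(d * d)))


def sdnn(nn: NNSeries | Sequence[float]) -> float:
    """Sample standard deviation (N-1 denominator) of the NN intervals, ms."""
    x = _values(nn)
    if x.size < 2:
        raise InsufficientDataError("SDNN needs at least 2 NN intervals")
    return float(np.std(x, ddof=1))


def pnn50(nn: NNSeries | Sequence[float]) -> float:
    """Percentage of successive differences strictly exceeding 50 ms."""
    x = _values(nn)
    if x.size < 2:
        raise InsufficientDataError("pNN50 needs at least 2 NN intervals")
    d = np.abs(np.diff(x))
    return float(100.0 * np.count_nonzero(d > PNN_THRESHOLD_MS) / d.size)


def mean_hr(nn: NNSeries | Sequence[float]) -> float:
    """Mean heart rate over the window: 60000 / mean(NN), beats/min."""
    x = _values(nn)
    if x.size < 1:
        raise InsufficientDataError("HR needs at least 1 NN interval")
    return float(60000.0 / np.mean(x))


def time_domain(
    nn: NNSeries | Sequence[float],
    config: PreprocessConfig = PreprocessConfig(),
    window_end_time_s: float | None = None,
) -> TimeDomainMetrics | None:
    """All time-domain metrics, or ``None`` when the >=min_nn gate withholds them."""
    x = _values(nn)
    if x.size < config.min_nn:
        return None
    return TimeDomainMetrics(
        hr_bpm=mean_hr(x),
        sdnn_ms=sdnn(x),
        rmssd_ms=rmssd(x),
        pnn50_pct=pnn50(x),
        n_nn=int(x.size),
        window_end_time_s=window_end_time_s,
    )
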