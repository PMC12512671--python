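"""Frequency-domain HRV: Welch spectrum of the resampled tachogram.

The tachogram (NN value against beat time) is unevenly sampled, so it is
first converted to a uniform series by linear interpolation at 10 Hz.  The
power spectral density is then estimated with Welch's method (Hann taper,
50% overlap, per-segment mean removal, segment length min(256, n), one-sided
density scaling so the PSD integrates to the series variance).  Band powers
are trapezoidal integrals of the PSD over the low-frequency band
(0.04-0.15 Hz, Mayer-wave/baroreflex range) and the high-frequency band
(0.15-0.40 Hz, respiratory sinus arrhythmia range); the series is in ms so
powers carry ms^2.

LF/HF is reported only when HF power exceeds a small floor (1e-6 ms^2 by
default) -- below it the ratio is numerically meaningless and is withheld
(``lf_hf = None``), mirroring the >=10-NN gate of the time domain.

The PSD bin at exactly 0.15 Hz belongs to LF: the LF band is closed on both
edges, HF is open at 0.15 and closed at 0.40, so no power is counted twice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import signal

from .errors import InsufficientDataError
from .packets import RRSample, rr_to_samples
from .preprocess import NNSeries


@dataclass(frozen=True)
class SpectralConfig:
    resample_hz: float = 10.0
    lf_band: tuple[float, float] = (0.04, 0.15)
    hf_band: tuple[float, float] = (0.15, 0.40)
    max_segment: int = 256
    hf_gate: float = 1e-6  # ms^2
    window: str = "hann"
    overlap_fraction: float = 0.5
    min_welch_samples: int = 16

    def __post_init__(self) -> None:
        lf_lo, lf_hi = self.lf_band
        hf_lo, hf_hi = self.hf_band
        if not (0 < lf_lo < lf_hi <= hf_lo < hf_hi < self.resample_hz / 2):
            raise ValueError("bands must be ordered, disjoint and below Nyquist")
        if self.max_segment < 8:
            raise ValueError("max_segment must be >= 8")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")


@dataclass(frozen=True)
class FrequencyDomainMetrics:
    lf_power_ms2: float
    hf_power_ms2: float
    lf_hf: float | None  # None = withheld by the HF-power gate
    n_samples_used: int


def resample_tachogram(
    nn: NNSeries | Sequence[RRSample] | Sequence[float],
    config: SpectralConfig = SpectralConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate the tachogram onto a uniform grid.

    Accepts an :class:`NNSeries` or bare millisecond list (beat times then
    reconstructed as cumulative RR sums) or a sequence of
    :class:`~hrvstream.packets.RRSample`.  Returns ``(t, values)`` where the
    grid runs from the first to the last beat time in steps of
    ``1/resample_hz`` s (count = floor(span * resample_hz) + 1).
    """
    if isinstance(nn, NNSeries):
        samples = rr_to_samples(nn.nn_ms)
    elif len(nn) and isinstance(nn[0], RRSample):
        samples = list(nn)  # type: ignore[arg-type]
    else:
        samples = rr_to_samples([float(v) for v in nn])  # type: ignore[arg-type]
    if len(samples) < 2:
        raise InsufficientDataError("resampling needs at least 2 beats")
    beat_t = np.array([s.beat_time_s for s in samples])
    values = np.array([s.rr_ms for s in samples])
    step = 1.0 / config.resample_hz
    span = beat_t[-1] - beat_t[0]
    n_grid = int(np.floor(span / step + 1e-9)) + 1
    t = beat_t[0] + step * np.arange(n_grid)
    return t, np.interp(t, beat_t, values)


def welch_psd(
    series: Sequence[float] | np.ndarray,
    config: SpectralConfig = SpectralConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD of a uniformly sampled series.

    Segment length is min(max_segment, len(series)); Hann taper, 50%
    overlap and constant detrend per segment by default.  Density scaling:
    the trapezoidal integral of the PSD over [0, Nyquist] approximates the
    series variance.
    """
    x = np.asarray(series, dtype=float)
    if x.size < config.min_welch_samples:
        raise InsufficientDataError(
            f"Welch PSD needs >= {config.min_welch_samples} samples, got {x.size}"
        )
    nperseg = min(config.max_segment, x.size)
    noverlap = int(nperseg * config.overlap_fraction)
    freqs, psd = signal.welch(
        x,
        fs=config.resample_hz,
        window=config.window,
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
        return_onesided=True,
    )
    return freqs, psd


def band_power(
    freqs: np.ndarray,
    psd: np.ndarray,
    band: tuple[float, float],
    edges: Literal["both", "right"] = "both",
) -> float:
    """Trapezoidal integral of the PSD over the bins inside ``band``.

    ``edges="both"`` keeps bins with low <= f <= high; ``edges="right"``
    excludes the lower edge (used for HF so the shared 0.15-Hz bin is
    counted once, in LF).  A band covering fewer than two bins has zero
    integral width and returns 0.0.
    """
    f = np.asarray(freqs, dtype=float)
    p = np.asarray(psd, dtype=float)
    lo, hi = band
    if edges == "both":
        mask = (f >= lo) & (f <= hi)
    else:
        mask = (f > lo) & (f <= hi)
    if np.count_nonzero(mask) < 2:
        return 0.0
    return float(np.trapezoid(p[mask], f[mask]))


def lf_hf_ratio(
    lf_power: float, hf_power: float, config: SpectralConfig = SpectralConfig()
) -> float | None:
    """LF/HF, or ``None`` (withheld) when HF power is at or below the gate."""
    if hf_power > config.hf_gate:
        return lf_power / hf_power
    return None


def frequency_domain(
    nn: NNSeries | Sequence[RRSample] | Sequence[float],
    config: SpectralConfig = SpectralConfig(),
) -> FrequencyDomainMetrics:
    """Resample, estimate the PSD, integrate the bands and gate the ratio."""
    _, series = resample_tachogram(nn, config)
    freqs, psd = welch_psd(series, config)
    lf = band_power(freqs, psd, config.lf_band, edges="both")
    hf = band_power(freqs, psd, config.hf_band, edges="right")
    return FrequencyDomainMetrics(
        lf_power_ms2=lf,
        hf_power_ms2=hf,
        lf_hf=lf_hf_ratio(lf, hf, config),
        n_samples_used=int(series.size),
    )
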