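"""Synthetic RR tachogram generator.

Emulates the autonomic structure the HRV metrics assume: a mean inter-beat
interval modulated by two sinusoids -- one in the LF band (default 0.10 Hz,
the Mayer-wave rhythm) and one in the HF band (default 0.25 Hz, respiratory
sinus arrhythmia at ~15 breaths/min) -- plus white jitter and optionally
injected artifacts:

    RR_i = mean + A_LF sin(2*pi*f_LF*t_i) + A_HF sin(2*pi*f_HF*t_i) + e_i

with ``t_i`` the cumulative beat time, so the spectral content is exact on
the tachogram the pipeline analyzes (beat-time phase, not wall clock).

Artifact models mimic common sensor failures: ``spike_double`` (a missed
beat doubles the interval), ``spike_half`` (a false detection halves it),
``out_of_range`` (values outside the 300-2000 ms plausibility window).
Every stochastic path is seeded; the same spec yields the same stream.

What this emulates and what it does not: band-limited quasi-periodic
modulation and isolated artifacts, yes; respiration-coupled frequency
drift, circadian trends, ectopy bursts and the integral-pulse-frequency-
modulation relation between heart period and modulation amplitude, no.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

from .packets import RawPacket, RRSample, encode_packets

ArtifactModel = Literal["spike_double", "spike_half", "out_of_range"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters of a test tachogram.

    Amplitudes are in ms; ``jitter_sd_ms`` is the standard deviation of the
    additive white noise; ``artifact_rate`` is the per-beat corruption
    probability.  Defaults give a resting adult at 75 bpm with moderate,
    balanced LF/HF modulation.
    """

    mean_rr_ms: float = 800.0
    a_lf_ms: float = 25.0
    f_lf_hz: float = 0.10
    a_hf_ms: float = 25.0
    f_hf_hz: float = 0.25
    jitter_sd_ms: float = 5.0
    artifact_rate: float = 0.0
    artifact_model: ArtifactModel = "out_of_range"
    duration_s: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 300.0 < self.mean_rr_ms < 2000.0:
            raise ValueError("mean_rr_ms must lie in (300, 2000)")
        if not 0.04 <= self.f_lf_hz <= 0.15:
            raise ValueError("f_lf_hz must lie in the LF band [0.04, 0.15]")
        if not 0.15 < self.f_hf_hz <= 0.40:
            raise ValueError("f_hf_hz must lie in the HF band (0.15, 0.40]")
        if self.a_lf_ms < 0 or self.a_hf_ms < 0 or self.jitter_sd_ms < 0:
            raise ValueError("amplitudes and jitter must be non-negative")
        if not 0 <= self.artifact_rate < 1:
            raise ValueError("artifact_rate must lie in [0, 1)")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")


def generate_rr(spec: SyntheticSpec) -> list[float]:
    """Generate the millisecond RR series (artifacts included if requested)."""
    rng = np.random.default_rng(spec.seed)
    rr: list[float] = []
    t = 0.0
    while t < spec.duration_s:
        v = (
            spec.mean_rr_ms
            + spec.a_lf_ms * np.sin(2 * np.pi * spec.f_lf_hz * t)
            + spec.a_hf_ms * np.sin(2 * np.pi * spec.f_hf_hz * t)
        )
        if spec.jitter_sd_ms > 0:
            v += rng.normal(0.0, spec.jitter_sd_ms)
        v = max(v, 1.0)  # guard: RR must stay positive
        rr.append(float(v))
        t += v / 1000.0
    if spec.artifact_rate > 0:
        rr, _ = inject_artifacts(rr, spec)
    return rr


def generate(spec: SyntheticSpec) -> list[RRSample]:
    """Generate a beat-time-placed RR stream (deterministic given the seed)."""
    from .packets import rr_to_samples

    return rr_to_samples(generate_rr(spec))


def inject_artifacts(
    clean_rr: Sequence[float], spec: SyntheticSpec
) -> tuple[list[float], np.ndarray]:
    """Corrupt a clean series per the spec's artifact model.

    Returns the corrupted series and a boolean mask of injected positions.
    Corruption draws use a stream derived from ``spec.seed`` but independent
    of the generation draws, so the same positions corrupt the same series.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5EED]))
    x = [float(v) for v in clean_rr]
    mask = rng.random(len(x)) < spec.artifact_rate
    for i in np.flatnonzero(mask):
        if spec.artifact_model == "spike_double":
            x[i] *= 2.0
        elif spec.artifact_model == "spike_half":
            x[i] *= 0.5
        else:  # out_of_range: alternate below/above the plausibility window
            x[i] = 150.0 if rng.random() < 0.5 else 2500.0
    return x, mask


def generate_packets(
    spec: SyntheticSpec, packet_rate_hz: float = 1.0
) -> list[RawPacket]:
    """Emit the stream as encoded heart-rate-measurement packets at ~1 Hz."""
    return encode_packets(generate_rr(spec), packet_rate_hz)


def with_amplitudes(spec: SyntheticSpec, a_lf_ms: float, a_hf_ms: float) -> SyntheticSpec:
    """Convenience for amplitude-grid experiments."""
    return replace(spec, a_lf_ms=a_lf_ms, a_hf_ms=a_hf_ms)
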