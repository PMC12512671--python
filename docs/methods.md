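# Methods

`hrvstream` implements a real-time heart-rate-variability (HRV) pipeline of
the kind used to couple a chest-strap heart-rate sensor to downstream
consumers (dashboards, biofeedback applications, language-model agents):
packet decoding, artifact rejection, rolling-window metric computation, and
a JSON record service. This note documents the model, the parameter
choices, the numerical details, and the limits of what the synthetic tests
demonstrate.

## Signal model and pipeline

The atom of the pipeline is the R–R interval: the time between successive
R-peaks of the ECG, in milliseconds. The sensor transmits the standard GATT
heart-rate-measurement characteristic at ~1 Hz (flags byte; 8/16-bit HR;
optional energy-expended field; zero or more 16-bit little-endian R–R
values in 1/1024-s units). Decoding converts each raw value `v` to
`v * 1000/1024` ms and places it on the *beat clock* — the cumulative sum
of R–R intervals — which is the physiologically meaningful time base;
packet arrival times are retained only as an eviction fallback. The encoder
(used for round-trip testing and sensor-free replay) quantizes to the same
unit, so an encode/decode round trip is exact to ±1000/2048 ≈ 0.49 ms per
sample.

Incoming intervals feed a rolling buffer with a 60-second horizon. The
buffer retains the samples in the half-open window
`(newest_beat_time − 60 s, newest_beat_time]`: with steady 1-Hz beats it
settles at 60 samples spanning 59 s. The half-open convention is chosen so
that a closed-window ambiguity at exactly 60 s cannot retain an extra beat.

Every metric update cleans the current buffer contents with a three-stage
cascade, in this order:

1. **Plausibility**: keep only intervals in [300, 2000] ms (inclusive
   bounds — "within" is read inclusively, and the boundary behaviour is
   pinned by tests).
2. **Median-3**: a width-3 running median with edge replication
   (length-preserving, so counts stay interpretable). This suppresses
   isolated spikes such as a single missed or doubled beat.
3. **IQR fence**: keep values in [Q1 − 1.5·IQR, Q3 + 1.5·IQR], with
   quartiles by the linear-interpolation percentile convention. The fence
   is computed per analysis window (the buffer), not per session, because
   every published value is derived from the rolling buffer.

The cascade removes; it never corrects. Survivors are NN
("normal-to-normal") intervals.

**A known property, not a bug:** one pass of a 3-sample median filter is
not a root-signal operator, so the cascade is *not* idempotent
value-for-value — re-cleaning cleaned data re-flattens the extrema the
first pass already smoothed. What does hold, and what the tests assert, is
that the cascade's *rejection* is idempotent: applying the plausibility and
IQR stages to cleaned output removes nothing (verified across artifact
models, rates up to 8% and jitter up to 30 ms), and plausibility filtering
alone is exactly idempotent. A degenerate corner worth knowing: when a
window is nearly constant, the IQR is 0 and the fence collapses to a single
value, trimming any off-value survivors; this is the literal behaviour of
the fence rule and is pinned by a hand-traced test.

## Time-domain metrics

Computed on the cleaned NN series of the window (N = count):

- `RMSSD = sqrt( (1/(N−1)) Σ (NN_{i+1} − NN_i)² )` — short-term, vagally
  mediated variability;
- `SDNN` — sample standard deviation, N−1 denominator — global variability;
- `pNN50 = 100 · #{ |ΔNN| > 50 ms } / (N−1)` — the threshold is strict: a
  difference of exactly 50 ms does not count;
- `HR = 60000 / mean(NN)` bpm. (Mean-of-instantaneous-rates was considered
  and rejected: dividing first weights short intervals and is noisier.)

Metrics are emitted only when N ≥ 10 after filtering. Below the gate the
pipeline returns a *withheld* outcome (`None`, serialized as JSON nulls),
never an error and never a dropped record, so the update cadence remains
observable even through signal dropouts.

## Frequency-domain metrics

The NN tachogram (value vs. beat time) is unevenly sampled, so it is
linearly interpolated onto a uniform 10-Hz grid running from the first to
the last beat of the window. The PSD is estimated by Welch's method with
segment length `min(256, n_samples)`, Hann taper, 50% overlap, per-segment
mean removal, one-sided density scaling (the PSD integrates to the series
variance). Taper/overlap/detrend are the de-facto standard choices and are
configurable in `SpectralConfig`.

Band powers are trapezoidal integrals of the PSD over the bins inside
LF = [0.04, 0.15] Hz and HF = (0.15, 0.40] Hz. The bin at exactly 0.15 Hz
belongs to LF (closed-left, open-right HF), so no power is double-counted.
The series is in ms, so powers carry ms². `LF/HF` is reported only when
HF power exceeds `1e-6` (ms² on this scaling); at or below that floor the
ratio is numerically meaningless and is withheld.

**Resolution bias.** With 10-Hz resampling and 256-point segments the bin
width is ≈0.039 Hz, so the LF band spans only ~2–3 bins. Trapezoidal
integration over so few bins biases the LF integral low (peak leakage
skirts the 0.04-Hz edge): a synthetic tachogram with a 2:1 LF:HF amplitude
ratio (power ratio 4) recovers LF/HF ≈ 3.1. Rank order across amplitude
grids is nevertheless preserved exactly, which is what comparative use of
the ratio needs. Users who require unbiased absolute band powers should
lengthen the analysis window and raise `max_segment`.

## Record service

One `HRVRecord` (HR, RMSSD, SDNN, pNN50, LF/HF, LF and HF powers, NN
count, ISO-8601 UTC timestamp, strictly increasing integer id) is computed
from the buffer every 5 s and appended to an in-process, append-only store
with optional JSON-lines persistence. The REST surface — `GET /all`,
`GET /latest`, `GET /data_by_time?start=&end=` (closed interval),
`GET /download_hrv_json`, `POST /receive_hrv_data` — serves and accepts
those records as JSON; every endpoint requires the API key, carried as
`Authorization: Bearer <key>` or `X-API-Key`. Submitted payloads are
schema-validated (pydantic) and rejected with field-level reasons; the
server assigns record ids. Push consumers can subscribe in-process, over
`GET /ws` (a minimal RFC 6455 server-side WebSocket that sends each record
as one text frame), or over `GET /stream` (newline-delimited JSON). The
HTTP layer is the stdlib threading server: the service's value is its
contract, not a framework.

## Synthetic tachogram generator

Test tachograms follow

    RR_i = mean + A_LF·sin(2π f_LF t_i) + A_HF·sin(2π f_HF t_i) + ε_i

with `t_i` the cumulative beat time and `ε_i ~ N(0, jitter_sd²)`. Defaults:
mean 800 ms (75 bpm, resting adult), `f_LF = 0.10 Hz` (Mayer-wave rhythm),
`f_HF = 0.25 Hz` (respiration at 15 breaths/min), amplitudes 25 ms each
(moderate, balanced modulation), jitter 5 ms, 300-s duration. Artifacts are
injected per beat at a configurable rate under three models: `spike_double`
(missed beat), `spike_half` (false detection), `out_of_range` (telemetry
glitches at 150 or 2500 ms, outside the plausibility window). All
randomness is seeded; identical specs produce identical streams.

Because the phase is evaluated at beat times, spectral content is exact on
the tachogram the pipeline analyzes. What the generator deliberately does
*not* emulate: integral-pulse-frequency-modulation coupling between heart
period and modulation amplitude, respiratory frequency drift, ectopy
bursts, trends, or sensor contact loss. Passing tests therefore demonstrate
that the pipeline computes its defined quantities correctly on band-limited
quasi-periodic signals with isolated artifacts — not that the metrics are
robust to every failure mode of real ambulatory recordings.

## Problem sizes and numerical conventions

Simulation-based tests use 300-s tachograms (~375 beats), long enough for
~12 Welch segments at 10 Hz; the 5×5 amplitude-recovery grid uses
pairwise-distinct amplitudes {5, 7, 11, 13, 17} ms so all 25 expected
ratios are distinct and rank agreement is testable strictly. Oracle tests
compare against independent brute-force loops (explicit sums, sorting-based
percentiles, manual trapezoids) at 1e-9 on ≥1000 random instances.
Percentiles use the linear-interpolation convention throughout; skewness is
the Fisher third standardized moment and kurtosis is excess kurtosis (both
population-moment estimators); CV = SD/mean. On a constant window SD and CV
are 0 and the shape statistics are reported as undefined (`None`) rather
than NaN. Descriptive statistics of a session summarize the records
computed while the latest 200 R–R intervals arrived (count-based window on
the raw stream, cascade applied inside it); a marker withheld in fewer than
3 records is reported undefined.

## Known limitations

- The cascade's median stage alters values near extrema even on clean
  data; metrics are therefore computed on a lightly smoothed series.
- LF band powers are biased low at the default spectral resolution (see
  above); LF/HF is best used comparatively.
- The HF-power floor of 1e-6 is effectively never the binding constraint on
  physiological signals at ms² scaling; it guards the degenerate
  constant-signal case.
- The store is in-process; persistence is an append-only JSON-lines file.
  Multi-user auth, TLS and deployment concerns are out of scope.
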