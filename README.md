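# hrvstream

A streaming heart-rate-variability (HRV) pipeline, hardware-optional. It
takes R–R intervals — the times between successive heartbeats — from a
Bluetooth chest-strap packet stream, a replay file, or a built-in synthetic
generator, rejects artifacts, computes the standard HRV markers on a
rolling 60-second window, and serves the results as JSON records over REST
and WebSocket. It is aimed at anyone building physiology-aware
applications (biofeedback, adaptive tutoring, digital-health dashboards,
LLM agents that consume autonomic state) who needs a tested, reproducible
signal path between a heart-rate sensor and their consumer.

## What it computes

From each 60-s window of NN intervals (R–R intervals surviving artifact
rejection), with N the window count:

- **RMSSD** = √[(1/(N−1)) Σ (NN_{i+1} − NN_i)²] — short-term, vagally
  mediated variability
- **SDNN** — sample standard deviation of the NN intervals — global
  variability
- **pNN50** = 100 · #{|ΔNN| > 50 ms}/(N−1) — strict threshold
- **HR** = 60000 / mean(NN) beats/min
- **LF, HF, LF/HF** — band powers of the 10-Hz-resampled tachogram
  (Welch PSD, nperseg ≤ 256), trapezoid-integrated over 0.04–0.15 Hz and
  0.15–0.40 Hz; the ratio is withheld when HF power ≤ 1e-6

Artifact rejection is a three-stage cascade: plausibility bounds
(300–2000 ms) → 3-sample median filter → 1.5×IQR fence per window.
Time-domain metrics are withheld below 10 NN intervals; withheld values are
served as JSON nulls at an unbroken 5-s record cadence. See
`docs/methods.md` for the full model, conventions and limitations.

## Worked example

```python
from hrvstream import SyntheticSpec, generate_rr, clean, time_domain, frequency_domain

spec = SyntheticSpec(seed=1, duration_s=300.0)   # 75 bpm, balanced LF/HF modulation
rr = generate_rr(spec)
nn = clean(rr)                                   # plausibility -> median-3 -> IQR fence
t = time_domain(nn)
f = frequency_domain(nn)

print(f"beats generated : {len(rr)}   NN retained: {nn.n}")
print(f"HR    = {t.hr_bpm:6.2f} bpm")
print(f"SDNN  = {t.sdnn_ms:6.2f} ms")
print(f"RMSSD = {t.rmssd_ms:6.2f} ms")
print(f"pNN50 = {t.pnn50_pct:6.2f} %")
print(f"LF    = {f.lf_power_ms2:7.2f} ms^2   HF = {f.hf_power_ms2:7.2f} ms^2   LF/HF = {f.lf_hf:5.3f}")
```

prints

```
beats generated : 376   NN retained: 376
HR    =  75.12 bpm
SDNN  =  21.78 ms
RMSSD =  18.98 ms
pNN50 =   1.07 %
LF    =  128.87 ms^2   HF =  138.47 ms^2   LF/HF = 0.931
```

All 376 synthetic beats are plausible, so the cascade removes nothing. HR
recovers the 800-ms mean interval (75.12 bpm). SDNN reflects the two 25-ms
modulations plus 5-ms jitter; RMSSD is smaller because slow LF modulation
contributes little to successive differences; pNN50 is near zero because
beat-to-beat steps rarely exceed 50 ms at these amplitudes. The equal
modulation amplitudes give LF/HF near 1.

## Command line

```
hrvstream simulate --out rr.txt --seed 4 --duration 200   # synthetic tachogram
hrvstream simulate --out session.bin --seed 4             # ...as encoded packets
hrvstream decode   --in session.bin --out rr.txt          # packet log -> RR file
hrvstream compute  --rr rr.txt --window 60 --step 5       # JSON records to stdout
hrvstream report   --rr rr.txt --last 200                 # descriptive stats table
hrvstream serve    --rr rr.txt --period 5 --api-key k     # REST/WebSocket service
```

The service exposes `GET /all`, `GET /latest`,
`GET /data_by_time?start=&end=`, `GET /download_hrv_json`,
`POST /receive_hrv_data`, plus push feeds at `/ws` (WebSocket) and
`/stream` (NDJSON). Every endpoint requires the API key
(`Authorization: Bearer <key>` or `X-API-Key`).

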