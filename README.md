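# dopplerfhr

Beat-to-beat fetal heart rate (FHR) extraction from raw demodulated
Doppler ultrasound signals, with the evaluation machinery needed to
judge such a processing chain against a reference beat series, and a
synthetic signal generator with known beat times.

## The problem

Clinical fetal monitors estimate the fetal heart rate from the Doppler
echo of the moving heart. Because the echo of one cardiac cycle is a
complex multi-burst pattern (valve clicks around 300–600 Hz, wall
motions around 100–300 Hz) rather than a clean R wave, monitors measure
*periodicity* with a windowed autocorrelation function (AF) and emit
one smoothed value every 250 ms. That representation duplicates and
averages the underlying beat intervals, which wrecks the clinically
important *short-term variability* (STV) indices — they need a **time
series of events**: exactly one interval T_i per heartbeat, as a fetal
ECG would give (FHR_i = 60000 / T_i bpm, physiological range 60–240 bpm
↔ 1000–250 ms).

This package implements a complete channel that recovers such an event
series from the raw audio-band Doppler signal:

1. **Preprocessing** — zero-phase Butterworth band-pass (walls 100–300 Hz,
   valves 300–600 Hz, or full band) and reduction to a unipolar envelope
   at 1 kHz, by rectification + low-pass or by Hilbert-transform
   magnitude with moving-average smoothing.
2. **Periodicity** — sliding-window (default D = 1 s, hop K = 25 ms)
   normalized autocorrelation of the envelope; the dominant peak's lag
   in [250, 1000] ms is the instantaneous period F_j. Peaks below 0.1
   are loss markers; below 0.5 a trapezoidal *prediction function*
   centred on the last reliable period (lower base S = 500 ms, base
   ratio 1:4) re-weights the curve before the argmax.
3. **Event extraction** — two independent methods:
   * **D1**: build the monitor-style 250-ms series (median of 10
     measurements per slot, 0.25 bpm quantization) and convert maximal
     runs of duplicate values into the most probable number of beats;
   * **D2**: segment the 25-ms measurement stream directly — grow each
     segment until n·25 ms exceeds the running median, which then
     becomes T_i — with an RMS-based starting point and a matching
     algorithm (MAA) that keeps segment timestamps phase-locked to the
     measurement stream by ±γ/5 = ±5 ms corrections.
4. **Validation** — each interval must sit in an asymmetric acceptance
   corridor around its predecessor (T_{i−1} − 0.1·Δ, T_{i−1} + 0.15·Δ
   with Δ = T_{i−1} − 300 ms, floored at 20 ms) within a group of ≥ 3
   conforming intervals, checked in both timeline directions; a
   monotonicity product test (> 35 ms²) confirms the rejects.
5. **Evaluation** — automatic synchronization against a reference event
   series (±3000 ms search, 1 ms steps), interval-difference statistics
   ΔT̄, SD, |ΔT|̄ sampled at reference-interval midpoints in the 5–55 s
   window, time-weighted signal loss, twelve author-named STV/LTV
   variability indices, and their relative errors.

The synthetic generator (`dopplerfhr.simulate`) renders programmable
FHR profiles (baseline, sinusoidal long-term variability,
acceleration/deceleration episodes, Gaussian beat-to-beat jitter) as
multi-phase burst waveforms with amplitude drift, broadband noise and
movement-interference episodes, so every stage is testable against
known beat times.

## Worked example

```python
import dopplerfhr as dp
from dopplerfhr.simulate import UsSimParams

prof = dp.FhrProfile(duration=60.0, baseline=120.0, stv_jitter_sd=5.0, seed=0)
beats = dp.generate_beat_times(prof)                       # ground truth
record = dp.synthesize_us_signal(beats, UsSimParams(), seed=1)
reference = dp.beats_to_reference(beats)

report = dp.run_pipeline(dp.RunConfig(), record, reference)  # D2 defaults
print(f"shift      : {report.sync.shift:+.0f} ms")
print(f"mean dT    : {report.stats.mean_dT:+.2f} ms")
print(f"SD dT      : {report.stats.sd_dT:.2f} ms")
print(f"mean |dT|  : {report.stats.mean_abs_dT:.2f} ms")
print(f"signal loss: {report.stats.signal_loss_pct:.2f} %")
```

prints

```
shift      : +547 ms
mean dT    : +0.01 ms
SD dT      : 1.22 ms
mean |dT|  : 0.99 ms
signal loss: 0.49 %
```

i.e. after automatic synchronization (the extraction chain introduces a
content-dependent time offset, here 547 ms), the recovered beat
intervals deviate from the ground truth by about 1 ms on average and
less than half a percent of the 5–55 s analysis window lacks a valid
measurement. `report.indices_test` / `report.index_errors` carry the
twelve variability indices and their relative errors against the
reference.

The same chain is available from the shell:

```bash
dopplerfhr simulate --duration 60 --baseline 120 --jitter 5 --seed 0 \
    --wav sig.wav --truth truth.csv
dopplerfhr process sig.wav --method d2 --out events.csv
dopplerfhr evaluate events.csv truth.csv
dopplerfhr sweep sig.wav truth.csv --out sweep.csv   # parameter grid
```

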