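# Methods

This note documents the models, conventions and numerical choices
behind `dopplerfhr`, in the order the processing chain runs.

## Signal model and the synthetic generator

A demodulated Doppler ultrasound recording of the fetal heart is
modelled as a train of per-beat burst clusters. Each cardiac cycle
contributes one Gaussian-windowed sinusoid per configured *phase*:
valve events (mitral close/open Mc/Mo, aortic open/close Ao/Ac) with
carrier frequencies in 300–600 Hz, wall events (ventricular walls Vc,
atrial contraction Atc) in 100–300 Hz. The default six-phase cycle
places the bursts at fractions {0.00, 0.05, 0.12, 0.35, 0.45, 0.90} of
the beat interval with durations of 30–70 ms and amplitudes 0.4–1.0;
these offsets are a plausible mechanical ordering chosen once for this
package — they are configurable, not anatomical ground truth. The
burst window is `exp(-dt²/2σ²)` with σ = duration/6, which keeps each
burst's spectral footprint inside its band (verified by a periodogram
test: ≥ 95% of noise-free power in the union of phase bands).

Beat times come from a rate profile: baseline [bpm] + sinusoidal
long-term-variability components + trapezoidal acceleration/deceleration
episodes (linear rise over the first quarter of the episode, plateau,
linear fall over the last quarter). Intervals are laid down
iteratively as T_i = 60000/rate(t_i) + ε_i with ε_i ~ N(0, σ_STV);
i.i.d. interval jitter makes successive-difference SD √2·σ_STV, which
the tests check by Monte Carlo. Profiles whose rate or interval goes
non-positive are rejected.

Degradations: slow sinusoidal amplitude drift (default depth 0.3 at
0.05 Hz) emulating transducer-to-heart geometry changes; additive
white Gaussian noise with SD relative to the strongest phase amplitude
(default 0.05, which puts the raw-signal SNR near 11 dB at 120 bpm —
the study condition "SNR ≥ 10 dB" used throughout the tests); optional
movement-interference episodes as 100–600 Hz band-limited noise bursts
uncorrelated with the beats. One seeded `default_rng` per synthesis
call makes waveforms bit-reproducible.

What the generator does *not* emulate: the 1 MHz carrier and
demodulation electronics, maternal ECG/abdominal contamination,
transducer repositioning transients, and the non-Gaussian burst-shape
changes of real fetuses. Passing tests therefore demonstrate the
correctness and internal consistency of the algorithms under a
controlled signal model, not clinical performance.

The default sample rate is 3 kHz (5× the 600 Hz band top); any
fs ≥ 1.5 kHz is accepted.

## Preprocessing

Band separation and envelope low-pass use 4th-order Butterworth
filters applied forward–backward (`sosfiltfilt`), so filtering is
zero-phase and beat timing is preserved (tested: burst centres move by
≤ 1 ms). Two envelope paths exist:

* rectify + low-pass: |x| then zero-phase LPF with cutoff in
  {25, 50, 75, 100, 150} Hz or none;
* Hilbert: analytic-signal magnitude, then a centred moving average of
  11 or 21 *raw* samples (applied before resampling; the alternative —
  averaging after resampling — is equally defensible but this package
  fixes the former).

Both paths resample to a fixed 1 kHz envelope rate (`resample_poly`),
so the autocorrelation lag quantum is exactly 1 ms, and clip the tiny
negative undershoot that filtering/resampling can introduce (an
envelope is a magnitude by definition).

## Instantaneous periodicity

Within each sliding window (width D ∈ {0.8, 1, 1.5, 2, 3} s, hop
K ∈ {25, 250} ms, stamped at the window end) the envelope is
mean-removed and autocorrelated with symmetric per-lag normalization

    af(k) = 2 Σ x_i x_{i+k} / Σ (x_i² + x_{i+k}²),

the normalized-square-difference convention of pitch trackers. This
estimator is bounded by 1 (Cauchy–Schwarz), has af(0) = 1 exactly, and
carries no finite-window taper, so the two absolute amplitude
thresholds — 0.1 for loss marking, 0.5 for engaging the prediction
function — mean the same thing for a 250 ms period as for a 1000 ms
one. (A plain biased estimator would cap a 500 ms period at amplitude
0.5 inside a 1-s window; a plain unbiased one amplifies long-lag noise
and picks period multiples. Both were tried and rejected.)

The period search range is [250, 1000] ms (60–240 bpm), additionally
capped at D·1000 − 200 ms so every candidate lag keeps ≥ 200 ms of
overlap support; the legacy wide range 30–2000 ms remains available
for prediction-free runs. Peak selection prefers the *shortest* lag
among local maxima within 0.01 of the global maximum — near-equal
peaks at lag multiples are period ambiguities, and this half-rate
guard resolves them downward.

Prediction: when the peak amplitude is in [0.1, 0.5) and a previous
reliable period exists, the curve is multiplied by a trapezoid centred
on that period (plateau S/4, lower base S ∈ {125, 250, 500} ms, zero
outside — the strongest suppression consistent with a 1:4 base ratio)
and the argmax is retaken. Such measurements are flagged `predicted`
and do not move the prediction centre; loss marking always uses the
pre-prediction amplitude.

## Event extraction

**D1 (duplicate correction).** The 25-ms stream is collapsed to
250-ms slots (median of the 10 constituent measurements; loss when
more than 5 are invalid), quantized to the 0.25 bpm monitor
resolution so duplicates repeat exactly. Maximal runs of n equal
slots of value T become beats: with Min = (n−1)·250/T and
Max = (n+1)·250/T, equal rounded values give that count, otherwise
round(n·250/T) (half-up, at least 1). Loss slots break runs.
Limitation: the rule is exact on genuinely duplicated (sample-and-hold)
streams — where the recovered event count matches truth within 2% —
but on jittered signals the slot values rarely repeat exactly, runs
degenerate to singletons, and the at-least-one-event fallback
overcounts beats by tens of percent. The probabilistic cross-run
reconciliation that would repair this is deliberately out of scope;
D1's interval-error statistics (midpoint-sampled) remain valid, and D2
is the method of choice for event counts.

**D2 (segmentation).** Analysis starts at the point P where, walking
backward from the RMS maximum of the first three seconds of the
envelope (sliding RMS window ∈ {100, 200, 250, 500, 1000} ms, default
500 ms, 1 ms step), the RMS first drops below 2/3 of that maximum
(P = 0 if it never does). Valid measurements are accumulated with a
running sample median m until n·25 ms exceeds m; m is emitted as T_i
at the segment start and the procedure repeats. Invalid measurements
close the segment as a recorded loss gap and segmentation restarts at
the next valid value.

**Matching algorithm (MAA).** Applied on-line during emission. Each
interval value is the median of the measurements inside
[τ_i, τ_i + T_{i−1}) — the previous interval bounds the current
segment, an intentional one-interval lag kept as designed. Over the
last seven intervals the mean absolute difference between each
measurement and the interval value containing it is evaluated for
marker shifts {−γ, 0, +γ}; if a nonzero shift wins, the next timestamp
is nudged by γ/5 = 5 ms in that direction (ties favour no shift).
Sign convention: the nudge follows the *winning shift's* direction,
which makes the correction contractive — a planted 25 ms phase error
decays in 5 ms steps, and on periodic input timestamps stay within one
step γ of the true beat boundaries after burn-in. Interval values are
never changed by MAA, only timestamps.

## Validation

Corridor: T_i is acceptable after T_{i−1} when
T_{i−1} − 0.1·Δ < T_i < T_{i−1} + 0.15·Δ (open interval), with
Δ = T_{i−1} − 300 ms when T_{i−1} ≥ 320 ms, else Δ = 20 ms. An
interval must additionally belong to a run of ≥ 3 consecutive
corridor-satisfying intervals. The pass runs forward and, with the
asymmetric fractions mirrored (−0.15/+0.1), backward over the reversed
series; only intervals rejected by both passes become candidates. The
mirroring convention is a declared choice (the alternative — unchanged
thresholds — is selectable). Candidates are confirmed incorrect only
when their differences to both neighbours share a sign and the product
exceeds 35 ms²; otherwise they are rescued. Validation only sets
flags; τ and T are never modified, and the procedure is idempotent.
Note that in very short series (≲ 7 events) the group-of-three
requirement also strips the good intervals flanking an artifact; the
rule set behaves as intended from about nine events on.

## Evaluation

Synchronization scans shifts in ±3000 ms at 1 ms steps. The primary
score at each shift is the mean |T_test − T_ref| over reference-interval
midpoints inside the 5–55 s window (midpoints in test loss gaps are
skipped). That score is flat on a ±half-interval plateau around the
true alignment and its raw per-shift minimum overfits pairing noise,
so the implementation locates the valley on the score smoothed over
±125 ms and then, within ±250 ms of it, minimizes the mean *phase
distance* between reference midpoints and the containing test
interval's own midpoint — a V-shaped criterion that recovers planted
integer shifts exactly on clean series and to the millisecond under
interval noise; remaining ties resolve to the smallest |shift|. The
interval statistics are unaffected by the refinement because every
plateau shift induces the same midpoint pairing.

Interval statistics (mean ΔT, SD with ddof = 1, mean |ΔT|) are
computed over the midpoint pairs; signal loss is time-weighted — the
fraction of the 50-s window not covered by valid (shifted) test
intervals.

Variability indices are computed over valid intervals whose midpoints
fall in the window (≥ 10 required, otherwise NaN — never a silent 0);
difference-based sums never bridge loss gaps. The historical formulas
are not standardized, so the registry carries operational definitions,
pluggable per index: S_DAW mean absolute successive difference
averaged per 3.75-s epoch; S_YEH 1000·SD of (T_i−T_{i+1})/(T_i+T_{i+1});
S_HAA IQR of arctan(T_{i+1}/T_i); S_ZUG SD of successive differences;
S_HUE mean |successive difference| at sign changes (0 when differences
exist but never change sign); S_DAL mean |successive difference|;
L_DAW mean per-epoch range; L_YEH and L_ZUG 1000·SD/mean; L_HAA IQR of
√(T_i²+T_{i+1}²); L_HUE SD; L_DAL mean absolute deviation. Relative
errors are (test − ref)/ref·100%, undefined for a zero reference.

A `monitor_series` helper renders an event series the way a classical
monitor would emit it — every 250 ms, either the interval containing
the tick (pure sample-and-hold duplication) or the overlap-weighted
mean over a trailing 1.5-s window (duplication + correlation-window
averaging), quantized to 0.25 bpm. The averaged rendering reproduces
the characteristic downward bias of every STV index relative to the
event series.

## Default configuration and problem sizes

The default `RunConfig` is the chain's empirical optimum: valve band
300–600 Hz, Hilbert envelope with MA-21, D = 1 s, K = 25 ms,
prediction with S = 500 ms, D2 with RMS window 500 ms and MAA,
validation on. Enumerated parameters outside the supported sets
require `allow_nonstandard`.

Tests and the acceptance script run on 60-s synthetic recordings
(120 bpm baseline, 5 ms STV jitter, ~11 dB SNR), ten seeds for the
recovery check and three to five seeds for the directional trends —
sizes chosen so the whole suite completes in well under a minute of
compute per property while keeping Monte-Carlo margins comfortable.

## Known limitations

* D1 overcounts events on non-duplicated streams (see above).
* No sub-millisecond peak interpolation: all periods are integer
  milliseconds by construction of the 1 kHz envelope.
* The variability-index formulas are operational stand-ins, not the
  historical originals; relative errors are meaningful, absolute index
  values should not be compared across implementations.
* The backward-validation threshold mirroring and the segmentation
  starting-point backward-scan are declared conventions where several
  readings are defensible.
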