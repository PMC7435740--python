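"""Synthetic Doppler ultrasound generator with known beat times.

A demodulated Doppler echo of the fetal heart is an audio-band signal in
which every cardiac cycle shows up as a cluster of short bursts: the
opening/closing of the aortic and atrioventricular valves (Ao, Ac, Mo, Mc)
produce fast movements with spectral content around 300-600 Hz, while the
slower wall motions (atrial contraction Atc, ventricular walls Vc) sit
around 100-300 Hz.  This module generates (a) ground-truth beat onset
trains from a programmable heart-rate profile and (b) raw waveforms with
that multi-phase burst structure, plus amplitude drift, broadband noise
and movement-interference episodes, so every downstream stage can be
tested against a known answer.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .events import BeatEventSeries

__all__ = [
    "BeatTrain",
    "FhrProfile",
    "Phase",
    "UsSimParams",
    "UltrasoundRecord",
    "generate_beat_times",
    "synthesize_us_signal",
    "beats_to_reference",
]

#: physiological instantaneous rate limits [bpm]
FHR_MIN_BPM = 60.0
FHR_MAX_BPM = 240.0

VALVE_PHASES = ("Ao", "Ac", "Mo", "Mc")
WALL_PHASES = ("Atc", "Vc")


@dataclass
class BeatTrain:
    """Strictly increasing beat-onset times [ms]."""

    onsets: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if len(self.onsets) > 1 and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("beat onsets must be strictly increasing")

    @property
    def intervals(self) -> np.ndarray:
        """T_i = onsets[i+1] - onsets[i] [ms]."""
        return np.diff(self.onsets)

    def __len__(self) -> int:
        return len(self.onsets)

    def true_interval_at(self, t: np.ndarray) -> np.ndarray:
        """True interval [ms] containing each query time (NaN outside)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.full(t.shape, np.nan)
        if len(self.onsets) < 2:
            return out
        idx = np.searchsorted(self.onsets, t, side="right") - 1
        ok = (idx >= 0) & (idx < len(self.onsets) - 1)
        out[ok] = self.intervals[idx[ok]]
        return out


@dataclass
class FhrProfile:
    """Programmable fetal heart rate profile.

    Parameters
    ----------
    duration : float
        Length of the generated train [s].
    baseline : float
        Baseline rate [bpm], within the physiological 60-240 bpm range.
    stv_jitter_sd : float
        SD of the i.i.d. Gaussian beat-to-beat interval jitter [ms].
    ltv_components : sequence of (amplitude [bpm], frequency [Hz])
        Slow sinusoidal rate modulation (long-term variability).
    episodes : sequence of (start [s], end [s], delta [bpm])
        Acceleration (delta > 0) / deceleration (delta < 0) episodes,
        applied as trapezoidal ramps (linear rise over the first quarter,
        plateau, linear fall over the last quarter).
    seed : int
        RNG seed; the generator is deterministic for a fixed seed.
    """

    duration: float = 60.0
    baseline: float = 120.0
    stv_jitter_sd: float = 0.0
    ltv_components: Sequence[tuple] = field(default_factory=list)
    episodes: Sequence[tuple] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not (FHR_MIN_BPM <= self.baseline <= FHR_MAX_BPM):
            raise ValueError(f"baseline must lie in [{FHR_MIN_BPM}, {FHR_MAX_BPM}] bpm")

    def rate_at(self, t_s: np.ndarray) -> np.ndarray:
        """Instantaneous deterministic rate [bpm] at times ``t_s`` [s]."""
        t_s = np.asarray(t_s, dtype=float)
        rate = np.full(t_s.shape, self.baseline, dtype=float)
        for amp, freq in self.ltv_components:
            rate = rate + amp * np.sin(2.0 * np.pi * freq * t_s)
        for start, end, delta in self.episodes:
            span = end - start
            if span <= 0:
                continue
            x = (t_s - start) / span
            ramp = np.clip(np.minimum(4.0 * x, 4.0 * (1.0 - x)), 0.0, 1.0)
            rate = rate + delta * np.where((x >= 0) & (x <= 1), ramp, 0.0)
        return rate


@dataclass
class Phase:
    """One cardiac phase burst: a Gaussian-windowed sinusoid per beat."""

    name: str
    offset_fraction: float  # position within the cycle, in [0, 1)
    burst_duration: float   # full burst width [ms] (~6 sigma)
    center_freq: float      # [Hz]
    amplitude: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.offset_fraction < 1.0):
            raise ValueError("offset_fraction must lie in [0, 1)")
        if self.name in VALVE_PHASES and not (300.0 <= self.center_freq <= 600.0):
            raise ValueError(f"valve phase {self.name} must have center_freq in [300, 600] Hz")
        if self.name in WALL_PHASES and not (100.0 <= self.center_freq <= 300.0):
            raise ValueError(f"wall phase {self.name} must have center_freq in [100, 300] Hz")


def default_phases() -> list:
    """Six-phase cycle: valve clicks (300-600 Hz) and wall motions (100-300 Hz).

    The within-cycle offsets are a plausible ordering of the mechanical
    events (mitral close, ventricular wall, aortic open/close, mitral
    open, atrial contraction); they are configurable, not anatomical
    ground truth.
    """
    return [
        Phase("Mc", 0.00, 30.0, 500.0, 1.00),
        Phase("Vc", 0.05, 70.0, 150.0, 0.50),
        Phase("Ao", 0.12, 30.0, 450.0, 0.90),
        Phase("Ac", 0.35, 30.0, 400.0, 0.80),
        Phase("Mo", 0.45, 35.0, 350.0, 0.70),
        Phase("Atc", 0.90, 60.0, 200.0, 0.40),
    ]


@dataclass
class UsSimParams:
    """Waveform synthesis parameters.

    ``noise_sd`` is the broadband Gaussian noise SD relative to the
    strongest phase amplitude.  The default 0.05 puts the raw-signal SNR
    near 11 dB for the default six-phase cycle at 120 bpm.  ``drift`` is
    a slow sinusoidal amplitude modulation (depth, frequency [Hz])
    emulating transducer-to-heart geometry changes.  ``interference``
    episodes superimpose band-limited noise bursts uncorrelated with the
    beats (fetal/maternal movement).
    """

    fs: float = 3000.0
    phases: Sequence[Phase] = field(default_factory=default_phases)
    noise_sd: float = 0.05
    drift: tuple = (0.3, 0.05)  # (modulation depth, frequency [Hz])
    interference: Sequence[tuple] = field(default_factory=list)  # (start s, end s, rel. amplitude)

    def __post_init__(self) -> None:
        if self.fs < 1500.0:
            raise ValueError("fs must be >= 1500 Hz (Nyquist margin for 600 Hz content)")


@dataclass
class UltrasoundRecord:
    """Sampled demodulated Doppler waveform."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    def __len__(self) -> int:
        return len(self.samples)


def generate_beat_times(profile: FhrProfile) -> BeatTrain:
    """Generate ground-truth beat onsets from a rate profile.

    Beats are laid down iteratively: the i-th interval is the local
    deterministic period 60000 / rate(t_i) plus i.i.d. Gaussian jitter of
    SD ``stv_jitter_sd`` ms, so successive-interval first differences
    have SD ~ sqrt(2) * stv_jitter_sd.
    """
    rng = np.random.default_rng(profile.seed)
    horizon = profile.duration * 1000.0
    onsets = [0.0]
    t = 0.0
    while t <= horizon:
        rate = float(profile.rate_at(t / 1000.0))
        if rate <= 0:
            raise ValueError(f"profile rate non-positive at t={t / 1000.0:.2f} s")
        T = 60000.0 / rate
        if profile.stv_jitter_sd > 0:
            T += rng.normal(0.0, profile.stv_jitter_sd)
        if T <= 0:
            raise ValueError("profile yields a non-positive interval; reduce jitter or fix episodes")
        t += T
        onsets.append(t)
    return BeatTrain(np.array(onsets))


def _add_burst(samples: np.ndarray, fs: float, center_ms: float, phase: Phase) -> None:
    """Add one Gaussian-windowed sinusoidal burst in place."""
    sigma_ms = phase.burst_duration / 6.0
    half_ms = phase.burst_duration  # +/- 6 sigma support
    i0 = max(0, int(np.floor((center_ms - half_ms) * fs / 1000.0)))
    i1 = min(len(samples), int(np.ceil((center_ms + half_ms) * fs / 1000.0)) + 1)
    if i1 <= i0:
        return
    t_ms = np.arange(i0, i1) / fs * 1000.0
    dt = t_ms - center_ms
    env = np.exp(-0.5 * (dt / sigma_ms) ** 2)
    samples[i0:i1] += phase.amplitude * env * np.cos(2.0 * np.pi * phase.center_freq * dt / 1000.0)


def synthesize_us_signal(beats: BeatTrain, params: UsSimParams, seed: int = 0) -> UltrasoundRecord:
    """Render a beat train as a raw demodulated Doppler waveform.

    Each beat contributes one Gaussian-windowed sinusoidal burst per
    configured phase, centred at ``offset_fraction * T_i`` after the beat
    onset.  Slow amplitude drift multiplies the burst train; broadband
    Gaussian noise and any interference episodes are then added.
    Deterministic for a fixed ``seed``.
    """
    if len(beats) == 0:
        raise ValueError("beat train is empty")
    rng = np.random.default_rng(seed)
    fs = params.fs
    intervals = beats.intervals
    if len(intervals) == 0:
        raise ValueError("need at least two onsets to synthesize a cycle")
    total_ms = beats.onsets[-1] + intervals[-1]
    n = int(round(total_ms * fs / 1000.0))
    samples = np.zeros(n)

    min_T = float(np.min(intervals))
    max_burst = max(p.burst_duration for p in params.phases) if params.phases else 0.0
    if max_burst > min_T:
        warnings.warn("burst duration exceeds the shortest interval; phases overlap", stacklevel=2)

    for i, onset in enumerate(beats.onsets[:-1]):
        T = intervals[i]
        for phase in params.phases:
            _add_burst(samples, fs, onset + phase.offset_fraction * T, phase)

    if params.drift is not None:
        depth, freq = params.drift
        if depth > 0:
            t_s = np.arange(n) / fs
            samples *= 1.0 + depth * np.sin(2.0 * np.pi * freq * t_s)

    peak = max((p.amplitude for p in params.phases), default=1.0)
    if params.noise_sd > 0:
        samples += rng.normal(0.0, params.noise_sd * peak, size=n)

    for start, end, rel_amp in params.interference:
        i0, i1 = int(start * fs), min(n, int(end * fs))
        if i1 <= i0:
            continue
        burst = rng.normal(0.0, 1.0, size=i1 - i0)
        # confine the interference to the 100-600 Hz Doppler band
        from scipy.signal import butter, sosfiltfilt

        sos = butter(4, [100.0, 600.0], btype="bandpass", fs=fs, output="sos")
        burst = sosfiltfilt(sos, burst)
        burst *= rel_amp * peak / max(np.std(burst), 1e-12)
        samples[i0:i1] += burst

    return UltrasoundRecord(samples, fs)


def beats_to_reference(beats: BeatTrain) -> BeatEventSeries:
    """Emit the reference event series (tau_i, T_i) from known onsets.

    This plays the role of the beat series a direct fetal ECG would give.
    A single onset defines no interval, so it yields an empty series.
    """
    if len(beats) < 2:
        return BeatEventSeries.empty(source="reference")
    tau = beats.onsets[:-1]
    T = beats.intervals
    return BeatEventSeries(tau, T, np.ones(len(T), dtype=bool), source="reference")


def measured_snr_db(beats: BeatTrain, params: UsSimParams, seed: int = 0) -> float:
    """Raw-signal SNR [dB]: burst-train power over total added noise power.

    Computed by synthesizing the clean and the noisy waveform with the
    same seed and comparing power of the clean part to the residual.
    """
    noisy = synthesize_us_signal(beats, params, seed=seed)
    clean_params = UsSimParams(
        fs=params.fs, phases=params.phases, noise_sd=0.0, drift=params.drift, interference=[]
    )
    clean = synthesize_us_signal(beats, clean_params, seed=seed)
    resid = noisy.samples - clean.samples
    p_sig = float(np.mean(clean.samples**2))
    p_noise = float(np.mean(resid**2))
    if p_noise == 0:
        return float("inf")
    return 10.0 * np.log10(p_sig / p_noise)
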