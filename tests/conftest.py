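import numpy as np
import pytest

import dopplerfhr as dp
from dopplerfhr.simulate import UsSimParams


@pytest.fixture(scope="session")
def jittered_beats():
    """60-s beat train at 120 bpm baseline with 5 ms beat-to-beat jitter."""
    prof = dp.FhrProfile(duration=60.0, baseline=120.0, stv_jitter_sd=5.0, seed=0)
    return dp.generate_beat_times(prof)


@pytest.fixture(scope="session")
def jittered_reference(jittered_beats):
    return dp.beats_to_reference(jittered_beats)


@pytest.fixture(scope="session")
def clean_record():
    """Noise-free 30-s waveform at a constant 120 bpm (known 500 ms period)."""
    prof = dp.FhrProfile(duration=30.0, baseline=120.0, seed=0)
    beats = dp.generate_beat_times(prof)
    record = dp.synthesize_us_signal(beats, UsSimParams(noise_sd=0.0, drift=None), seed=0)
    return beats, record


@pytest.fixture(scope="session")
def noisy_record(jittered_beats):
    """Realistic noisy waveform rendered from the jittered train."""
    record = dp.synthesize_us_signal(jittered_beats, UsSimParams(), seed=1000)
    return jittered_beats, record


def make_measurements(values, t0=0.0, step=25.0, af_peak=0.9):
    """Hand-built instantaneous measurement stream (NaN = loss marker)."""
    from dopplerfhr.periodicity import InstantMeasurement

    out = []
    for j, v in enumerate(values):
        valid = np.isfinite(v)
        out.append(
            InstantMeasurement(
                t=t0 + j * step,
                F=float(v) if valid else float("nan"),
                af_peak=af_peak if valid else 0.0,
                valid=bool(valid),
            )
        )
    return out
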