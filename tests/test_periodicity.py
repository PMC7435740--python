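import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dopplerfhr.periodicity import (
    AfConfig,
    AFCurve,
    autocorrelation,
    measure_instantaneous,
    trapezoidal_pf,
)
from dopplerfhr.preprocessing import Envelope, VALVE_BAND, bandpass, envelope_hilbert


def periodic_envelope(period_ms, n=3000):
    t = np.arange(n, dtype=float)
    return 1.0 + np.sin(2 * np.pi * t / period_ms)


class TestAutocorrelation:
    def test_unit_value_at_zero_lag(self):
        af = autocorrelation(periodic_envelope(400.0, 1000), 800)
        assert af.values[0] == pytest.approx(1.0)

    def test_periodic_window_peaks_at_true_period(self):
        af = autocorrelation(periodic_envelope(400.0, 1000), 800)
        lag, val = af.argmax_in(250, 800)
        assert abs(lag - 400.0) <= 1.0
        assert val > 0.9

    def test_constant_window_has_no_defined_periodicity(self):
        assert autocorrelation(np.full(1000, 3.3), 800) is None

    def test_white_noise_rarely_reaches_half_amplitude(self):
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            af = autocorrelation(rng.normal(size=1000), 800)
            _, peak = af.argmax_in(250, 800)
            hits += peak < 0.5
        assert hits >= 190  # >= 95% of seeds


class TestTrapezoidalPf:
    def test_plateau_and_base_geometry(self):
        lags = np.arange(1001, dtype=float)
        af = AFCurve(lags, np.ones(1001))
        out = trapezoidal_pf(af, center=500.0, S=400.0)
        assert out.values[500] == pytest.approx(1.0)          # centre
        assert out.values[500 - 50] == pytest.approx(1.0)     # plateau edge (S/8)
        assert out.values[500 - 200] == pytest.approx(0.0)    # lower base edge (S/2)
        assert out.values[500 + 200] == pytest.approx(0.0)
        assert out.values[900] == 0.0                         # outside the base

    def test_suppresses_spurious_peak_outside_base(self):
        lags = np.arange(1001, dtype=float)
        vals = np.zeros(1001)
        vals[320] = 0.45   # spurious higher peak far from the expectation
        vals[510] = 0.40   # true peak near the last interval
        out = trapezoidal_pf(AFCurve(lags, vals), center=500.0, S=250.0)
        lag, _ = out.argmax_in(250, 1000)
        assert lag == 510.0

    @settings(deadline=None, max_examples=100)
    @given(
        center=st.floats(250.0, 1000.0),
        S=st.sampled_from([125.0, 250.0, 500.0]),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_never_raises_af_pointwise(self, center, S, seed):
        rng = np.random.default_rng(seed)
        af = AFCurve(np.arange(1001, dtype=float), rng.uniform(-1, 1, 1001))
        out = trapezoidal_pf(af, center, S)
        assert np.all(out.values <= np.maximum(af.values, 0.0) + 1e-12)
        assert np.all(np.abs(out.values) <= np.abs(af.values) + 1e-12)


class TestMeasureInstantaneous:
    def test_clean_periodic_envelope_recovers_period(self, clean_record):
        beats, record = clean_record
        env = envelope_hilbert(bandpass(record, VALVE_BAND), 21)
        ms = measure_instantaneous(env, AfConfig(D=1.0, K=25.0))
        F = np.array([m.F for m in ms])
        valid = np.array([m.valid for m in ms])
        assert abs(np.median(F[valid]) - 500.0) <= 2.0
        # interior windows are all valid; resampling edges may lose a few
        assert np.mean(valid) > 0.98

    def test_all_zero_envelope_gives_only_loss_markers(self):
        env = Envelope(np.zeros(5000))
        ms = measure_instantaneous(env, AfConfig())
        assert len(ms) > 0
        assert not any(m.valid for m in ms)

    def test_weak_af_peak_marks_loss(self):
        # noise alone cannot raise the AF peak above the loss threshold often;
        # every measurement below p_th must be invalid
        rng = np.random.default_rng(1)
        env = Envelope(np.abs(rng.normal(size=10000)) * 0.01)
        ms = measure_instantaneous(env, AfConfig())
        assert all((m.af_peak >= 0.1) == m.valid for m in ms)

    def test_timestamps_increase_by_hop(self):
        env = Envelope(periodic_envelope(500.0, 8000))
        ms = measure_instantaneous(env, AfConfig(D=1.0, K=25.0))
        t = np.array([m.t for m in ms])
        assert np.allclose(np.diff(t), 25.0)

    def test_stateless_without_prediction(self):
        # with the prediction disabled each window is measured independently:
        # starting later must reproduce the same values at the same times
        env = Envelope(periodic_envelope(430.0, 8000))
        cfg = AfConfig(pf_enabled=False)
        full = measure_instantaneous(env, cfg)
        late = measure_instantaneous(env, cfg, start_ms=1000.0)
        by_t = {m.t: m.F for m in full}
        assert all(by_t[m.t] == m.F for m in late if m.t in by_t)

    def test_envelope_shorter_than_window_warns_and_is_empty(self):
        env = Envelope(np.ones(500) + np.sin(np.arange(500) / 10.0) ** 2)
        with pytest.warns(UserWarning):
            out = measure_instantaneous(env, AfConfig(D=1.0))
        assert out == []

    def test_prediction_marks_predicted_and_keeps_centre(self, noisy_record):
        beats, record = noisy_record
        env = envelope_hilbert(bandpass(record, VALVE_BAND), 21)
        ms = measure_instantaneous(env, AfConfig())
        predicted = [m for m in ms if m.predicted]
        for m in predicted:
            assert m.valid
            assert m.af_peak < 0.5

    def test_config_validation(self):
        with pytest.raises(ValueError):
            AfConfig(p_th=0.6)  # loss threshold above the prediction gate
        with pytest.raises(ValueError):
            AfConfig(D=0.4)  # window cannot support the lag range
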