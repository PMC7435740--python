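import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dopplerfhr as dp
from dopplerfhr.preprocessing import bandpass, BandSpec
from dopplerfhr.simulate import Phase, UsSimParams, measured_snr_db


class TestGenerateBeatTimes:
    def test_constant_rate_gives_constant_intervals(self):
        prof = dp.FhrProfile(duration=10.0, baseline=120.0, seed=0)
        beats = dp.generate_beat_times(prof)
        assert np.allclose(beats.intervals, 500.0)
        assert len(beats.intervals) >= 20  # 10 s at 500 ms

    def test_physiological_extremes_map_to_interval_limits(self):
        # 240 bpm <-> 250 ms; 60 bpm <-> 1000 ms
        fast = dp.generate_beat_times(dp.FhrProfile(duration=5.0, baseline=240.0, seed=0))
        slow = dp.generate_beat_times(dp.FhrProfile(duration=5.0, baseline=60.0, seed=0))
        assert np.allclose(fast.intervals, 250.0)
        assert np.allclose(slow.intervals, 1000.0)

    def test_jitter_sd_matches_first_difference_statistics(self):
        # i.i.d. interval jitter of SD s makes first differences SD ~ sqrt(2)*s
        # (long train: adjacent first differences are MA(1)-correlated, so the
        # sample SD needs many beats to settle)
        prof = dp.FhrProfile(duration=300.0, baseline=120.0, stv_jitter_sd=10.0, seed=42)
        beats = dp.generate_beat_times(prof)
        sd = np.std(np.diff(beats.intervals), ddof=1)
        assert abs(sd - np.sqrt(2) * 10.0) / (np.sqrt(2) * 10.0) < 0.2

    def test_deterministic_for_fixed_seed(self):
        prof = dp.FhrProfile(duration=20.0, baseline=140.0, stv_jitter_sd=5.0, seed=7)
        a = dp.generate_beat_times(prof)
        b = dp.generate_beat_times(prof)
        np.testing.assert_array_equal(a.onsets, b.onsets)

    def test_episode_modulates_rate(self):
        prof = dp.FhrProfile(
            duration=60.0, baseline=120.0, episodes=[(20.0, 40.0, 30.0)], seed=0
        )
        beats = dp.generate_beat_times(prof)
        mids = (beats.onsets[:-1] + beats.onsets[1:]) / 2000.0  # [s]
        inside = (mids > 27) & (mids < 33)  # plateau of the trapezoid
        outside = mids < 15
        assert np.mean(60000.0 / beats.intervals[inside]) > np.mean(
            60000.0 / beats.intervals[outside]
        ) + 25.0

    def test_profile_yielding_nonpositive_rate_rejected(self):
        prof = dp.FhrProfile(
            duration=30.0, baseline=60.0, episodes=[(5.0, 25.0, -80.0)], seed=0
        )
        with pytest.raises(ValueError):
            dp.generate_beat_times(prof)

    def test_baseline_outside_physiological_range_rejected(self):
        with pytest.raises(ValueError):
            dp.FhrProfile(duration=10.0, baseline=300.0)


class TestSynthesize:
    def test_deterministic_waveform_for_fixed_seed(self):
        beats = dp.generate_beat_times(dp.FhrProfile(duration=5.0, baseline=120.0, seed=1))
        a = dp.synthesize_us_signal(beats, UsSimParams(), seed=3)
        b = dp.synthesize_us_signal(beats, UsSimParams(), seed=3)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_single_wall_phase_is_band_limited(self):
        beats = dp.generate_beat_times(dp.FhrProfile(duration=10.0, baseline=120.0, seed=0))
        params = UsSimParams(phases=[Phase("Vc", 0.05, 70.0, 150.0, 1.0)], noise_sd=0.0, drift=None)
        rec = dp.synthesize_us_signal(beats, params, seed=0)
        f, p = _periodogram(rec)
        in_band = p[(f >= 100) & (f <= 300)].sum()
        assert in_band / p.sum() > 0.95

    def test_spectral_confinement_of_default_phases(self):
        # with no noise, >= 95% of power lies in the union of phase bands
        beats = dp.generate_beat_times(dp.FhrProfile(duration=10.0, baseline=120.0, seed=0))
        rec = dp.synthesize_us_signal(beats, UsSimParams(noise_sd=0.0, drift=None), seed=0)
        f, p = _periodogram(rec)
        in_band = p[(f >= 100) & (f <= 600)].sum()
        assert in_band / p.sum() > 0.95

    def test_one_burst_cluster_per_cycle(self):
        beats = dp.generate_beat_times(dp.FhrProfile(duration=10.0, baseline=120.0, seed=0))
        rec = dp.synthesize_us_signal(beats, UsSimParams(noise_sd=0.0, drift=None), seed=0)
        env = dp.envelope_hilbert(bandpass(rec, BandSpec(300, 600)), None)
        # strongest envelope peaks must repeat at the 500 ms period
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(env.values, height=0.5 * env.values.max(), distance=400)
        spacing = np.diff(peaks.astype(float))
        assert np.all(np.abs(spacing - 500.0) < 20.0)

    def test_default_snr_above_10db(self):
        beats = dp.generate_beat_times(dp.FhrProfile(duration=20.0, baseline=120.0, seed=0))
        assert measured_snr_db(beats, UsSimParams(), seed=0) >= 10.0

    def test_overlapping_bursts_warn(self):
        beats = dp.generate_beat_times(dp.FhrProfile(duration=3.0, baseline=240.0, seed=0))
        params = UsSimParams(phases=[Phase("Vc", 0.1, 300.0, 150.0, 1.0)], noise_sd=0.0)
        with pytest.warns(UserWarning, match="overlap"):
            dp.synthesize_us_signal(beats, params, seed=0)

    def test_low_sample_rate_rejected(self):
        with pytest.raises(ValueError):
            UsSimParams(fs=1000.0)


class TestBeatsToReference:
    def test_simple_onsets(self):
        ev = dp.beats_to_reference(dp.BeatTrain(np.array([0.0, 500.0, 1000.0])))
        np.testing.assert_array_equal(ev.tau, [0.0, 500.0])
        np.testing.assert_array_equal(ev.T, [500.0, 500.0])
        assert ev.valid.all()

    def test_single_onset_gives_empty_series(self):
        assert len(dp.beats_to_reference(dp.BeatTrain(np.array([100.0])))) == 0

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(1.0, 1000.0), min_size=1, max_size=50))
    def test_intervals_telescope_to_total_span(self, gaps):
        onsets = np.concatenate([[0.0], np.cumsum(gaps)])
        ev = dp.beats_to_reference(dp.BeatTrain(onsets))
        assert np.isclose(ev.T.sum(), onsets[-1] - onsets[0], rtol=0, atol=1e-9)


def _periodogram(rec):
    from scipy.signal import periodogram

    return periodogram(rec.samples, fs=rec.fs)
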