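import numpy as np
import pytest

import dopplerfhr as dp
from dopplerfhr.events import BeatEventSeries
from dopplerfhr.evaluation import (
    LTV_INDICES,
    STV_INDICES,
    fhr_from_interval,
    interval_errors,
    relative_index_error,
    synchronize,
    variability_indices,
)


def series_of(T_values, valid=None, t0=0.0):
    T = np.asarray(T_values, dtype=float)
    tau = t0 + np.concatenate([[0.0], np.cumsum(T[:-1])])
    if valid is None:
        valid = np.ones(len(T), bool)
    return BeatEventSeries(tau, T, valid)


def shifted(series, s):
    return BeatEventSeries(series.tau + s, series.T, series.valid, source="d2")


@pytest.fixture(scope="module")
def jittered_series():
    rng = np.random.default_rng(11)
    T = 500.0 + rng.normal(0.0, 5.0, size=130)
    return series_of(T)


class TestConversion:
    def test_physiological_span(self):
        assert fhr_from_interval(250.0) == pytest.approx(240.0)
        assert fhr_from_interval(1000.0) == pytest.approx(60.0)
        assert fhr_from_interval(500.0) == pytest.approx(120.0)

    def test_round_trip_over_physiological_range(self):
        for f in np.linspace(60.0, 240.0, 19):
            assert fhr_from_interval(60000.0 / f) == pytest.approx(f)

    def test_nonpositive_interval_rejected(self):
        with pytest.raises(ValueError):
            fhr_from_interval(0.0)


class TestSynchronize:
    def test_identical_series_zero_shift(self, jittered_series):
        res = synchronize(jittered_series, jittered_series)
        assert res.shift == 0.0
        assert res.mean_abs_err == 0.0

    def test_planted_shift_recovered_exactly(self, jittered_series):
        for s in (-3000, -137, 137, 2500, 3000):
            res = synchronize(shifted(jittered_series, s), jittered_series)
            assert res.shift == s
            assert res.mean_abs_err == 0.0

    def test_shift_recovery_with_interval_noise(self, jittered_series):
        rng = np.random.default_rng(5)
        noisy = BeatEventSeries(
            jittered_series.tau + 137.0,
            jittered_series.T + rng.normal(0.0, 5.0, len(jittered_series)),
            jittered_series.valid,
        )
        res = synchronize(noisy, jittered_series)
        assert abs(res.shift - 137.0) <= 3.0

    def test_disjoint_series_raise(self, jittered_series):
        far = shifted(jittered_series, 1e6)
        with pytest.raises(ValueError):
            synchronize(far, jittered_series)


class TestIntervalErrors:
    def test_identical_series(self, jittered_series):
        st = interval_errors(jittered_series, jittered_series, 0.0)
        assert st.mean_dT == 0.0 and st.sd_dT == 0.0 and st.mean_abs_dT == 0.0
        assert st.signal_loss_pct == pytest.approx(0.0, abs=1e-9)

    def test_constant_bias_measured(self, jittered_series):
        biased = BeatEventSeries(jittered_series.tau, jittered_series.T + 2.0, jittered_series.valid)
        st = interval_errors(biased, jittered_series, 0.0)
        assert st.mean_dT == pytest.approx(2.0)
        assert st.sd_dT == pytest.approx(0.0, abs=1e-9)
        assert st.mean_abs_dT == pytest.approx(2.0)

    def test_one_second_gap_is_two_percent_loss(self, jittered_series):
        # knock out the events covering [20 s, 21 s]
        valid = jittered_series.valid.copy()
        ends = jittered_series.tau + jittered_series.T
        inside = (ends > 20000.0) & (jittered_series.tau < 21000.0)
        valid[inside] = False
        gap_ms = np.sum(jittered_series.T[inside])
        test = BeatEventSeries(jittered_series.tau, jittered_series.T, valid)
        st = interval_errors(test, jittered_series, 0.0)
        assert st.signal_loss_pct == pytest.approx(gap_ms / 50000.0 * 100.0, rel=0.01)


class TestVariabilityIndices:
    def test_constant_series_has_zero_stv(self):
        idx = variability_indices(series_of([500.0] * 120))
        for name in STV_INDICES:
            assert idx[name] == pytest.approx(0.0, abs=1e-9)

    def test_alternating_series_forces_s_dal(self):
        T = [490.0, 510.0] * 60
        idx = variability_indices(series_of(T))
        assert idx["S_DAL"] == pytest.approx(20.0)

    def test_too_few_intervals_undefined_not_zero(self):
        idx = variability_indices(series_of([500.0] * 5))
        assert all(np.isnan(v) for v in idx.values())

    def test_neighbor_averaging_strictly_decreases_every_stv_index(self, jittered_series):
        T = jittered_series.T
        smoothed = np.convolve(T, np.ones(3) / 3.0, mode="same")
        smoothed[0], smoothed[-1] = T[0], T[-1]
        idx_raw = variability_indices(jittered_series)
        idx_smooth = variability_indices(series_of(smoothed))
        for name in STV_INDICES:
            assert idx_smooth[name] < idx_raw[name]

    def test_scale_invariance_of_ratio_indices(self, jittered_series):
        # full-span windows so both series keep the identical interval set
        doubled = series_of(jittered_series.T * 2.0)
        a = variability_indices(jittered_series, window=(0.0, jittered_series.T.sum()))
        b = variability_indices(doubled, window=(0.0, doubled.T.sum()))
        for name in ("S_YEH", "L_YEH", "L_ZUG"):
            assert b[name] == pytest.approx(a[name], rel=1e-9)

    def test_gaps_break_difference_sums(self):
        # a huge value hidden behind a loss marker must not leak into STV
        T = [500.0] * 60 + [900.0] + [500.0] * 60
        valid = np.ones(121, bool)
        valid[60] = False
        idx = variability_indices(series_of(T, valid))
        assert idx["S_DAL"] == pytest.approx(0.0, abs=1e-9)


class TestIndexErrors:
    def test_reference_cases(self):
        ref = {"S_DAL": 4.0}
        assert relative_index_error({"S_DAL": 4.0}, ref)["S_DAL"] == pytest.approx(0.0)
        assert relative_index_error({"S_DAL": 2.0}, ref)["S_DAL"] == pytest.approx(-50.0)
        assert relative_index_error({"S_DAL": 4.4}, ref)["S_DAL"] == pytest.approx(10.0)

    def test_zero_reference_undefined(self):
        out = relative_index_error({"S_DAL": 1.0}, {"S_DAL": 0.0})
        assert np.isnan(out["S_DAL"])
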