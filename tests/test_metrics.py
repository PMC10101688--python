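"""Trace quantification: peaks, fold potentiation, latency scoring,
fractional inhibition, Hill fits and model time-course tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from otopkin import (
    DataError,
    Trace,
    fold_potentiation,
    fractional_inhibition,
    hill_fit,
    hill_remaining_fraction,
    peak_inward,
    time_to_peak,
    timecourse_table,
)


def make_trace(values, hz=1000.0, **annotations):
    return Trace(hz, np.asarray(values, dtype=float), annotations)


class TestPeakInward:
    def test_flat_trace_reports_window_start(self):
        tr = make_trace(np.full(1000, -2.0))
        mag, t = peak_inward(tr, (0.1, 0.5))
        assert mag == 2.0
        assert t == pytest.approx(0.1)

    def test_linear_ramp_peaks_at_end(self):
        t = np.arange(0, 4.001, 1e-3)
        tr = make_trace(-t)
        mag, tp = peak_inward(tr, (0.0, 4.0))
        assert mag == pytest.approx(4.0)
        assert tp == pytest.approx(4.0)

    def test_empty_window_raises(self):
        tr = make_trace(np.zeros(100))
        with pytest.raises(DataError):
            peak_inward(tr, (0.5, 0.2))

    def test_smoothing_suppresses_a_noise_spike(self):
        values = np.zeros(2000)
        values[700] = -50.0  # single-sample artifact
        values[1000:1400] = -3.0  # genuine plateau
        tr = make_trace(values)
        mag_raw, _ = peak_inward(tr, (0.0, 2.0))
        mag_sm, t_sm = peak_inward(tr, (0.0, 2.0), smooth_s=0.05)
        assert mag_raw == 50.0
        assert mag_sm < 5.0
        assert 1.0 <= t_sm <= 1.4


class TestFoldPotentiation:
    def test_identical_traces_give_one(self):
        tr = make_trace(-np.sin(np.linspace(0, np.pi, 500)))
        assert fold_potentiation(tr, tr) == pytest.approx(1.0)

    def test_scaled_trace_gives_scale(self):
        base = -np.sin(np.linspace(0, np.pi, 500))
        assert fold_potentiation(
            make_trace(10 * base), make_trace(base)
        ) == pytest.approx(10.0)

    def test_zero_control_is_an_error(self):
        with pytest.raises(DataError):
            fold_potentiation(make_trace(-np.ones(10)), make_trace(np.zeros(10)))

    @settings(max_examples=30, deadline=None)
    @given(c=st.floats(1e-6, 1e6))
    def test_scale_invariance(self, c):
        base = -np.sin(np.linspace(0, np.pi, 200))
        test = 3.7 * base
        f0 = fold_potentiation(make_trace(test), make_trace(base))
        f1 = fold_potentiation(make_trace(c * test), make_trace(c * base))
        assert f1 == pytest.approx(f0, rel=1e-9)


class TestTimeToPeak:
    def test_monotone_growth_scores_the_cap(self):
        t = np.arange(0, 10, 1e-3)
        tr = make_trace(-t)
        assert time_to_peak(tr, onset_s=0.0, cap_s=8.0) == 8.0

    def test_peak_at_onset_scores_zero(self):
        values = np.concatenate([[-5.0], np.linspace(-4, 0, 999)])
        tr = make_trace(values)
        assert time_to_peak(tr, onset_s=0.0) == 0.0

    def test_equal_minima_report_the_earlier(self):
        values = np.zeros(4000)
        values[1000] = -3.0
        values[3000] = -3.0
        tr = make_trace(values)
        assert time_to_peak(tr, onset_s=0.0) == pytest.approx(1.0)

    def test_attained_peak_is_reported_in_seconds(self):
        t = np.arange(0, 8, 1e-3)
        tr = make_trace(-np.exp(-((t - 2.5) ** 2)))
        assert time_to_peak(tr, onset_s=0.0) == pytest.approx(2.5, abs=1e-2)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 6999))
    def test_latency_never_exceeds_cap(self, k):
        values = np.zeros(7000)
        values[k] = -1.0
        tr = make_trace(values)
        assert 0.0 <= time_to_peak(tr, onset_s=0.0, cap_s=8.0) <= 8.0

    def test_onset_after_trace_end_raises(self):
        tr = make_trace(np.zeros(100))
        with pytest.raises(DataError):
            time_to_peak(tr, onset_s=5.0)


class TestFractionalInhibition:
    def test_unchanged_current_gives_zero(self):
        tr = make_trace(np.full(2000, -4.0))
        assert fractional_inhibition(tr, 0.5, 1.5) == pytest.approx(0.0)

    def test_halved_current_gives_half(self):
        values = np.concatenate([np.full(1000, -4.0), np.full(1000, -2.0)])
        tr = make_trace(values)
        assert fractional_inhibition(tr, 0.5, 1.5) == pytest.approx(0.5)

    def test_zero_baseline_is_an_error(self):
        tr = make_trace(np.zeros(2000))
        with pytest.raises(DataError):
            fractional_inhibition(tr, 0.5, 1.5)


class TestHillFit:
    @pytest.mark.parametrize(
        "ic50, n",
        [(0.31e-3, 0.94), (1e-3, 1.0), (1e-5, 0.5), (1e-2, 3.0), (2e-4, 2.0)],
    )
    def test_noiseless_round_trip_is_exact(self, ic50, n):
        conc = np.logspace(np.log10(0.03e-3), np.log10(10e-3), 8)
        frac = hill_remaining_fraction(conc, ic50, n)
        fit = hill_fit(conc, frac)
        assert fit.ic50_molar == pytest.approx(ic50, rel=1e-6)
        assert fit.hill_n == pytest.approx(n, rel=1e-6)

    def test_canonical_hill_midpoint(self):
        conc = np.logspace(-5, -1, 9)
        fit = hill_fit(conc, hill_remaining_fraction(conc, 1e-3, 1.0))
        assert hill_remaining_fraction(fit.ic50_molar, fit.ic50_molar,
                                       fit.hill_n) == 0.5

    def test_noisy_recovery_within_15_percent(self):
        from otopkin import generate_dose_response

        df = generate_dose_response(
            0.31e-3, 0.94,
            np.logspace(np.log10(0.03e-3), np.log10(10e-3), 8),
            sigma=0.02, replicates=6, seed=20,
        )
        fit = hill_fit(df["concentration_M"], df["remaining_fraction"])
        assert fit.ic50_molar == pytest.approx(0.31e-3, rel=0.15)

    def test_input_validation(self):
        with pytest.raises(DataError):
            hill_fit([1e-3, 2e-3], [0.5, 0.4])
        with pytest.raises(DataError):
            hill_fit([0.0, 1e-3, 2e-3], [1.0, 0.5, 0.4])
        with pytest.raises(DataError):
            hill_fit([1e-3, 2e-3, 4e-3], [1.5, 0.5, 0.4])


@pytest.fixture(scope="module")
def pre_table(model):
    return timecourse_table(
        model, mode="pre_exposure",
        durations_s=(1.0, 4.0, 16.0),
        concentrations_molar=(0.3e-3, 1e-3, 3e-3),
        sample_interval_s=5e-3,
    )


class TestTimecourseTable:

    def test_fold_increases_with_concentration(self, pre_table):
        at16 = pre_table[pre_table.duration_s == 16.0].sort_values("zn_molar")
        folds = at16.fold_potentiation.to_numpy()
        assert np.all(np.diff(folds) > 0)
        assert np.all(folds > 1.0)

    def test_fold_increases_with_exposure_duration(self, pre_table):
        at1mm = pre_table[pre_table.zn_molar == 1e-3].sort_values("duration_s")
        folds = at1mm.fold_potentiation.to_numpy()
        assert np.all(np.diff(folds) > 0)

    def test_potentiation_speeds_time_to_peak(self, pre_table, model):
        row = pre_table[
            (pre_table.zn_molar == 1e-3) & (pre_table.duration_s == 16.0)
        ].iloc[0]
        ctrl = timecourse_table(
            model, mode="pre_exposure", durations_s=(16.0,),
            concentrations_molar=(0.0,), sample_interval_s=5e-3,
        ).iloc[0]
        assert row.time_to_peak_s < ctrl.time_to_peak_s

    def test_wash_off_fold_decays_monotonically(self, model):
        table = timecourse_table(
            model, mode="wash_off", durations_s=(1.0, 8.0, 32.0),
            concentrations_molar=(1e-3,), sample_interval_s=5e-3,
        )
        folds = table.sort_values("duration_s").fold_potentiation.to_numpy()
        assert np.all(np.diff(folds) < 0)
        assert np.all(folds >= 1.0)

    def test_zero_wash_off_equals_pre_exposure(self, model):
        """A wash-off of zero duration reduces to the plain pre-exposure
        protocol (the wash epoch is dropped)."""
        wash = timecourse_table(
            model, mode="wash_off", durations_s=(0.0,),
            concentrations_molar=(1e-3,), sample_interval_s=5e-3,
        ).iloc[0]
        pre = timecourse_table(
            model, mode="pre_exposure", durations_s=(16.0,),
            concentrations_molar=(1e-3,), sample_interval_s=5e-3,
        ).iloc[0]
        assert wash.fold_potentiation == pytest.approx(
            pre.fold_potentiation, rel=1e-9
        )
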