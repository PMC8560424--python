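"""Train-metric tests: success classification, depression/recovery fits,
RRP integrals, spontaneous events, cohort statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from calyxatp import (
    EpscTrain,
    RecoveryMeasurement,
    SweepTrace,
    classify_successes,
    cohort_summary,
    detect_spontaneous_events,
    fit_depression,
    fit_recovery_time_course,
    fractional_recovery,
    paired_pulse_ratio,
    rolling_success,
    rrp_from_integral,
    steady_state_depression,
    time_to_first_failure,
)


def make_train(amplitudes, frequency=100.0, **kw):
    amplitudes = np.asarray(amplitudes, dtype=float)
    t = np.arange(len(amplitudes)) / frequency
    return EpscTrain(stim_times=t, amplitudes=amplitudes,
                     frequency=frequency, **kw)


class TestClassifySuccesses:
    def test_five_percent_threshold(self):
        tr = make_train([10.0, 0.4, 6.0])
        np.testing.assert_array_equal(
            classify_successes(tr, 0.05, baseline_amp=10.0),
            [True, False, True])

    def test_exactly_at_threshold_is_success(self):
        tr = make_train([10.0, 0.5, 10.0])
        assert classify_successes(tr, 0.05, baseline_amp=10.0)[1]

    def test_all_at_baseline_all_true(self):
        tr = make_train([7.0] * 30)
        assert classify_successes(tr).all()

    def test_nonpositive_baseline_rejected(self):
        tr = make_train([10.0, 5.0])
        with pytest.raises(ValueError):
            classify_successes(tr, baseline_amp=0.0)


class TestRollingSuccess:
    @pytest.mark.parametrize("flags, expected_last", [
        ([True] * 25, 100.0),
        ([True] * 20 + [False] * 5, 80.0),
        ([bool((i + 1) % 2) for i in range(25)], 52.0),  # alternating, 13/25
    ])
    def test_trailing_window_values(self, flags, expected_last):
        out = rolling_success(flags, window=25)
        assert out[-1] == pytest.approx(expected_last)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            rolling_success([True] * 10, window=25)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(st.booleans(), min_size=25, max_size=200))
    def test_bounded_and_all_true_saturates(self, flags):
        out = rolling_success(flags, window=25)
        assert np.all((out >= 0) & (out <= 100 + 1e-9))
        if all(flags):
            np.testing.assert_allclose(out, 100.0)


class TestTimeToFirstFailure:
    def test_first_consecutive_pair(self):
        s = [1, 1, 0, 1, 0, 0, 1]
        t = np.arange(7) / 100.0
        assert time_to_first_failure(np.array(s, bool), t) == \
            pytest.approx(0.04)

    @pytest.mark.parametrize("s", [
        [1, 1, 1, 1], [1, 0, 1, 0, 1, 0]])  # no pair of failures
    def test_none_without_a_pair(self, s):
        assert time_to_first_failure(np.array(s, bool),
                                     np.arange(len(s)) / 100.0) is None

    def test_invariant_to_later_events(self):
        t = np.arange(10) / 100.0
        early = np.array([1, 0, 0, 1, 1, 1, 1, 1, 1, 1], bool)
        noisy = np.array([1, 0, 0, 0, 1, 0, 0, 1, 0, 0], bool)
        assert time_to_first_failure(early, t) == \
            time_to_first_failure(noisy, t)


class TestPairedPulseRatio:
    @pytest.mark.parametrize("amps, ppr", [
        ([10, 8, 5], 0.8), ([4, 4, 4], 1.0), ([5, 6], 1.2)])
    def test_ratio(self, amps, ppr):
        assert paired_pulse_ratio(make_train(amps)) == pytest.approx(ppr)

    def test_zero_first_amp_rejected(self):
        with pytest.raises(ValueError):
            paired_pulse_ratio(make_train([0.0, 5.0]))


class TestDepressionFit:
    @staticmethod
    def synthetic(ss, tau, frequency, n, scale=1.0):
        t = np.arange(n) / frequency
        return make_train(scale * (ss + (1 - ss) * np.exp(-t / tau)),
                          frequency=frequency)

    @pytest.mark.parametrize("frequency, n, window", [
        (100.0, 20, (3, 20)), (300.0, 46, (3, 46))])
    def test_recovers_generating_tau(self, frequency, n, window):
        tr = self.synthetic(ss=0.3, tau=0.05, frequency=frequency, n=n)
        res = fit_depression(tr)
        assert res["fit_window"] == window
        assert res["tau"] == pytest.approx(0.05, rel=0.01)
        assert res["steady_state_frac"] == pytest.approx(0.3, rel=0.02)

    def test_scale_invariance(self):
        a = fit_depression(self.synthetic(0.3, 0.05, 100.0, 20))
        b = fit_depression(self.synthetic(0.3, 0.05, 100.0, 20, scale=37.0))
        assert a["tau"] == pytest.approx(b["tau"], rel=1e-6)

    def test_constant_train_flagged_degenerate(self):
        res = fit_depression(make_train([5.0] * 20))
        assert res["flag"] == "degenerate_constant"
        assert res["steady_state_frac"] == pytest.approx(1.0)

    def test_explicit_window_beyond_train_rejected(self):
        with pytest.raises(ValueError):
            fit_depression(make_train([5.0] * 10), window=(3, 20))

    def test_default_window_clamps_to_short_burst(self):
        """A 45-stimulus 300 Hz burst fits over pulses 3-45."""
        tr = self.synthetic(ss=0.3, tau=0.05, frequency=300.0, n=45)
        res = fit_depression(tr)
        assert res["fit_window"] == (3, 45)
        assert res["tau"] == pytest.approx(0.05, rel=0.01)


class TestSteadyState:
    def test_mean_of_tail_after_three_tau(self):
        tr = make_train([10.0] * 5 + [4.0] * 15)
        # tau chosen so 3*tau falls inside the constant tail
        assert steady_state_depression(tr, tau=0.016) == pytest.approx(0.4)

    def test_pure_exponential_tail_mean(self):
        ss, tau = 0.3, 0.05
        tr = TestDepressionFit.synthetic(ss, tau, 100.0, 20)
        t = tr.stim_times
        expect = np.mean((ss + (1 - ss) * np.exp(-t / tau))[t > 3 * tau])
        assert steady_state_depression(tr, tau) == pytest.approx(expect)
        assert expect == pytest.approx(0.31, abs=0.02)

    def test_all_equal_gives_unity(self):
        tr = make_train([6.0] * 20)
        assert steady_state_depression(tr, tau=0.01) == pytest.approx(1.0)

    def test_no_tail_coverage_rejected(self):
        tr = make_train([10.0] * 20)
        with pytest.raises(ValueError):
            steady_state_depression(tr, tau=1.0)


class TestRrpIntegral:
    def test_rectangular_current(self):
        fs = 10_000.0
        y = np.zeros(int(0.4 * fs))
        t = np.arange(len(y)) / fs
        y[(t >= 0.1) & (t < 0.3)] = 1.0
        sweep = SweepTrace(sampling_rate=fs, samples=y)
        q = rrp_from_integral(sweep, (0.1, 0.3))
        assert q == pytest.approx(0.2, rel=0.01)

    def test_linearity_in_amplitude(self):
        fs = 10_000.0
        rng = np.random.default_rng(5)
        y = rng.normal(2.0, 0.1, int(0.3 * fs))
        s1 = SweepTrace(sampling_rate=fs, samples=y)
        s3 = SweepTrace(sampling_rate=fs, samples=3 * y)
        q1 = rrp_from_integral(s1, (0.1, 0.25))
        assert rrp_from_integral(s3, (0.1, 0.25)) == pytest.approx(3 * q1,
                                                                   rel=1e-9)

    def test_additive_over_disjoint_windows(self):
        fs = 10_000.0
        y = np.sin(np.linspace(0, 20, int(0.5 * fs))) + 2.0
        sweep = SweepTrace(sampling_rate=fs, samples=y)
        q_all = rrp_from_integral(sweep, (0.1, 0.4), baseline_window=0.05)
        q_a = rrp_from_integral(sweep, (0.1, 0.25), baseline_window=0.05)
        # same pre-train baseline for the second half to keep windows comparable
        t = np.arange(len(y)) / fs
        base = float(np.median(y[(t >= 0.05) & (t < 0.1)]))
        sel = (t >= 0.25) & (t <= 0.4)
        q_b = float(np.trapezoid(y[sel] - base, t[sel]))
        assert q_all == pytest.approx(q_a + q_b, rel=1e-6)

    def test_artifact_blanking_restores_clean_integral(self):
        """Artifact spikes inside blank windows leave the integral unchanged."""
        fs = 10_000.0
        n = int(0.5 * fs)
        t = np.arange(n) / fs
        clean = np.where((t >= 0.1) & (t < 0.35), 1.5, 0.0)
        stim = np.arange(0.1, 0.35, 0.05)
        dirty = clean.copy()
        for st_ in stim:
            dirty[(t >= st_) & (t < st_ + 0.0004)] += 80.0
        s_clean = SweepTrace(sampling_rate=fs, samples=clean, stim_times=stim,
                             artifact_window=0.0005)
        s_dirty = SweepTrace(sampling_rate=fs, samples=dirty, stim_times=stim,
                             artifact_window=0.0005)
        q_clean = rrp_from_integral(s_clean, (0.1, 0.35))
        q_dirty = rrp_from_integral(s_dirty, (0.1, 0.35))
        assert q_dirty == pytest.approx(q_clean, rel=0.01)

    def test_window_outside_sweep_rejected(self):
        sweep = SweepTrace(sampling_rate=1000.0, samples=np.zeros(100))
        with pytest.raises(ValueError):
            rrp_from_integral(sweep, (0.0, 1.0))


class TestRecoveryFit:
    def test_recovers_generating_tau(self):
        tau, f0 = 2.0, 0.2
        iv = np.array([0.1, 0.3, 1, 2, 4, 8, 13.0])
        frac = 1 - (1 - f0) * np.exp(-iv / tau)
        rec = RecoveryMeasurement(intervals=iv, fractional=frac)
        res = fit_recovery_time_course(rec)
        assert res["tau"] == pytest.approx(2.0, rel=0.02)

    def test_exclusion_removes_facilitation_points(self):
        tau, f0 = 2.0, 0.2
        iv = np.array([0.01, 0.1, 0.3, 1, 2, 4, 8, 13.0])
        frac = 1 - (1 - f0) * np.exp(-iv / tau)
        frac[iv < 0.4] = 1.3   # transient facilitation at short intervals
        rec = RecoveryMeasurement(intervals=iv, fractional=frac)
        res = fit_recovery_time_course(rec, exclude_before=0.4)
        assert res["n_points"] == int(np.sum(iv >= 0.4))
        assert res["tau"] == pytest.approx(2.0, rel=0.05)

    def test_full_recovery_flagged(self):
        rec = RecoveryMeasurement(intervals=np.array([0.5, 1, 2, 4.0]),
                                  fractional=np.ones(4))
        assert fit_recovery_time_course(rec)["flag"] == \
            "degenerate_full_recovery"

    def test_too_few_points_rejected(self):
        rec = RecoveryMeasurement(intervals=np.array([1.0, 2.0]),
                                  fractional=np.array([0.5, 0.8]))
        with pytest.raises(ValueError):
            fit_recovery_time_course(rec)


class TestFractionalRecovery:
    @pytest.mark.parametrize("pre, post, frac", [
        (10, 8, 0.8), (10, 10, 1.0), (10, 12, 1.2)])
    def test_ratio(self, pre, post, frac):
        assert fractional_recovery(pre, post) == pytest.approx(frac)

    def test_nonpositive_pre_rejected(self):
        with pytest.raises(ValueError):
            fractional_recovery(0.0, 5.0)


class TestSpontaneousEvents:
    def test_injected_events_counted(self):
        fs = 10_000.0
        rng = np.random.default_rng(2)
        y = rng.normal(0, 5.0, int(20 * fs))
        times = [2.0, 6.0, 9.5, 14.0, 18.0]
        for et in times:
            y[int(et * fs)] = 100.0
        sweep = SweepTrace(sampling_rate=fs, samples=y)
        res = detect_spontaneous_events(sweep, amp_threshold=25.0,
                                        min_interval=0.01)
        assert len(res["times"]) == 5
        assert res["frequency"] == pytest.approx(0.25)

    def test_empty_trace(self):
        sweep = SweepTrace(sampling_rate=1000.0, samples=np.zeros(5000))
        res = detect_spontaneous_events(sweep, amp_threshold=1.0)
        assert res["frequency"] == 0.0 and len(res["times"]) == 0

    def test_median_amplitude_recovered(self):
        fs = 10_000.0
        y = np.zeros(int(10 * fs))
        amps = [60, 80, 120.0]
        for k, a in enumerate(amps):
            y[int((2 + 3 * k) * fs)] = a
        sweep = SweepTrace(sampling_rate=fs, samples=y)
        res = detect_spontaneous_events(sweep, amp_threshold=30.0)
        assert res["median_amplitude"] == pytest.approx(80.0)

    def test_zero_analyzable_duration_rejected(self):
        sweep = SweepTrace(sampling_rate=1000.0, samples=np.zeros(1000))
        with pytest.raises(ValueError):
            detect_spontaneous_events(sweep, 1.0,
                                      exclude_windows=[(0.0, 2.0)])


class TestCohortSummary:
    def test_identical_values_zero_cv(self):
        assert cohort_summary([1.0, 1.0, 1.0])["cv"] == 0.0

    def test_two_values(self):
        res = cohort_summary([2.0, 4.0])
        assert res["mean"] == pytest.approx(3.0)
        assert res["cv"] == pytest.approx(np.sqrt(2) / 3)

    def test_cv_scale_invariant(self):
        v = [3.0, 5.0, 9.0, 4.0]
        assert cohort_summary(v)["cv"] == pytest.approx(
            cohort_summary([10 * x for x in v])["cv"])

    @pytest.mark.parametrize("vals", [[1.0], []])
    def test_too_few_rejected(self, vals):
        with pytest.raises(ValueError):
            cohort_summary(vals)
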