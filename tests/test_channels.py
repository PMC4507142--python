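"""Idealization, survival analysis, amplitude histograms, summaries."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gakit.channels import (
    ChannelEvent,
    EventList,
    amplitude_histogram,
    detect_events,
    fit_lifetime,
    reconstruct_ideal_trace,
    summarize_conditions,
    survival_curve,
)
from gakit.synthetic import (
    CurrentTrace,
    GatingParams,
    events_to_trace,
    simulate_channel_trace,
)

from conftest import match_events


class TestDetectEvents:
    def test_constant_trace_yields_no_events(self):
        trace = CurrentTrace(dt=2e-4, samples=np.zeros(5000))
        assert len(detect_events(trace)) == 0

    def test_flat_noisy_trace_yields_no_events(self):
        rng = np.random.default_rng(0)
        trace = CurrentTrace(dt=2e-4, samples=rng.normal(0, 0.3, 20000))
        assert len(detect_events(trace)) == 0

    def test_two_step_fixture_recovered_exactly(self, two_step_events):
        dt = 1.0 / 5000.0
        trace = events_to_trace(two_step_events, duration=0.6, dt=dt,
                                unit_current=2.8)
        found = detect_events(trace)
        assert len(found) == 2
        assert found[0].duration == pytest.approx(0.10, abs=dt)
        assert found[1].duration == pytest.approx(0.05, abs=dt)
        assert found[0].step_amplitude == pytest.approx(2.8, abs=1e-9)
        assert found[1].step_amplitude == pytest.approx(2.8, abs=1e-9)
        assert found[0].start == pytest.approx(0.1, abs=dt)

    def test_saturated_trace_rejected(self):
        samples = np.clip(np.linspace(-1, 6, 5000), 0.0, 5.0)
        trace = CurrentTrace(dt=2e-4, samples=samples)
        with pytest.raises(ValueError, match="saturat"):
            detect_events(trace, unit_amplitude_hint=2.8,
                          clip_limits=(0.0, 5.0))

    def test_structureless_excursions_rejected(self):
        # a smooth ramp has excursions but no integer-level grid
        t = np.linspace(0, 1, 5000)
        trace = CurrentTrace(dt=2e-4, samples=5.0 * t)
        with pytest.raises(ValueError, match="unresolvable unit amplitude"):
            detect_events(trace)

    def test_detection_matches_simulator_ground_truth(self):
        # >= 95% of events longer than 2x dead time matched one-to-one
        params = GatingParams(appearance_rate=5.0, mean_lifetime=0.05,
                              noise_sd=0.3, seed=42)
        trace, truth = simulate_channel_trace(params, 100.0)
        found = detect_events(trace)
        dead = found.metadata["dead_time_s"]
        rise = 0.3321 / params.filter_cutoff
        long_truth = [e for e in truth if e.duration > 2 * dead
                      and e.end < 100.0]
        assert len(long_truth) >= 400
        matched = match_events(long_truth, list(found), start_tol=rise)
        assert matched / len(long_truth) >= 0.95

    def test_idempotent_on_reconstructed_ideal_trace(self):
        params = GatingParams(appearance_rate=3.0, mean_lifetime=0.08,
                              noise_sd=0.3, seed=7)
        trace, _ = simulate_channel_trace(params, 40.0)
        first = detect_events(trace)
        unit = first.metadata["unit_pA"]
        ideal = reconstruct_ideal_trace(first, duration=40.0, dt=params.dt,
                                        unit_current=unit)
        second = detect_events(ideal, unit_amplitude_hint=unit)
        assert len(second) == len(first)
        for a, b in zip(first, second):
            assert b.start == pytest.approx(a.start, abs=1e-12)
            assert b.duration == pytest.approx(a.duration, abs=1e-12)
            assert b.level == a.level


class TestSurvivalCurve:
    def test_strict_inequality_convention(self):
        curve = survival_curve([1.0, 2.0, 3.0])
        assert curve.n_at(0.0) == 3
        assert curve.n_at(2.0) == 1
        assert curve.n_at(3.0) == 0

    def test_equal_lifetimes_single_step(self):
        curve = survival_curve([0.5] * 7)
        assert curve.n_at(0.499) == 7
        assert curve.n_at(0.5) == 0

    def test_exponential_slope_oracle(self):
        # -slope of ln N(t) over [0, 2 tau] ~ 1/tau
        rng = np.random.default_rng(1)
        tau = 0.5
        curve = survival_curve(rng.exponential(tau, 10_000))
        t, n = curve.step_coordinates()
        sel = (t <= 2 * tau) & (n > 0)
        slope = np.polyfit(t[sel], np.log(n[sel]), 1)[0]
        assert -1.0 / slope == pytest.approx(tau, rel=0.05)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            survival_curve([])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1e3), min_size=1,
                    max_size=200))
    def test_monotone_and_complete(self, lifetimes):
        curve = survival_curve(lifetimes)
        t, n = curve.step_coordinates()
        assert n[0] == len(lifetimes)  # N(0) = n
        assert np.all(np.diff(n) <= 0)  # non-increasing
        assert curve.n_at(max(lifetimes)) == 0


class TestFitLifetime:
    def test_degenerate_equal_lifetimes(self):
        fit = fit_lifetime([0.12] * 20, min_dwell=0.02)
        assert fit.tau == pytest.approx(0.10)

    def test_truncated_exponential_recovery(self):
        rng = np.random.default_rng(13)
        draws = 0.01 + rng.exponential(0.5, 10_000)
        fit = fit_lifetime(draws, min_dwell=0.01)
        assert fit.tau == pytest.approx(0.5, rel=0.02)
        assert fit.ci[0] < 0.5 < fit.ci[1]

    def test_dead_time_censoring_left_truncation_unbiased(self):
        # 20% of true events fall below the dead time; truncated MLE stays
        # unbiased after discarding them
        rng = np.random.default_rng(3)
        tau = 0.5
        dead = -tau * np.log(0.8)
        draws = rng.exponential(tau, 25_000)
        kept = draws[draws >= dead]
        assert abs(kept.size / draws.size - 0.8) < 0.01
        fit = fit_lifetime(kept, min_dwell=dead)
        se = tau / np.sqrt(kept.size)
        assert abs(fit.tau - tau) < 4 * se

    def test_small_sample_flag_and_empty_error(self):
        assert fit_lifetime([0.1] * 5).small_sample
        assert not fit_lifetime([0.1] * 50).small_sample
        with pytest.raises(ValueError):
            fit_lifetime([])

    def test_survival_lsq_alternative_agrees(self):
        rng = np.random.default_rng(4)
        draws = rng.exponential(0.3, 20_000)
        mle = fit_lifetime(draws, method="mle")
        lsq = fit_lifetime(draws, method="survival-lsq")
        assert lsq.tau == pytest.approx(mle.tau, rel=0.1)


class TestAmplitudeHistogram:
    def test_identical_amplitudes_give_exact_conductance(self):
        # 2.8 pA steps at 200 mV correspond to 14 pS
        hist = amplitude_histogram([2.8] * 100, voltage=200.0)
        assert hist.mu == 2.8
        assert hist.conductance == pytest.approx(14.0)
        assert not hist.fitted

    def test_gaussian_peak_recovery(self):
        rng = np.random.default_rng(5)
        amps = rng.normal(2.8, 0.2, 10_000)
        hist = amplitude_histogram(amps, bin_width=0.05, voltage=200.0)
        assert hist.mu == pytest.approx(2.8, rel=0.01)
        assert hist.sigma == pytest.approx(0.2, rel=0.2)

    def test_sign_symmetry_under_voltage_flip(self):
        rng = np.random.default_rng(6)
        amps = rng.normal(2.8, 0.2, 2000)
        pos = amplitude_histogram(amps, voltage=200.0)
        neg = amplitude_histogram(-amps, voltage=-200.0)
        assert neg.conductance == pytest.approx(pos.conductance, rel=1e-6)

    def test_counts_sum_to_event_count(self):
        rng = np.random.default_rng(7)
        amps = rng.normal(2.8, 0.2, 500)
        hist = amplitude_histogram(amps)
        assert hist.counts.sum() == 500

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            amplitude_histogram([])


class TestSummarizeConditions:
    def test_control_row_is_exactly_one(self):
        out = summarize_conditions(
            {"control": (0.5, 2.8), "same": (0.5, 2.8)}, "control")
        by = {s.condition: s for s in out}
        assert by["control"].tau_ratio == 1.0
        assert by["same"].tau_ratio == pytest.approx(1.0)
        assert by["same"].current_ratio == pytest.approx(1.0)

    def test_tenfold_lifetime_ratio(self):
        out = summarize_conditions(
            {"control": (0.5, 2.8), "C10mim": (5.0, 1.4)}, "control")
        by = {s.condition: s for s in out}
        assert by["C10mim"].tau_ratio == pytest.approx(10.0)
        assert by["C10mim"].current_ratio == pytest.approx(0.5)

    def test_missing_or_zero_control_rejected(self):
        with pytest.raises(ValueError):
            summarize_conditions({"a": (1.0, 1.0)}, "control")
        with pytest.raises(ValueError):
            summarize_conditions({"control": (0.0, 1.0)}, "control")


class TestEndToEndRecovery:
    def test_lifetime_and_conductance_recovered_through_idealization(self):
        # pipeline recovery on one long trace (tau = 500 ms ground truth)
        params = GatingParams(appearance_rate=1.0, mean_lifetime=0.5,
                              noise_sd=0.3, seed=31)
        durations, amps = [], []
        for rep in range(4):
            trace, _ = simulate_channel_trace(
                GatingParams(appearance_rate=1.0, mean_lifetime=0.5,
                             noise_sd=0.3, seed=31 + rep), 60.0)
            found = detect_events(trace)
            durations.extend(found.durations)
            amps.extend(found.amplitudes)
        assert len(durations) >= 150
        dead = 2 * 0.3321 / params.filter_cutoff
        fit = fit_lifetime(durations, min_dwell=dead)
        assert fit.tau == pytest.approx(0.5, rel=0.10)
        hist = amplitude_histogram(amps, voltage=200.0)
        assert hist.conductance == pytest.approx(14.0, rel=0.05)

    def test_event_table_roundtrip(self, tmp_path):
        ev = EventList(events=[ChannelEvent(0.1, 0.2, 2.8, 1),
                               ChannelEvent(0.5, 0.1, 2.7, 2)])
        p = tmp_path / "events.csv"
        ev.to_csv(p)
        back = EventList.from_csv(p)
        assert len(back) == 2
        assert back[1].level == 2
        assert back[0].duration == pytest.approx(0.2)
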