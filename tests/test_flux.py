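"""Normalization, stretched-exponential fitting, quench rates."""
import numpy as np
import pytest

from gakit.flux import (
    concentration_response,
    fit_stretched_exp,
    normalize_flux,
    quality_flags,
    quench_rate,
    quench_rate_curve,
)
from gakit.synthetic import simulate_flux_traces, stretched_exp


def _noiseless_pair(beta, tau0, **kw):
    ts = simulate_flux_traces(beta_true=beta, tau0_true=tau0, noise_sd=0.0,
                              seed=0, **kw)
    plus, minus = ts.pair("sample")
    return ts, plus, minus


class TestNormalizeFlux:
    def test_identical_traces_normalize_to_constant(self):
        ts, plus, _ = _noiseless_pair(0.7, 0.02)
        t, norm = normalize_flux((ts.time, plus), (ts.time, plus))
        assert np.ptp(norm) == 0.0

    def test_background_round_trip_recovers_model(self):
        # fast decay so the record truly reaches its plateau
        ts, plus, minus = _noiseless_pair(0.9, 0.005, il_background=200.0,
                                          leak_rate=0.0)
        t, norm = normalize_flux((ts.time, plus), (ts.time, minus))
        expected = np.exp(-np.power(t / 0.005, 0.9))
        assert norm[0] == pytest.approx(1.0, abs=1e-9)  # F0 -> 1
        assert abs(norm[-1]) < 1e-6  # F_inf -> 0
        assert np.max(np.abs(norm - expected)) < 1e-6

    def test_affine_invariance(self):
        ts, plus, minus = _noiseless_pair(0.7, 0.02)
        t, a = normalize_flux((ts.time, plus), (ts.time, minus))
        _, b = normalize_flux((ts.time, 3.5 * plus + 11.0),
                              (ts.time, 3.5 * minus + 11.0))
        assert np.allclose(a, b, atol=1e-10)

    def test_nonoverlapping_ranges_rejected(self):
        t = np.linspace(0, 0.1, 200)
        with pytest.raises(ValueError, match="cover"):
            normalize_flux((t, np.ones_like(t)),
                           (t + 1.0, np.ones_like(t)))

    def test_zero_dynamic_range_with_structure_rejected(self):
        # corrected signal keeps structure but pre and plateau coincide
        t = np.linspace(0, 0.1, 500)
        pulse = np.exp(-(((t - 0.05) / 0.01) ** 2))  # returns to its start
        with pytest.raises(ValueError, match="dynamic range"):
            normalize_flux((t, pulse), (t, np.zeros_like(t)))

    def test_control_resampled_onto_plus_grid(self):
        ts, plus, minus = _noiseless_pair(0.8, 0.01)
        coarse = np.linspace(ts.time[0], ts.time[-1], 301)
        minus_coarse = np.interp(coarse, ts.time, minus)
        t, a = normalize_flux((ts.time, plus), (coarse, minus_coarse))
        assert t.size == ts.time.size
        _, b = normalize_flux((ts.time, plus), (ts.time, minus))
        assert np.allclose(a, b, atol=1e-6)


class TestStretchedExpFit:
    def test_exact_exponential_recovers_beta_one(self):
        ts, plus, minus = _noiseless_pair(1.0, 0.01, il_background=0.0,
                                          leak_rate=0.0)
        t, norm = normalize_flux((ts.time, plus), (ts.time, minus))
        fit = fit_stretched_exp(t, norm)
        assert fit.beta == pytest.approx(1.0, abs=1e-6)
        assert fit.tau0 == pytest.approx(0.01, rel=1e-6)
        assert fit.converged

    def test_noiseless_stretched_recovery(self):
        t = np.arange(0.0, 0.12, 1 / 5000.0)
        v = stretched_exp(t, 1.0, 0.0, 0.7, 0.02)
        fit = fit_stretched_exp(t, v)
        assert fit.beta == pytest.approx(0.7, rel=1e-4)
        assert fit.tau0 == pytest.approx(0.02, rel=1e-4)
        assert fit.residual_rms < 1e-6  # of unit dynamic range

    def test_monte_carlo_recovery_at_one_percent_noise(self):
        betas, taus = [], []
        for s in range(30):
            ts = simulate_flux_traces(beta_true=0.6, tau0_true=0.02,
                                      noise_sd=9.0, seed=500 + s)
            plus, minus = ts.pair("sample")
            t, norm = normalize_flux((ts.time, plus), (ts.time, minus))
            fit = fit_stretched_exp(t, norm)
            betas.append(fit.beta)
            taus.append(fit.tau0)
        assert abs(np.mean(betas) - 0.6) < 0.05
        assert abs(np.mean(taus) - 0.02) < 0.002

    def test_window_needs_enough_samples(self):
        t = np.linspace(0, 0.2, 30)
        with pytest.raises(ValueError, match="20 samples"):
            fit_stretched_exp(t, np.exp(-t / 0.05))

    def test_rising_trace_rejected(self):
        t = np.arange(0.0, 0.12, 1 / 5000.0)
        with pytest.raises(ValueError, match="not decaying"):
            fit_stretched_exp(t, t.copy())


class TestQuenchRate:
    def test_beta_one_rate_is_reciprocal_tau(self):
        t = np.arange(0.0, 0.12, 1 / 5000.0)
        fit = fit_stretched_exp(t, stretched_exp(t, 1.0, 0.0, 1.0, 0.01))
        ks = quench_rate_curve(fit, np.array([0.002, 0.01, 0.05]))
        assert np.allclose(ks, 100.0, rtol=1e-6)

    def test_half_beta_closed_form_value(self):
        # beta=0.5, tau0=10 ms, t*=2 ms -> (0.5/10ms) * 0.2^-0.5 ~ 0.1118/ms
        t = np.arange(0.0, 0.12, 1 / 5000.0)
        fit = fit_stretched_exp(t, stretched_exp(t, 1.0, 0.0, 0.5, 0.01))
        res = quench_rate(fit, t_star=0.002)
        assert res.k == pytest.approx(111.80, rel=1e-3)

    def test_rate_matches_numerical_differentiation(self):
        # k(t*) vs central difference of -ln of the normalized fitted curve
        t = np.arange(0.0, 0.12, 1 / 5000.0)
        fit = fit_stretched_exp(t, stretched_exp(t, 1.0, 0.0, 0.7, 0.02))
        t_star, h = 0.002, 1e-7
        def neg_log_norm(x):
            return np.power(x / fit.tau0, fit.beta)
        numeric = (neg_log_norm(t_star + h) - neg_log_norm(t_star - h)) / (2 * h)
        assert quench_rate(fit, t_star).k == pytest.approx(numeric, rel=1e-3)

    def test_rate_scales_as_two_to_beta_when_tau0_halved(self):
        # closed form: tau0 -> tau0/2 multiplies k(t*) by exactly 2^beta,
        # sublinear for a dispersed ensemble (beta < 1)
        t = np.arange(0.0, 0.12, 1 / 5000.0)
        f1 = fit_stretched_exp(t, stretched_exp(t, 1.0, 0.0, 0.6, 0.02))
        f2 = fit_stretched_exp(t, stretched_exp(t, 1.0, 0.0, 0.6, 0.01))
        k1 = quench_rate(f1, 0.002).k
        k2 = quench_rate(f2, 0.002).k
        assert k2 > k1  # monotone in 1/tau0
        assert k2 / k1 == pytest.approx(2.0 ** 0.6, rel=1e-3)

    def test_invalid_t_star_rejected_and_subsample_flagged(self):
        t = np.arange(0.0, 0.12, 1 / 5000.0)
        fit = fit_stretched_exp(t, stretched_exp(t, 1.0, 0.0, 0.7, 0.02))
        with pytest.raises(ValueError):
            quench_rate(fit, t_star=0.0)
        res = quench_rate(fit, t_star=1e-5, dt=2e-4)
        assert "t_star_below_sampling_interval" in res.flags


class TestConcentrationResponse:
    def _result(self, cond, k_scale, il=None, conc=None):
        # scaling tau0 by k_scale^(-1/beta) scales k(t*) by exactly k_scale
        t = np.arange(0.0, 0.12, 1 / 5000.0)
        tau0 = 0.02 * k_scale ** (-1.0 / 0.7)
        fit = fit_stretched_exp(t, stretched_exp(t, 1.0, 0.0, 0.7, tau0))
        return quench_rate(fit, condition=cond, il=il, concentration=conc)

    def test_known_scalings_reproduced(self):
        results = [self._result("control", 1.0),
                   self._result("a", 0.8, il="C8mim", conc=1e-3),
                   self._result("b", 0.5, il="C10mim", conc=1e-3)]
        df = concentration_response(results, control="control")
        by = dict(zip(df.condition, df.k_ratio))
        assert by["control"] == 1.0
        assert by["a"] == pytest.approx(0.8, rel=1e-3)
        assert by["b"] == pytest.approx(0.5, rel=1e-3)

    def test_ordered_by_chain_length_then_concentration(self):
        results = [self._result("c10", 0.5, il="C10mim", conc=1e-4),
                   self._result("control", 1.0),
                   self._result("c4hi", 0.9, il="C4mim", conc=1e-2),
                   self._result("c4lo", 0.95, il="C4mim", conc=1e-3)]
        df = concentration_response(results, control="control")
        assert list(df.condition) == ["control", "c4lo", "c4hi", "c10"]

    def test_empty_and_missing_control_rejected(self):
        with pytest.raises(ValueError):
            concentration_response([], control="control")
        with pytest.raises(ValueError, match="control"):
            concentration_response([self._result("a", 1.0)], control="x")


class TestQualityFlags:
    def test_clean_decay_unflagged(self):
        t = np.arange(0.0, 0.12, 1 / 5000.0)
        assert quality_flags(t, stretched_exp(t, 1.0, 0.0, 0.7, 0.02)) == []

    def test_rising_trace_flagged(self):
        t = np.arange(0.0, 0.12, 1 / 5000.0)
        v = np.concatenate([np.linspace(1, 0.5, t.size // 2),
                            np.linspace(0.5, 1.0, t.size - t.size // 2)])
        assert "non_monotonic_decay" in quality_flags(t, v)

    def test_pure_noise_flagged_low_dynamic_range(self):
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 0.12, 1 / 5000.0)
        flags = quality_flags(t, 1.0 + rng.normal(0, 0.05, t.size))
        assert "low_dynamic_range" in flags
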