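"""Turbidity observation, derivative analysis, sigmoid descriptors, and
rate-constant estimation by multi-start nonlinear least squares."""

import numpy as np
import pytest

import fibrilkin as fk
from fibrilkin.errors import DomainError, NotSaturatedError


def logistic_curve(t0=200.0, r=0.03, amp=1.0, baseline=0.05, dt=10.0, t_max=1000.0):
    t = np.arange(0.0, t_max + dt, dt)
    return fk.KineticCurve(t, baseline + amp / (1.0 + np.exp(-r * (t - t0))),
                           label="logistic")


class TestObserveTurbidity:
    def test_linear_readout(self, traj_1mg):
        obs = fk.ObservationModel(alpha=9.7, baseline=0.02)
        od = fk.observe_turbidity(traj_1mg, obs)
        assert od.values[0] == pytest.approx(0.02)  # B(0) = 0
        np.testing.assert_allclose(od.values, 0.02 + 9.7 * traj_1mg.B)

    def test_zero_alpha_is_flat_and_scaling_is_linear(self, traj_1mg):
        flat = fk.observe_turbidity(traj_1mg, fk.ObservationModel(0.0, 0.1))
        assert np.all(flat.values == 0.1)
        od1 = fk.observe_turbidity(traj_1mg, fk.ObservationModel(2.0, 0.1))
        od2 = fk.observe_turbidity(traj_1mg, fk.ObservationModel(4.0, 0.1))
        np.testing.assert_allclose(od2.values - 0.1, 2.0 * (od1.values - 0.1))


class TestSmoothDerivative:
    def test_linear_ramp_recovers_slope(self):
        t = np.arange(0.0, 500.0, 10.0)
        curve = fk.KineticCurve(t, 0.3 + 0.002 * t)
        d = fk.smooth_derivative(curve)
        np.testing.assert_allclose(d.values, 0.002, atol=1e-12)

    def test_constant_curve_zero_derivative(self):
        curve = fk.KineticCurve(np.arange(0.0, 200.0, 10.0), np.full(20, 0.7))
        assert np.allclose(fk.smooth_derivative(curve).values, 0.0, atol=1e-14)

    def test_logistic_peak_at_midpoint(self):
        curve = logistic_curve(t0=400.0, dt=10.0, t_max=900.0)
        d = fk.smooth_derivative(curve)
        t_peak = curve.times[np.argmax(d.values)]
        assert abs(t_peak - 400.0) <= 10.0  # within one sample

    def test_nonuniform_grid_asks_for_resampling(self):
        curve = fk.KineticCurve(np.array([0.0, 1.0, 3.0, 7.0, 8.0, 9.0, 10.0]),
                                np.zeros(7))
        with pytest.raises(DomainError, match="resample"):
            fk.smooth_derivative(curve)

    def test_window_validation(self):
        curve = logistic_curve()
        with pytest.raises(DomainError):
            fk.smooth_derivative(curve, window=4)
        with pytest.raises(DomainError):
            fk.smooth_derivative(curve, window=3, polyorder=3)


class TestInitialGuess:
    def test_round_trip_guesses_within_factor_five(self, clean_curve_1mg, preset_1mg):
        rates, a0 = preset_1mg
        g_rates, g_obs = fk.initial_guess_from_derivative(clean_curve_1mg, a0)
        for got, true in [(g_rates.k1, rates.k1), (g_rates.k2, rates.k2),
                          (g_obs.alpha, 9.7)]:
            assert true / 5 < got < true * 5

    def test_flat_curve_not_saturated(self):
        curve = fk.KineticCurve(np.arange(0.0, 500.0, 10.0), np.zeros(50))
        with pytest.raises(NotSaturatedError):
            fk.initial_guess_from_derivative(curve, 0.1)

    def test_rising_unsaturated_curve_rejected(self, preset_1mg):
        rates, a0 = preset_1mg
        obs = fk.ObservationModel(alpha=9.7, baseline=0.02)
        cfg = fk.GeneratorConfig(noise_sd=0.0)
        # stop at ~t50: no plateau yet
        curve = fk.gen_turbidity(rates, a0, obs, t_max=450.0, cfg=cfg)
        with pytest.raises(NotSaturatedError):
            fk.initial_guess_from_derivative(curve, a0)

    def test_initial_slope_matches_small_t_expansion(self, preset_1mg):
        # dOD/dt(0) = alpha * k1 * A0 when sampled densely
        rates, a0 = preset_1mg
        obs = fk.ObservationModel(alpha=9.7, baseline=0.0)
        traj = fk.integrate_assembly(rates, a0, np.arange(0.0, 51.0, 1.0))
        od = fk.observe_turbidity(traj, obs)
        d0 = fk.smooth_derivative(od).values[0]
        assert d0 == pytest.approx(9.7 * rates.k1 * a0, rel=0.05)


class TestSigmoidDescriptors:
    def test_logistic_t50_at_midpoint(self):
        curve = logistic_curve(t0=300.0, r=0.05, t_max=1200.0)
        desc = fk.sigmoid_descriptors(curve)
        assert abs(desc["t50"] - 300.0) <= 10.0
        assert desc["plateau"] == pytest.approx(1.05, rel=1e-3)
        # logistic v_max = r*amp/4
        assert desc["v_max"] == pytest.approx(0.05 / 4, rel=0.05)
        assert desc["lag_time"] < desc["t50"]

    def test_time_scaling(self):
        slow = logistic_curve(t0=400.0, r=0.02, dt=10.0, t_max=2000.0)
        fast = fk.KineticCurve(slow.times / 2.0, slow.values)
        d_slow = fk.sigmoid_descriptors(slow)
        d_fast = fk.sigmoid_descriptors(fast)
        assert d_fast["t50"] == pytest.approx(d_slow["t50"] / 2.0, rel=0.02)
        assert d_fast["v_max"] == pytest.approx(d_slow["v_max"] * 2.0, rel=0.05)

    def test_preset_concentration_ordering_of_t50(self):
        # assembly accelerates with concentration: t50 smallest at 10 mg/ml
        t50 = {}
        for c in (1.0, 5.0, 10.0):
            rates = fk.RATE_PRESETS[c]
            a0 = fk.preset_a0_mM(c)
            obs = fk.ObservationModel(alpha=1.0 / a0, baseline=0.02)
            curve = fk.gen_turbidity(rates, a0, obs, cfg=fk.GeneratorConfig(noise_sd=0.0))
            t50[c] = fk.sigmoid_descriptors(curve)["t50"]
        assert t50[10.0] < t50[5.0] < t50[1.0]

    def test_descriptor_stability_under_noise(self, preset_1mg):
        rates, a0 = preset_1mg
        obs = fk.ObservationModel(alpha=9.7, baseline=0.02)
        ref = fk.sigmoid_descriptors(
            fk.gen_turbidity(rates, a0, obs, cfg=fk.GeneratorConfig(noise_sd=0.0)))
        shifts = []
        for seed in range(50):
            cfg = fk.GeneratorConfig(seed=seed, noise_sd=0.01)
            noisy = fk.gen_turbidity(rates, a0, obs, cfg=cfg)
            shifts.append(abs(fk.sigmoid_descriptors(noisy)["t50"] - ref["t50"]))
        assert np.median(shifts) < 2 * 10.0  # < 2 sample intervals


class TestFitKinetics:
    def test_seed_determinism(self, clean_curve_1mg, preset_1mg):
        _, a0 = preset_1mg
        r1 = fk.fit_kinetics(clean_curve_1mg, a0, n_starts=4, seed=42)
        r2 = fk.fit_kinetics(clean_curve_1mg, a0, n_starts=4, seed=42)
        assert r1.params == r2.params

    def test_residual_not_worse_than_initial_guess(self, clean_curve_1mg, preset_1mg):
        _, a0 = preset_1mg
        model = fk.TurbidityKineticsModel(clean_curve_1mg, a0)
        g_rates, g_obs = fk.initial_guess_from_derivative(clean_curve_1mg, a0)
        guess_norm = float(np.linalg.norm(
            model.predict(g_rates, g_obs) - clean_curve_1mg.values))
        res = model.fit(n_starts=4, seed=0)
        assert res.residual_norm <= guess_norm

    def test_noisy_recovery_of_k1(self, preset_1mg):
        # median relative error of k1 under 1%-of-plateau noise stays < 10%
        rates, a0 = preset_1mg
        obs = fk.ObservationModel(alpha=9.7, baseline=0.02)
        errs = []
        for seed in range(20):
            cfg = fk.GeneratorConfig(seed=seed, noise_sd=0.01)
            curve = fk.gen_turbidity(rates, a0, obs, cfg=cfg)
            res = fk.fit_kinetics(curve, a0, n_starts=2, seed=seed)
            errs.append(abs(res.rates.k1 - rates.k1) / rates.k1)
        assert np.median(errs) < 0.10

    def test_fit_reports_standard_errors_and_summary(self, clean_curve_1mg, preset_1mg):
        _, a0 = preset_1mg
        res = fk.fit_kinetics(clean_curve_1mg, a0, n_starts=2, seed=0)
        assert res.converged
        assert set(res.bse) == {"k1", "k2", "k3", "alpha", "baseline"}
        text = res.summary()
        assert "k1" in text and "residual norm" in text

    def test_from_dataframe_constructor(self, clean_curve_1mg, preset_1mg):
        _, a0 = preset_1mg
        df = clean_curve_1mg.to_dataframe()
        model = fk.TurbidityKineticsModel.from_dataframe(df, a0_mM=a0)
        assert len(model.curve) == len(clean_curve_1mg)

    def test_short_curve_rejected(self):
        curve = fk.KineticCurve(np.arange(5) * 10.0, np.zeros(5))
        with pytest.raises(DomainError):
            fk.TurbidityKineticsModel(curve, 0.1)
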