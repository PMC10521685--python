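"""Deterministic three-reaction assembly model: right-hand side, solver,
closed form, derived mean length, and unit conversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fibrilkin as fk
from fibrilkin.errors import ConfigurationError, DomainError


rates_strategy = st.builds(
    fk.RateConstants,
    k1=st.floats(1e-5, 1e-1),
    k2=st.floats(1e-4, 1.0),
    k3=st.floats(0.0, 1.0),
)


class TestReactionRHS:
    def test_initial_state_only_nucleation_acts(self):
        # with no fibrils present the only flux is nucleation
        rates = fk.RateConstants(2e-3, 5e-2, 1e-2)
        dA, dB, dN = fk.reaction_rhs(fk.AssemblyState(0.5, 0.0, 0.0), rates)
        assert dA == pytest.approx(-2e-3 * 0.5)
        assert dB == -dA
        assert dN == pytest.approx(2e-3 * 0.5)

    def test_no_nucleation_no_fibrils_is_stationary(self):
        rates = fk.RateConstants(0.0, 5e-2, 1e-2)
        d = fk.reaction_rhs(fk.AssemblyState(0.5, 0.0, 0.0), rates)
        assert np.all(d == 0.0)

    def test_end_catalytic_hand_value(self):
        # dA/dt = -(k1*A + k2*A*N) evaluated by hand
        rates = fk.RateConstants(1e-3, 1e-2, 0.0)
        d = fk.reaction_rhs((0.1, 0.05, 0.01), rates, "end-catalytic")
        assert d[0] == pytest.approx(-1.1e-4, rel=1e-12)

    def test_mass_variant_uses_fibrillar_mass(self):
        rates = fk.RateConstants(0.0, 1e-2, 0.0)
        d = fk.reaction_rhs((0.1, 0.05, 0.01), rates, "mass-autocatalytic")
        assert d[1] == pytest.approx(1e-2 * 0.1 * 0.05, rel=1e-12)

    def test_conservation_is_exact(self):
        rates = fk.RateConstants(1e-3, 1e-2, 1e-3)
        d = fk.reaction_rhs((0.3, 0.2, 0.05), rates)
        assert d[0] + d[1] == 0.0

    def test_unknown_variant_rejected(self):
        rates = fk.RateConstants(1e-3, 1e-2, 1e-3)
        with pytest.raises(ConfigurationError):
            fk.reaction_rhs((0.1, 0.0, 0.0), rates, "secondary-nucleation")

    def test_negative_concentration_rejected(self):
        rates = fk.RateConstants(1e-3, 1e-2, 1e-3)
        with pytest.raises(DomainError):
            fk.reaction_rhs((-0.1, 0.0, 0.0), rates)


class TestIntegrateAssembly:
    def test_no_nucleation_means_no_assembly(self):
        rates = fk.RateConstants(0.0, 1e-2, 1e-3)
        traj = fk.integrate_assembly(rates, 0.5, np.arange(0.0, 1000.0, 10.0))
        assert np.allclose(traj.A, 0.5, atol=1e-10)
        assert np.allclose(traj.B, 0.0, atol=1e-10)

    @pytest.mark.parametrize("variant", fk.VARIANTS)
    def test_monotone_and_conserved(self, variant):
        rates = fk.RateConstants(2e-3, 8e-3, 3e-3)
        traj = fk.integrate_assembly(rates, 0.1, np.arange(0.0, 5000.0, 10.0), variant)
        assert np.all(np.diff(traj.A) <= 1e-12)
        assert np.all(np.diff(traj.B) >= -1e-12)
        assert np.max(np.abs(traj.A + traj.B - 0.1)) <= 1e-6 * 0.1

    def test_saturating_conversion_at_1mg_preset(self, preset_1mg):
        # B/A0 runs monotonically from 0 to 1; at this preset nucleation
        # outpaces autocatalysis (k2*A0 < k1), so the curve is concave
        # throughout rather than sigmoidal
        rates, a0 = preset_1mg
        traj = fk.integrate_assembly(rates, a0, np.arange(0.0, 8000.0, 10.0))
        frac = traj.converted_fraction
        assert frac[0] == 0.0
        assert frac[-1] > 0.99
        assert np.all(np.diff(frac) >= 0)

    def test_single_inflection_at_5mg_preset(self):
        # at 5 mg/ml autocatalysis dominates (k2*A0 > k1): B/A0 is
        # sigmoidal with exactly one inflection (one sign change of the
        # second difference)
        rates = fk.RATE_PRESETS[5.0]
        a0 = fk.preset_a0_mM(5.0)
        traj = fk.integrate_assembly(rates, a0, np.arange(0.0, 3000.0, 5.0))
        frac = traj.converted_fraction
        d2 = np.diff(frac, n=2)
        signs = np.sign(d2[np.abs(d2) > 1e-12])
        assert np.sum(np.diff(signs) != 0) == 1

    def test_n_never_exceeds_b(self, traj_1mg):
        assert np.all(traj_1mg.N <= traj_1mg.B + 1e-12)

    def test_initial_b_slope_is_k1_a0(self, preset_1mg):
        rates, a0 = preset_1mg
        t = np.array([0.0, 0.01])
        for variant in fk.VARIANTS:
            traj = fk.integrate_assembly(rates, a0, t, variant)
            slope = traj.B[1] / 0.01
            assert slope == pytest.approx(rates.k1 * a0, rel=1e-3)

    def test_bad_grid_rejected(self):
        rates = fk.RateConstants(1e-3, 1e-2, 1e-3)
        with pytest.raises(DomainError):
            fk.integrate_assembly(rates, 0.1, [10.0, 20.0])  # must start at 0
        with pytest.raises(DomainError):
            fk.integrate_assembly(rates, -0.1, [0.0, 10.0])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(rates=rates_strategy, A0=st.floats(0.01, 2.0))
    def test_conservation_property(self, rates, A0):
        traj = fk.integrate_assembly(rates, A0, np.linspace(0.0, 500.0, 60))
        assert np.max(np.abs(traj.A + traj.B - A0)) <= 1e-6 * A0


class TestFinkeWatzkyClosedForm:
    def test_identity_at_t0(self):
        assert fk.finke_watzky_closed_form(1e-3, 1e-2, 0.5, 0.0) == pytest.approx(0.5)

    def test_monotone_decay_to_zero(self):
        t = np.linspace(0.0, 1e6, 200)
        A = fk.finke_watzky_closed_form(1e-3, 1e-2, 0.5, t)
        assert np.all(np.diff(A) <= 0)
        assert A[-1] < 1e-6

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(k1=st.floats(1e-4, 1e-2), k2=st.floats(1e-3, 1e-1), A0=st.floats(0.05, 1.0))
    def test_matches_ode_in_mass_limit(self, k1, k2, A0):
        # the closed form is the k3 = 0, mass-autocatalytic solution
        rates = fk.RateConstants(k1, k2, 0.0)
        t50 = fk.time_to_half_conversion(rates, A0, "mass-autocatalytic")
        t = np.linspace(0.0, 10.0 * t50, 120)
        traj = fk.integrate_assembly(rates, A0, t, "mass-autocatalytic")
        A_cf = fk.finke_watzky_closed_form(k1, k2, A0, t)
        assert np.max(np.abs(traj.A - A_cf)) <= 1e-6 * A0

    def test_undefined_limits_raise_not_fallback(self):
        with pytest.raises(DomainError):
            fk.finke_watzky_closed_form(1e-3, 0.0, 0.5, 1.0)
        with pytest.raises(DomainError):
            fk.finke_watzky_closed_form(1e-3, 1e-2, 0.0, 1.0)


class TestMeanLength:
    def test_nucleation_only_gives_unit_length(self):
        rates = fk.RateConstants(1e-2, 0.0, 0.0)
        traj = fk.integrate_assembly(rates, 0.1, np.arange(0.0, 500.0, 10.0))
        L = fk.mean_length_trajectory(traj)
        assert np.isnan(L.values[0])  # no fibrils yet at t = 0
        assert np.allclose(L.values[1:], 1.0, atol=1e-6)

    def test_joining_increases_final_length(self, preset_1mg):
        rates, a0 = preset_1mg
        t = np.arange(0.0, 5000.0, 10.0)
        base = fk.mean_length_trajectory(fk.integrate_assembly(rates, a0, t))
        doubled = fk.mean_length_trajectory(fk.integrate_assembly(
            fk.RateConstants(rates.k1, rates.k2, 2.0 * rates.k3), a0, t))
        assert doubled.values[-1] > base.values[-1]

    def test_undefined_at_degenerate_start_is_nan_not_error(self, traj_1mg):
        L = fk.mean_length_trajectory(traj_1mg)
        assert np.isnan(L.values[0])


class TestUnitConversion:
    @pytest.mark.parametrize(
        "c,mw,expected",
        [(0.0, 9700.0, 0.0), (1.0, 9700.0, 0.10309278), (10.0, 9700.0, 1.0309278)],
    )
    def test_mg_per_ml_to_mM(self, c, mw, expected):
        assert fk.mg_per_ml_to_mM(c, mw) == pytest.approx(expected, rel=1e-6)

    def test_nonpositive_mw_rejected(self):
        with pytest.raises(DomainError):
            fk.mg_per_ml_to_mM(1.0, 0.0)
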