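"""Unit and property tests of the equilibrium gating models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kvtherm.thermo import (AllostericParams, StateDistribution, ThermoTransition,
                            boltzmann_open_fraction, combined_probability,
                            csi_availability, gv_curve, model_q10_profile,
                            open_probability, qv_curve, state_distribution,
                            two_state_open_probability)
from kvtherm.curves import BoltzmannFit
from kvtherm.pipeline import fit_boltzmann

from conftest import brute_force_state_probs


class TestBoltzmannOpenFraction:
    @pytest.mark.parametrize("v,v_half,q,temp,expected,atol", [
        (0.0, 0.0, 3.0, 24.0, 0.5, 0),           # midpoint by construction
        (-54.2, -54.2, 5.1, 11.0, 0.5, 0),
        (25.61, 0.0, 1.0, 24.0, 0.7311, 2e-4),   # exponent −1: 1/(1+e⁻¹)
        (150.0, 114.9, 0.76, 24.0, 0.7392, 5e-4),  # shallow TRP-type curve
    ])
    def test_values(self, v, v_half, q, temp, expected, atol):
        assert boltzmann_open_fraction(v, v_half, q, temp) == pytest.approx(
            expected, abs=max(atol, 1e-12))

    def test_monotone_increasing_for_positive_charge(self):
        v = np.linspace(-150, 150, 301)
        po = boltzmann_open_fraction(v, -20.0, 2.5, 24.0)
        assert np.all(np.diff(po) > 0)

    @pytest.mark.parametrize("bad", [np.nan, np.inf])
    def test_nonfinite_rejected(self, bad):
        with pytest.raises(ValueError):
            boltzmann_open_fraction(bad, 0.0, 1.0, 24.0)

    def test_subzero_kelvin_rejected(self):
        with pytest.raises(ValueError):
            boltzmann_open_fraction(0.0, 0.0, 1.0, -300.0)


class TestTwoStateOpenProbability:
    def test_half_at_compensation_temperature(self):
        # ΔG = 0 when T = ΔH/ΔS
        dH, dS = 418e3, 1340.0
        t_c = dH / dS - 273.15
        tr = ThermoTransition(dH, dS, 0.0)
        assert two_state_open_probability(tr, 0.0, t_c) == pytest.approx(0.5, abs=1e-12)

    def test_pure_thermal_form(self):
        # ΔG = 18.48 kJ/mol at 25 °C → P ≈ K = e^(−ΔG/RT) ≈ 5.8e−4
        tr = ThermoTransition(418e3, 1340.0, 0.0)
        p = two_state_open_probability(tr, 0.0, 25.0)
        assert p == pytest.approx(5.78e-4, rel=2e-3)

    def test_heat_deactivation_regime(self):
        # negative ΔH and ΔS: probability falls with temperature
        tr = ThermoTransition(-418e3, -1340.0, 0.0)
        temps = np.linspace(10.0, 50.0, 41)
        p = two_state_open_probability(tr, 0.0, temps)
        assert np.all(np.diff(p) < 0)

    def test_temperature_monotonicity_follows_enthalpy_sign(self, rng):
        """dP/dT > 0 iff the apparent enthalpy is positive (finite
        differences at 1000 random points). At zero gating charge the
        apparent enthalpy is ΔH itself; at fixed nonzero charge the
        electrical work shifts it to ΔH − z·F·V."""
        from kvtherm.constants import F
        for _ in range(1000):
            dH = rng.uniform(-600e3, 600e3)
            dS = rng.uniform(-2000, 2000)
            z = rng.uniform(-2, 6) if rng.uniform() < 0.5 else 0.0
            v = rng.uniform(-200, 200)
            t = rng.uniform(0.0, 60.0)
            tr = ThermoTransition(dH, dS, z)
            dp = (two_state_open_probability(tr, v, t + 1e-3)
                  - two_state_open_probability(tr, v, t - 1e-3))
            dH_apparent = dH - z * F * v * 1e-3
            if abs(dH_apparent) > 1e3 and abs(dp) > 1e-300:
                assert (dp > 0) == (dH_apparent > 0)

    def test_reduces_to_boltzmann_curve(self):
        """A transition built from (v_half, q) reproduces the Boltzmann
        open fraction exactly at the construction temperature."""
        tr = ThermoTransition.from_boltzmann(-54.2, 5.1, 24.0)
        v = np.linspace(-120, 40, 33)
        np.testing.assert_allclose(
            two_state_open_probability(tr, v, 24.0),
            boltzmann_open_fraction(v, -54.2, 5.1, 24.0), rtol=1e-12)


class TestStateDistribution:
    def test_matches_brute_force_oracle(self, rng):
        """Log-space occupancies agree with direct long-double enumeration
        of the four weights on 10,000 random parameter draws."""
        for _ in range(10_000):
            params = AllostericParams(
                J=ThermoTransition(rng.uniform(-6e5, 6e5), rng.uniform(-2e3, 2e3),
                                   rng.uniform(-2, 8)),
                L=ThermoTransition(rng.uniform(-6e5, 6e5), rng.uniform(-2e3, 2e3),
                                   rng.uniform(-2, 8)),
                D=rng.uniform(0.0, 1e6),
            )
            v = rng.uniform(-200, 200)
            t = rng.uniform(0, 60)
            expected = brute_force_state_probs(params, v, t)
            got = params.state_probs(v, t)
            np.testing.assert_allclose(got, expected, rtol=1e-10, atol=1e-300)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        dH_j=st.floats(-6e5, 6e5), dS_j=st.floats(-2e3, 2e3),
        z_j=st.floats(0, 8), dH_l=st.floats(-6e5, 6e5),
        dS_l=st.floats(-2e3, 2e3), d=st.floats(0, 1e6),
        v=st.floats(-200, 200), t=st.floats(0, 60),
    )
    def test_normalization_property(self, dH_j, dS_j, z_j, dH_l, dS_l, d, v, t):
        """Occupancies are a probability distribution everywhere in the
        physiological parameter box."""
        params = AllostericParams(J=ThermoTransition(dH_j, dS_j, z_j),
                                  L=ThermoTransition(dH_l, dS_l, 0.0), D=d)
        dist = state_distribution(params, v, t)
        total = dist.pC + dist.pCp + dist.pO + dist.pOp
        assert abs(total - 1.0) <= 1e-12
        assert dist.open_probability == pytest.approx(
            open_probability(params, v, t), rel=1e-12, abs=1e-300)

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError):
            StateDistribution(0.5, 0.5, 0.5, -0.5)

    def test_negative_coupling_rejected(self):
        with pytest.raises(ValueError):
            AllostericParams(J=ThermoTransition(0, 0, 1),
                             L=ThermoTransition(0, 0, 0), D=-1.0)


class TestOpenProbability:
    def test_decoupling_identity(self):
        """D = 1 with a voltage-insensitive pore: Po = L/(1+L) at every
        voltage, independent of the sensor."""
        L = ThermoTransition(418e3, 1340.0, 0.0)
        params = AllostericParams(J=ThermoTransition(88e3, 373.8, 5.1), L=L, D=1.0)
        v = np.linspace(-200, 200, 401)
        po = open_probability(params, v, 25.0)
        l_val = float(L.equilibrium_constant(0.0, 25.0))
        assert np.max(np.abs(po - l_val / (1 + l_val))) < 1e-12

    def test_hyperpolarized_limit_empties_sensor_states(self):
        """J → 0 at deep hyperpolarization: occupancy collapses onto the
        sensor-down states C and O."""
        params = AllostericParams(J=ThermoTransition(88e3, 373.8, 5.1),
                                  L=ThermoTransition(418e3, 1340.0, 0.0), D=1e4)
        dist = state_distribution(params, -300.0, 25.0)
        assert dist.pC + dist.pO == pytest.approx(1.0, abs=1e-10)
        assert dist.pOp < 1e-10

    def test_obligatory_coupling_limit_fits_sensor_charge(self):
        """As D → ∞ with L small, Po(V) becomes a Boltzmann carrying the
        voltage-sensor charge."""
        params = AllostericParams(J=ThermoTransition(88e3, 373.8, 5.1),
                                  L=ThermoTransition(418e3, 1340.0, 0.0), D=1e6)
        gv = gv_curve(params, np.arange(-140.0, 20.0, 1.0), 24.0)
        fit = fit_boltzmann(gv)
        assert fit.converged
        assert fit.q == pytest.approx(5.1, rel=0.02)


class TestCurves:
    def test_qv_normalized_endpoints(self, shaker_params):
        v = np.arange(-120.0, 60.0, 2.0)
        qv = qv_curve(shaker_params, v, 24.0)
        assert qv[0] == 0.0 and qv[-1] == 1.0
        assert np.all((qv >= 0) & (qv <= 1))

    def test_obligatory_coupling_overlays_qv_and_gv(self):
        """With D huge and L ≪ 1, charge movement and opening are the same
        transition: normalized Q-V ≈ normalized G-V pointwise."""
        params = AllostericParams(J=ThermoTransition(88e3, 373.8, 5.1),
                                  L=ThermoTransition(418e3, 1340.0, 0.0), D=1e6)
        v = np.arange(-120.0, 40.0, 1.0)
        qv = qv_curve(params, v, 24.0)
        g = open_probability(params, v, 24.0)
        gv_norm = (g - g.min()) / (g.max() - g.min())
        assert np.max(np.abs(qv - gv_norm)) < 0.02

    def test_decoupled_gv_flat_while_qv_moves(self):
        """D = 1, voltage-insensitive pore: the G-V is flat in voltage but
        the Q-V still tracks the sensor."""
        params = AllostericParams(J=ThermoTransition(88e3, 373.8, 5.1),
                                  L=ThermoTransition(418e3, 1340.0, 0.0), D=1.0)
        v = np.arange(-150.0, 50.0, 1.0)
        po = open_probability(params, v, 24.0)
        qv = qv_curve(params, v, 24.0)
        assert np.ptp(po) < 1e-12
        assert np.all(np.diff(qv) >= 0) and qv[-1] == 1.0

    def test_empty_grid_rejected(self, shaker_params):
        with pytest.raises(ValueError):
            gv_curve(shaker_params, np.array([]), 24.0)


class TestModelQ10Profile:
    def test_exponent_arithmetic(self):
        """Po doubling over exactly 10 °C gives Q10 = 2."""
        # ΔH chosen so K doubles between 20 and 30 °C, in the low-Po regime
        t1, t2 = 20.0, 30.0
        R = 8.314
        dH = np.log(2.0) * R / (1 / 293.15 - 1 / 303.15)
        dS = (dH - 30e3) / 293.15  # keep K ≈ e^(-30e3/RT) ≪ 1
        tr = ThermoTransition(dH, dS, 0.0)
        prof = model_q10_profile(tr, t1, t2, np.array([0.0]))
        assert prof.q10[0] == pytest.approx(2.0, rel=1e-3)

    def test_trp_like_q10_high_at_all_voltages(self, trp_transition):
        prof = model_q10_profile(trp_transition, 36.6, 46.0,
                                 np.arange(-100.0, 151.0, 1.0))
        assert np.all(np.isfinite(prof.q10))
        assert np.nanmin(prof.q10) > 20

    def test_coupled_kv_foot_peak(self, shaker_params):
        """The strongly coupled channel shows one local Q10 maximum, in the
        foot of the G-V curve (channel barely open at the cool temperature)
        and hyperpolarized of the fitted midpoint."""
        v = np.arange(-100.0, 51.0, 1.0)
        prof = model_q10_profile(shaker_params, 22.4, 27.7, v)
        q = prof.q10
        interior_maxima = [i for i in range(1, q.size - 1)
                           if q[i] > q[i - 1] and q[i] > q[i + 1]]
        assert len(interior_maxima) == 1
        i_peak = interior_maxima[0]
        po_cool = open_probability(shaker_params, v[i_peak], 22.4)
        assert po_cool < 0.10
        fit = fit_boltzmann(gv_curve(shaker_params, v, 22.4))
        assert v[i_peak] < fit.v_half

    def test_underflow_reported_as_undefined(self):
        # sensor frozen shut: Po underflows at hyperpolarized voltages
        params = AllostericParams(J=ThermoTransition(88e3, 200.0, 12.0),
                                  L=ThermoTransition(418e3, 1000.0, 0.0), D=1e4)
        prof = model_q10_profile(params, 20.0, 30.0, np.arange(-400.0, -300.0, 10.0))
        assert not np.all(np.isfinite(prof.q10))

    def test_temperature_order_enforced(self, trp_transition):
        with pytest.raises(ValueError):
            model_q10_profile(trp_transition, 40.0, 30.0, np.arange(-10.0, 10.0, 1.0))


class TestCSI:
    def test_availability_is_decreasing(self):
        v = np.linspace(-150, 50, 201)
        avail = csi_availability(v, -60.0, 3.2, 24.0)
        assert np.all(np.diff(avail) < 0)
        assert csi_availability(-60.0, -60.0, 3.2, 24.0) == pytest.approx(0.5)

    def test_combined_probability_trivial_cases(self):
        v = np.arange(-100.0, 101.0, 1.0)
        act = BoltzmannFit(-50.0, 4.0, 1.0, 0.0, 24.0)
        csi = BoltzmannFit(-50.0, 4.0, 1.0, 0.0, 24.0)
        comb = combined_probability(act, csi, v, 24.0)
        # equal midpoints and charges: peak exactly at the shared midpoint, 0.25
        i = np.argmax(comb)
        assert v[i] == -50.0
        assert comb[i] == pytest.approx(0.25, abs=1e-9)

    def test_combined_peak_between_midpoints(self):
        """Activation rising near −48 mV against a steeper availability
        falling through −60 mV: the product peaks between the midpoints,
        at the voltage satisfying the stationarity condition."""
        act = BoltzmannFit(-47.75, 4.44, 1.0, 0.0, 24.0)
        csi = BoltzmannFit(-60.0, 3.2, 1.0, 0.0, 24.0)
        v = np.arange(-100.0, 51.0, 0.01)
        comb = combined_probability(act, csi, v, 24.0)
        v_peak = v[np.argmax(comb)]
        assert -60.0 < v_peak < -47.75
        # analytic stationarity: d/dV [ln act + ln avail] = 0
        from kvtherm.constants import F, R
        t_k = 297.15
        act_frac = boltzmann_open_fraction(v_peak, act.v_half, act.q, 24.0)
        avail = csi_availability(v_peak, csi.v_half, csi.q, 24.0)
        deriv = act.q * (1 - act_frac) - csi.q * (1 - avail)
        assert abs(deriv) < 1e-2  # in units of F/(R·T) per mV

    def test_combined_unimodal_spanning_midpoints(self):
        act = BoltzmannFit(-40.0, 5.0, 1.0, 0.0, 24.0)
        csi = BoltzmannFit(-65.0, 4.0, 1.0, 0.0, 24.0)
        v = np.arange(-120.0, 21.0, 0.5)
        comb = combined_probability(act, csi, v, 24.0)
        d = np.diff(comb)
        sign_changes = np.sum(np.diff(np.sign(d[np.abs(d) > 1e-15])) != 0)
        assert sign_changes <= 1
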