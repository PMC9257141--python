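"""Closed-form RC/MC transients, power bookkeeping, and the Euler integrator."""

import math
import warnings

import numpy as np
import pytest

from memneuro import (
    FULL_FRACTION,
    MemristorParams,
    ParameterError,
    SeriesCircuitParams,
    euler_transient,
    first_crossing,
    full_charge_time,
    mc_charge,
    mc_discharge,
    powers,
    rc_charge,
    rc_discharge,
)


def mc_params(phi0=0.3, mode="verbatim", V_C0=0.0, flux_scale=1e3):
    return SeriesCircuitParams(
        E=100.0,
        C=1e-6,
        R=None,
        memristor=MemristorParams(mode=mode, flux_scale=flux_scale),
        phi0=phi0,
        V_C0=V_C0,
    )


class TestRcCharge:
    def test_values_at_zero_tau_and_5tau(self, rc_circuit, fine_grid):
        tr = rc_charge(rc_circuit, fine_grid)
        tau = rc_circuit.tau
        assert tr.V_C[0] == 0.0
        assert tr.V_leak[0] == 100.0
        assert tr.I[0] == pytest.approx(100.0)  # E/R in μA
        v_tau = np.interp(tau, tr.t, tr.V_C)
        assert v_tau == pytest.approx(100 * (1 - math.exp(-1)), rel=1e-6)
        assert round(v_tau) == 63
        assert round(float(np.interp(tau, tr.t, tr.V_leak))) == 37
        assert np.interp(5 * tau, tr.t, tr.V_C) == pytest.approx(
            100 * (1 - math.exp(-5)), rel=1e-6
        )

    def test_kvl_charge_and_q_cv(self, rc_circuit, fine_grid):
        tr = rc_charge(rc_circuit, fine_grid)
        np.testing.assert_allclose(tr.V_C + tr.V_leak, 100.0, rtol=1e-12)
        np.testing.assert_allclose(tr.Q, rc_circuit.C * tr.V_C * 1e-3, rtol=1e-12)

    def test_charging_requires_uncharged_start(self, rc_circuit):
        with pytest.raises(ParameterError):
            rc_charge(
                SeriesCircuitParams(E=100, C=1e-6, R=1e3, V_C0=50.0),
                np.linspace(0, 5, 10),
            )


class TestRcDischarge:
    def test_exponential_decay_from_initial(self, fine_grid):
        p = SeriesCircuitParams(E=100, C=1e-6, R=1e3, V_C0=100.0)
        tr = rc_discharge(p, fine_grid)
        assert tr.V_C[0] == 100.0
        assert np.interp(p.tau, tr.t, tr.V_C) == pytest.approx(
            100 * math.exp(-1), rel=1e-6
        )
        np.testing.assert_allclose(tr.V_leak, -tr.V_C, rtol=1e-12)
        np.testing.assert_allclose(
            tr.Q, p.C * 100e-3 * np.exp(-tr.t / p.tau), rtol=1e-9
        )

    def test_leak_dissipates_half_cv_squared(self):
        """∫P_leak over ≥10τ equals the stored energy ½·C·V0²."""
        p = SeriesCircuitParams(E=100, C=1e-6, R=1e3, V_C0=100.0)
        t = np.arange(0.0, 15 * p.tau, p.tau / 2000)
        tr = rc_discharge(p, t)
        dissipated = np.trapezoid(tr.P_leak, t * 1e-3)
        stored = 0.5 * p.C * (100e-3) ** 2
        assert dissipated == pytest.approx(stored, rel=1e-3)

    def test_discharge_powers_balance(self, fine_grid):
        p = SeriesCircuitParams(E=100, C=1e-6, R=1e3, V_C0=100.0)
        tr = rc_discharge(p, fine_grid)
        np.testing.assert_allclose(tr.P_C + tr.P_leak, 0.0, atol=1e-18)


class TestPowers:
    def test_charging_power_split(self, rc_circuit, fine_grid):
        tr = powers(rc_charge(rc_circuit, fine_grid), E=rc_circuit.E)
        assert tr.P_C[0] == 0.0  # V_C = 0 at t = 0
        assert tr.P_E[0] == pytest.approx(1e-5)  # E²/R = (0.1 V)²/1000 Ω
        np.testing.assert_allclose(tr.P_E, tr.P_C + tr.P_leak, rtol=1e-12)

    def test_full_charge_energy_conservation(self, rc_circuit):
        """Source energy C·E² splits evenly: ½CE² stored, ½CE² dissipated."""
        tau = rc_circuit.tau
        t = np.arange(0.0, 20 * tau, tau / 2000)
        tr = rc_charge(rc_circuit, t)
        t_s = t * 1e-3
        E_src = np.trapezoid(tr.P_E, t_s)
        E_cap = np.trapezoid(tr.P_C, t_s)
        E_leak = np.trapezoid(tr.P_leak, t_s)
        CE2 = rc_circuit.C * (0.1) ** 2
        assert E_src == pytest.approx(CE2, rel=1e-3)
        assert E_cap == pytest.approx(CE2 / 2, rel=1e-3)
        assert E_leak == pytest.approx(CE2 / 2, rel=1e-3)
        assert E_src == pytest.approx(E_cap + E_leak, rel=1e-12)


class TestMcFrozen:
    def test_low_state_time_constant(self):
        """M = 100 Ω, C = 10⁻⁶ F: τ = 0.1 ms, 63.2% of E reached there."""
        p = mc_params()
        assert p.tau == pytest.approx(0.1)
        t = np.arange(0.0, 1.0, 1e-4)
        tr = mc_charge(p, t)
        v63 = (1 - math.exp(-1)) * 100.0
        assert first_crossing(tr.t, tr.V_C, v63) == pytest.approx(0.1, rel=1e-6)

    def test_high_state_time_constant(self):
        p = mc_params(phi0=-1.0)
        assert p.tau == pytest.approx(20.0)  # 20000 Ω · 10⁻⁶ F

    def test_full_discharge_in_half_millisecond(self):
        p = mc_params(V_C0=100.0)
        t = np.arange(0.0, 1.0, 1e-5)
        tr = mc_discharge(p, t)
        t_full = first_crossing(tr.t, tr.V_C, 100 * math.exp(-5), rising=False)
        assert t_full == pytest.approx(0.5, rel=1e-4)

    def test_frozen_matches_rc_with_R_eq_M(self):
        t = np.linspace(0, 0.5, 500)
        tr_mc = mc_charge(mc_params(), t)
        tr_rc = rc_charge(SeriesCircuitParams(E=100, C=1e-6, R=100.0), t)
        np.testing.assert_allclose(tr_mc.V_C, tr_rc.V_C, rtol=1e-12)

    def test_requires_memristor_leak(self, rc_circuit):
        with pytest.raises(ParameterError):
            mc_charge(rc_circuit, np.linspace(0, 1, 10))


class TestMcCoupled:
    def test_trace_invariants_each_step(self):
        p = mc_params(phi0=0.0, mode="reconciled")
        t = np.arange(0.0, 50.0, 0.01)
        tr = mc_charge(p, t, mode="coupled")
        np.testing.assert_allclose(tr.V_C + tr.V_leak, 100.0, atol=1e-9)
        np.testing.assert_allclose(tr.I, tr.V_leak * 1e3 / tr.M, rtol=1e-12)

    def test_coupled_charges_no_slower_than_rc_at_initial_M(self):
        """From M(0)=10⁴ Ω the coupled memristor only speeds charging up."""
        p = mc_params(phi0=0.0, mode="reconciled")
        t = np.arange(0.0, 100.0, 0.005)
        tr_mc = mc_charge(p, t, mode="coupled")
        tr_rc = euler_transient(
            SeriesCircuitParams(E=100, C=1e-6, R=1e4), dt=0.005, T=100.0
        )
        v63 = (1 - math.exp(-1)) * 100.0
        t_mc = first_crossing(tr_mc.t, tr_mc.V_C, v63)
        t_rc = first_crossing(tr_rc.t, tr_rc.V_C, v63)
        assert t_mc <= t_rc

    def test_zero_drive_discharge_decays_monotonically(self):
        p = mc_params(phi0=0.0, mode="reconciled", V_C0=100.0)
        tr = euler_transient(p, dt=0.01, T=100.0, direction="discharge")
        assert np.all(np.diff(tr.V_C) <= 1e-12)
        assert tr.V_C[-1] < 1.0


class TestEuler:
    def test_single_step_from_zero(self, rc_circuit):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tr = euler_transient(rc_circuit, dt=0.5, T=1.0)
        # V(Δt) = E·Δt/τ from the corrected recurrence
        assert tr.V_C[1] == pytest.approx(100.0 * 0.5 / rc_circuit.tau)

    @pytest.mark.parametrize("direction", ["charge", "discharge"])
    def test_order_one_convergence(self, direction):
        """Sup-norm error vs the closed form halves (±20%) when dt halves."""
        V0 = 0.0 if direction == "charge" else 100.0
        p = SeriesCircuitParams(E=100, C=1e-6, R=1e3, V_C0=V0)
        errs = {}
        for dt in (p.tau / 100, p.tau / 200):
            tr = euler_transient(p, dt=dt, T=5 * p.tau, direction=direction)
            if direction == "charge":
                exact = 100 * (1 - np.exp(-tr.t / p.tau))
            else:
                exact = 100 * np.exp(-tr.t / p.tau)
            errs[dt] = np.max(np.abs(tr.V_C - exact))
        ratio = errs[p.tau / 100] / errs[p.tau / 200]
        assert 1.6 <= ratio <= 2.4

    def test_sub_percent_accuracy_at_tau_over_1000(self, rc_circuit):
        tr = euler_transient(rc_circuit, dt=rc_circuit.tau / 1000, T=5 * rc_circuit.tau)
        exact = 100 * (1 - np.exp(-tr.t / rc_circuit.tau))
        assert np.max(np.abs(tr.V_C - exact)) < 0.01 * 100

    def test_instability_guard(self, rc_circuit):
        with pytest.raises(ParameterError):
            euler_transient(rc_circuit, dt=2.5 * rc_circuit.tau, T=10.0)
        with pytest.warns(UserWarning):
            euler_transient(rc_circuit, dt=rc_circuit.tau / 5, T=5.0)

    def test_verbatim_sign_diverges_from_supply(self, rc_circuit):
        """The sign-flawed published recurrence runs away from E instead of toward it."""
        tr = euler_transient(rc_circuit, dt=rc_circuit.tau / 1000, T=2.0, verbatim_sign=True)
        assert tr.V_C[-1] < 0  # moves away from E = 100 mV
        assert abs(tr.V_C[-1] - 100.0) > 100.0


class TestFullChargeTime:
    def test_rc_five_tau_criterion(self, rc_circuit):
        assert full_charge_time(rc_circuit, 1 - math.exp(-5)) == pytest.approx(5.0)
        assert FULL_FRACTION == pytest.approx(1 - math.exp(-5))

    def test_mc_low_state(self):
        assert full_charge_time(mc_params(), 1 - math.exp(-5)) == pytest.approx(0.5)

    def test_half_charge_is_tau_ln2(self, rc_circuit):
        assert full_charge_time(rc_circuit, 0.5) == pytest.approx(math.log(2))

    def test_threshold_domain(self, rc_circuit):
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ParameterError):
                full_charge_time(rc_circuit, bad)
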