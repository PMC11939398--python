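"""Circuit primitives, conservation laws and the integrator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mclsim as m
from mclsim import _kernel as K
from mclsim.circuit import (chamber_pressure, circuit_rhs, find_steady_state,
                            simulate, valve_flow, ventricular_pressures)
from mclsim.control import normalized_elastance
from mclsim.errors import ConfigurationError, DegenerateChamberError
from mclsim.parameters import pack

from conftest import build_params


class TestChamberPressure:
    def test_reference_state_is_atmospheric(self):
        ch = m.WindkesselChamber(air_volume_ref=1500.0, water_volume=100.0,
                                 water_volume_ref=100.0)
        assert chamber_pressure(ch) == pytest.approx(0.0)

    def test_isothermal_law(self):
        ch = m.WindkesselChamber(air_volume_ref=1500.0, water_volume=100.0,
                                 water_volume_ref=0.0)
        assert chamber_pressure(ch) == pytest.approx(760.0 * 1500.0 / 1400.0 - 760.0)

    def test_small_signal_compliance_finite_difference(self):
        # dV/dP at the reference point equals air_volume_ref / pressure_abs_ref
        ch = lambda w: m.WindkesselChamber(air_volume_ref=1500.0,
                                           water_volume=w, water_volume_ref=500.0)
        dp = chamber_pressure(ch(501.0)) - chamber_pressure(ch(499.0))
        compliance = 2.0 / dp
        assert compliance == pytest.approx(1500.0 / 760.0, rel=2e-3)

    def test_monotone_in_water(self):
        w = np.linspace(0.0, 900.0, 20)
        p = [chamber_pressure(m.WindkesselChamber(
            air_volume_ref=1000.0, water_volume=wi, water_volume_ref=0.0))
            for wi in w]
        assert np.all(np.diff(p) > 0.0)

    def test_flooded_chamber_rejected(self):
        # at validation time ...
        with pytest.raises(ValueError):
            m.WindkesselChamber(air_volume_ref=40.0, water_volume=50.0,
                                water_volume_ref=0.0)
        # ... and at evaluation time for a state that flooded dynamically
        ch = m.WindkesselChamber.model_construct(
            air_volume_ref=40.0, pressure_abs_ref=760.0, water_volume=50.0,
            water_volume_ref=0.0)
        with pytest.raises(DegenerateChamberError):
            chamber_pressure(ch)


class TestValveFlow:
    VALVE = m.ValveParams(name="aortic", resistance=0.05)

    def test_closed_on_negative_gradient(self):
        assert valve_flow(5.0, 10.0, self.VALVE) == 0.0

    def test_linear_forward(self):
        assert valve_flow(20.0, 10.0, self.VALVE) == pytest.approx(200.0)

    @given(st.floats(-50.0, 50.0))
    @settings(deadline=None, derandomize=True)
    def test_rectification(self, dp):
        assert valve_flow(dp, 0.0, self.VALVE) >= 0.0

    def test_continuity_at_closure(self):
        eps = 1e-9
        assert valve_flow(eps, 0.0, self.VALVE) == pytest.approx(0.0, abs=1e-6)
        assert valve_flow(-eps, 0.0, self.VALVE) == 0.0


class TestVentricularPressures:
    def test_sv_configuration_is_pure_elastance(self, base_params):
        p = base_params.with_configuration("SV")
        state = m.default_initial_state(p)
        t = 0.37
        p_lv, _ = ventricular_pressures(state, t, p)
        e_n = normalized_elastance(t, p.period, p.waveform)
        e_lv = p.left.e_min + (p.left.e_max - p.left.e_min) * e_n
        assert p_lv == pytest.approx(e_lv * (state.v_lv - p.left.v0), rel=1e-12)

    def test_coupling_arithmetic(self, base_params):
        """Septal cross-talk adds a fraction of the other side's actively
        generated pressure (free-wall minus passive diastolic component)."""
        p = base_params.with_configuration("BV")
        p.coupling.alpha_rl = 0.2
        p.coupling.alpha_lr = 0.0
        p.coupling.pericardial_enabled = False
        state = m.default_initial_state(p)
        t = 0.1
        p_lv, p_rv = ventricular_pressures(state, t, p)
        p_sv = p.with_configuration("SV")
        lv_free, rv_free = ventricular_pressures(state, t, p_sv)
        rv_passive = p.right.e_min * (state.v_rv - p.right.v0)
        assert p_lv == pytest.approx(lv_free + 0.2 * (rv_free - rv_passive),
                                     rel=1e-12)
        assert p_rv == pytest.approx(rv_free, rel=1e-12)

    def test_coupling_silent_in_diastole(self, base_params):
        """With the activation at zero phase (~end-diastole) the septal terms
        vanish; only the pericardium could differ between SV and BV."""
        p = base_params.with_configuration("BV")
        p.coupling.alpha_rl = 0.4
        p.coupling.pericardial_enabled = False
        state = m.default_initial_state(p)
        p_sv = p.with_configuration("SV")
        t = 0.999  # end-diastole: activation < 1e-2
        c = ventricular_pressures(state, t, p)
        f = ventricular_pressures(state, t, p_sv)
        assert c[0] == pytest.approx(f[0], abs=0.2)

    def test_rv_volume_raises_lv_pressure_when_coupled(self, base_params):
        p = base_params.with_configuration("BV")
        p.coupling.pericardial_enabled = False
        s1 = m.default_initial_state(p)
        s2 = m.default_initial_state(p)
        s2.v_rv += 50.0
        assert ventricular_pressures(s2, 0.2, p)[0] > ventricular_pressures(s1, 0.2, p)[0]


class TestRhsConservation:
    @pytest.mark.parametrize("ecmo_on,site", [
        (False, "antegrade_aorta"),
        (True, "antegrade_aorta"),
        (True, "retrograde_femoral"),
    ])
    def test_volume_derivatives_sum_to_zero(self, base_params, ecmo_on, site):
        p = base_params.model_copy(deep=True)
        p.ecmo.enabled = ecmo_on
        p.ecmo.return_site = site
        P = pack(p)
        g = np.random.default_rng(42)
        dy = np.empty(K.N_STATE)
        aux = np.empty(K.N_AUX)
        for _ in range(1000):
            y = np.concatenate([g.uniform(30.0, 700.0, 4),
                                g.uniform(700.0, 1100.0, 4),
                                g.uniform(-50.0, 120.0, 1)])
            K._eval(g.uniform(0.0, 1.0), y, P, dy, aux)
            assert abs(np.sum(dy[:8])) < 1e-9

    def test_equilibrium_state_is_stationary(self):
        # all node pressures equal and valves shut -> every derivative zero
        pressure = 10.0
        p = build_params(configuration="SV")
        p.left.e_max = p.left.e_min + 1e-12
        p.right.e_max = p.right.e_min + 1e-12
        for ch in (p.aoc, p.svc, p.pac, p.pvc):
            # water level giving exactly `pressure` gauge
            ch.water_volume = ch.water_volume_ref + ch.air_volume_ref * (
                1.0 - ch.pressure_abs_ref / (ch.pressure_abs_ref + pressure))
        state = m.StateVector(
            v_lv=p.left.v0 + pressure / p.left.e_min,
            v_rv=p.right.v0 + pressure / p.right.e_min,
            v_la=p.vascular.c_la * pressure,
            v_ra=p.vascular.c_ra * pressure,
            water_aoc=p.aoc.water_volume, water_svc=p.svc.water_volume,
            water_pac=p.pac.water_volume, water_pvc=p.pvc.water_volume)
        dy = circuit_rhs(0.0, state, p)
        assert np.allclose(dy, 0.0, atol=1e-9)

    def test_two_compartment_discharge_matches_closed_form(self):
        # LA discharging through the mitral valve into a frozen-elastance LV,
        # with every other path blocked: dP decays as exp(-t (1/C + E)/R)
        p = build_params(configuration="SV")
        e = 0.05
        p.left.e_max = e + 1e-12
        p.left.e_min = e
        p.right.e_max = 0.05 + 1e-12
        p.right.e_min = 0.05
        big = 1e9
        p.vascular.r_pulm_venous = big
        p.vascular.r_venous_return = big
        p.vascular.r_upper_body = big
        p.vascular.r_lower_body = big
        p.vascular.r_pulmonary = big
        p.aortic.resistance = big
        p.tricuspid.resistance = big
        p.pulmonary.resistance = big
        R, c_la = p.mitral.resistance, p.vascular.c_la
        state = m.default_initial_state(p)
        state.v_la = c_la * 20.0          # LA at 20 mmHg
        state.v_lv = p.left.v0 + 5.0 / e  # LV at 5 mmHg
        traj = simulate(p, state, 0.2)
        dp0 = 15.0
        k = (1.0 / c_la + e) / R
        expected = dp0 * np.exp(-k * traj.t)
        observed = traj.p_la - traj.p_lv
        assert np.allclose(observed, expected, rtol=1e-6, atol=1e-8)


class TestSimulate:
    def test_zero_duration_returns_initial_only(self, base_params, base_initial):
        traj = simulate(base_params, base_initial, 0.0)
        assert len(traj) == 1
        assert np.allclose(traj.y[0], base_initial.as_array())

    def test_dt_must_divide_period_and_be_small(self, base_params, base_initial):
        with pytest.raises(ConfigurationError):
            simulate(base_params, base_initial, 1.0, dt=2e-3)
        with pytest.raises(ConfigurationError):
            simulate(base_params, base_initial, 1.0, dt=3e-4)

    def test_sv_equals_bv_with_zero_coupling_bitwise(self, base_params, base_initial):
        p_sv = base_params.with_configuration("SV")
        p_bv = base_params.with_configuration("BV")
        p_bv.coupling.alpha_rl = 0.0
        p_bv.coupling.alpha_lr = 0.0
        p_bv.coupling.pericardial_enabled = False
        t1 = simulate(p_sv, base_initial, 2.0)
        t2 = simulate(p_bv, base_initial, 2.0)
        assert np.array_equal(t1.y, t2.y)
        assert np.array_equal(t1.aux, t2.aux)

    def test_ecmo_disabled_is_inert(self, base_params, base_initial):
        p1 = base_params.model_copy(deep=True)
        p1.ecmo.enabled = False
        p1.ecmo.speed = 1900.0
        p2 = base_params.model_copy(deep=True)
        p2.ecmo.enabled = False
        p2.ecmo.speed = 3800.0  # differing branch settings must not matter
        t1 = simulate(p1, base_initial, 2.0)
        t2 = simulate(p2, base_initial, 2.0)
        assert np.array_equal(t1.y, t2.y)
        assert np.all(t1.q_ecmo == 0.0)

    def test_event_applied_at_boundary(self, base_params, base_initial):
        def clamp(params):
            out = params.model_copy(deep=True)
            out.vascular.clamp_factor = 1000.0
            return out

        traj = simulate(base_params, base_initial, 2.0,
                        event_schedule=[(1.0, clamp)])
        i_ev = int(round(1.0 / traj.dt))
        q_vr = traj.signal("q_vr")
        assert abs(q_vr[i_ev + 1]) < abs(q_vr[i_ev - 1]) / 100.0

    def test_volume_conserved_over_long_run(self, base_params, base_initial):
        traj = simulate(base_params, base_initial, 20.0)
        total = traj.y[:, :8].sum(axis=1)
        assert np.max(np.abs(total - total[0])) < 0.01


class TestFindSteadyState:
    def test_converges_fast_from_fixed_point(self, normal_steady, presets):
        params, _ = presets["normal"]
        res = find_steady_state(params, normal_steady.final_state, max_beats=30)
        assert res.converged
        assert res.n_beats <= 4

    def test_flag_false_at_one_beat(self, base_params, base_initial):
        res = find_steady_state(base_params, base_initial, max_beats=1)
        assert not res.converged

    def test_flow_continuity_at_steady_state(self, normal_steady):
        """Beat-mean inflow equals beat-mean outflow at every node (1%)."""
        traj = normal_steady.trajectory
        q_mv = np.trapezoid(traj.signal("q_mv"), traj.t)
        q_av = np.trapezoid(traj.signal("q_av"), traj.t)
        assert q_av == pytest.approx(q_mv, rel=0.01)
        # aortic node balance: valve inflow vs systemic branch outflow
        q_out = np.trapezoid(traj.signal("q_up") + traj.signal("q_low_in"), traj.t)
        assert q_out == pytest.approx(q_av, rel=0.01)
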