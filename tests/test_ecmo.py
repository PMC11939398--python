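"""Centrifugal pump characteristic and ECMO branch behaviour."""

import numpy as np
import pytest

import mclsim as m
from mclsim.ecmo import (configure_ecmo, ecmo_flow_rhs, pump_head,
                         steady_flow_balance, zero_ecmo_flow)
from mclsim.errors import ConfigurationError
from mclsim.metrics import summarize_trajectory


DISABLED = m.EcmoParams(enabled=False)
ENABLED = m.EcmoParams(enabled=True, speed=3000.0)


class TestPumpHead:
    def test_zero_speed_zero_flow(self):
        assert pump_head(0.0, 0.0, DISABLED) == 0.0

    def test_quadratic_speed_scaling_at_zero_flow(self):
        assert pump_head(3000.0, 0.0, ENABLED) == pytest.approx(
            ENABLED.c0 * 9.0e6)

    def test_monotone_decreasing_in_flow(self):
        flows = np.linspace(0.0, 8.0, 30)
        heads = [pump_head(3000.0, f, ENABLED) for f in flows]
        assert np.all(np.diff(heads) < 0.0)

    def test_faster_always_beats_slower(self):
        for f in np.linspace(0.0, 8.0, 17):
            assert pump_head(4000.0, f, ENABLED) > pump_head(1800.0, f, ENABLED)

    def test_speed_envelope_enforced_when_enabled(self):
        with pytest.raises(ConfigurationError):
            pump_head(1500.0, 2.0, ENABLED)
        with pytest.raises(ConfigurationError):
            pump_head(4200.0, 2.0, ENABLED)
        # disabled pump: characteristic may be queried anywhere
        assert pump_head(500.0, 0.0, DISABLED) >= 0.0


class TestConfigureEcmo:
    def test_only_ecmo_fields_change(self, base_params):
        p2 = configure_ecmo(base_params, enabled=True, speed=3400.0,
                            return_site="antegrade_aorta")
        d1, d2 = base_params.model_dump(), p2.model_dump()
        assert d1.pop("ecmo") != d2.pop("ecmo")
        assert d1 == d2

    def test_out_of_range_speed_rejected(self, base_params):
        with pytest.raises((ConfigurationError, ValueError)):
            configure_ecmo(base_params, enabled=True, speed=5000.0)

    def test_reconfiguration_is_deterministic(self, base_params, base_initial):
        p = configure_ecmo(base_params, enabled=True, speed=3400.0)
        t1 = m.simulate(p, base_initial, 2.0)
        p_again = configure_ecmo(configure_ecmo(p, enabled=False),
                                 enabled=True, speed=3400.0)
        t2 = m.simulate(p_again, base_initial, 2.0)
        assert np.array_equal(t1.y, t2.y)

    def test_disabled_branch_rhs_rejected(self, base_params, base_initial):
        with pytest.raises(ConfigurationError):
            ecmo_flow_rhs(base_initial, base_params)

    def test_zeroing_helper(self, base_initial):
        s = base_initial
        s.q_ecmo = 42.0
        assert zero_ecmo_flow(s).q_ecmo == 0.0


@pytest.fixture(scope="module")
def ecmo_steady(presets, steady_states):
    params, _ = presets["lvf"]
    start = steady_states["lvf"]
    p = configure_ecmo(start.params, enabled=True, speed=3400.0)
    res = m.find_steady_state(p, start.final_state, max_beats=200)
    assert res.converged
    return p, res


class TestEcmoSteadyState:
    def test_momentum_balance_vanishes_at_steady_state(self, ecmo_steady):
        p, res = ecmo_steady
        traj = res.trajectory
        # beat-mean dq/dt over the final beat is ~0
        q = traj.signal("q_ecmo")
        spb = int(round(p.period / traj.dt))
        drift = (q[-1] - q[-spb - 1]) / p.period
        assert abs(drift) < 0.5  # mL/s^2, vs pump accelerations of ~1e3

    def test_bisection_oracle_matches_simulated_flow(self, ecmo_steady):
        """Steady pump flow solves the algebraic head balance (within 1%)."""
        p, res = ecmo_steady
        traj = res.trajectory
        q_sim = float(np.trapezoid(traj.signal("q_ecmo"), traj.t)
                      / (traj.t[-1] - traj.t[0])) * 0.06
        p_ra = float(np.trapezoid(traj.p_ra, traj.t) / (traj.t[-1] - traj.t[0]))
        p_ret = float(np.trapezoid(traj.signal("p_fem"), traj.t)
                      / (traj.t[-1] - traj.t[0]))
        q_oracle = steady_flow_balance(p, p_ra, p_ret)
        assert q_sim == pytest.approx(q_oracle, rel=0.01)

    def test_positive_flow_on_every_preset_at_speed(self, presets, steady_states):
        for name in ("normal", "lvf", "rvf", "bvf"):
            start = steady_states[name]
            p = configure_ecmo(start.params, enabled=True, speed=3400.0)
            res = m.find_steady_state(p, start.final_state, max_beats=150)
            s = summarize_trajectory(res.trajectory)
            assert s.mean.ecmo_flow > 0.0, name

    def test_return_site_switch_only_reroutes_flow(self, base_params,
                                                   base_initial):
        from mclsim.circuit import circuit_rhs
        s = base_initial
        s.q_ecmo = 50.0
        pa = configure_ecmo(base_params, enabled=True, speed=3000.0,
                            return_site="antegrade_aorta")
        pr = configure_ecmo(pa, return_site="retrograde_femoral")
        da = circuit_rhs(0.3, s, pa)
        dr = circuit_rhs(0.3, s, pr)
        # heart chambers and the pulmonary side see identical balances
        assert np.allclose(da[[0, 1, 2, 3, 6, 7]], dr[[0, 1, 2, 3, 6, 7]])
        # the return flow shifts from the aortic node toward the venous side
        assert da[4] > dr[4]
        assert da[5] < dr[5]
        # and total volume balance is unchanged
        assert np.sum(da[:8]) == pytest.approx(np.sum(dr[:8]), abs=1e-9)
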