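"""Elastance waveform, Frank-Starling law and controller behaviour."""

import numpy as np
import pytest

import mclsim as m
from mclsim.control import (FsControllerState, fs_beat_update, fs_target_esp,
                            normalized_elastance, set_contractility)
from mclsim.errors import ConfigurationError
from mclsim.metrics import summarize_trajectory

from conftest import build_params


class TestElastanceWaveform:
    PERIOD = 1.0

    def test_diastolic_start(self):
        assert normalized_elastance(0.0, self.PERIOD) < 0.01

    def test_end_diastole_relaxed(self):
        assert normalized_elastance(0.999 * self.PERIOD, self.PERIOD) < 0.01

    def test_peak_normalised_to_one(self):
        t = np.linspace(0.0, self.PERIOD, 10_000, endpoint=False)
        e = normalized_elastance(t, self.PERIOD)
        assert 0.999 <= float(e.max()) <= 1.0 + 1e-9
        assert float(e.min()) >= 0.0

    def test_periodicity(self):
        g = np.random.default_rng(1)
        t = g.uniform(0.0, 10.0, 100)
        e1 = normalized_elastance(t, self.PERIOD)
        e2 = normalized_elastance(t + self.PERIOD, self.PERIOD)
        assert np.allclose(e1, e2, atol=1e-12)

    def test_invalid_period(self):
        with pytest.raises(ConfigurationError):
            normalized_elastance(0.1, 0.0)


class TestFsTargetEsp:
    def test_zero_slope_gives_intercept(self):
        for lap in (0.0, 5.0, 40.0):
            assert fs_target_esp(lap, 0.0, 30.0) == 30.0

    def test_linear_law(self):
        assert fs_target_esp(12.0, 4.0, 20.0) == pytest.approx(68.0)

    def test_floor_at_zero(self):
        assert fs_target_esp(10.0, 4.0, -100.0) == 0.0


class TestFsBeatUpdate:
    FS = m.FsParams(enabled=True, slope_lv=4.0, intercept_lv=20.0,
                    slope_rv=2.0, intercept_rv=8.0, gain=0.3,
                    e_max_bounds=(0.05, 12.0))

    @staticmethod
    def ctrl():
        return FsControllerState(current_e_max_lv=1.0, current_e_max_rv=0.5)

    def test_zero_error_is_fixed_point(self):
        measured = {"lap": 10.0, "rap": 6.0, "lvesp": 60.0, "rvesp": 20.0}
        new = fs_beat_update(self.ctrl(), self.FS, measured)
        assert new.current_e_max_lv == pytest.approx(1.0)
        assert new.current_e_max_rv == pytest.approx(0.5)

    def test_control_direction(self):
        measured = {"lap": 10.0, "rap": 6.0, "lvesp": 40.0, "rvesp": 30.0}
        new = fs_beat_update(self.ctrl(), self.FS, measured)
        assert new.current_e_max_lv > 1.0   # target 60 above measured 40
        assert new.current_e_max_rv < 0.5   # target 20 below measured 30

    def test_clipping_to_bounds(self):
        measured = {"lap": 100.0, "rap": 0.0, "lvesp": 1.0, "rvesp": 100.0}
        fs = self.FS.model_copy(update={"gain": 50.0})
        new = fs_beat_update(self.ctrl(), fs, measured)
        assert new.current_e_max_lv == fs.e_max_bounds[1]
        assert new.current_e_max_rv == fs.e_max_bounds[0]

    def test_disabled_controller_rejected(self):
        fs = self.FS.model_copy(update={"enabled": False})
        with pytest.raises(ConfigurationError):
            fs_beat_update(self.ctrl(), fs, {"lap": 1, "rap": 1,
                                             "lvesp": 1, "rvesp": 1})

    def test_closed_loop_tracks_target(self, presets):
        """On the calibrated preset the controller holds measured LVESP within
        2 mmHg of the linear setpoint within 30 beats."""
        params, initial = presets["normal"]
        res = m.find_steady_state(params, initial, max_beats=30)
        last = res.fs_trace[-1]
        assert abs(last["lvesp"] - last["target_lvesp"]) < 2.0


class TestSetContractility:
    def test_identity_scale_preserves_output(self, base_params, base_initial):
        p2 = set_contractility(base_params, "left", "scale_e_max", 1.0)
        t1 = m.simulate(base_params, base_initial, 1.0)
        t2 = m.simulate(p2, base_initial, 1.0)
        assert np.array_equal(t1.y, t2.y)

    def test_fs_modes_require_controller(self, base_params):
        p = base_params.with_configuration("SV")
        with pytest.raises(ConfigurationError):
            set_contractility(p, "left", "fs_slope", 2.0)
        with pytest.raises(ConfigurationError):
            set_contractility(p, "right", "fs_intercept", 5.0)

    def test_unknown_mode_rejected(self, base_params):
        with pytest.raises(ConfigurationError):
            set_contractility(base_params, "left", "voltage", 2.0)

    def test_only_named_knob_changes(self, base_params):
        p2 = set_contractility(base_params, "left", "fs_slope", 1.5)
        assert p2.fs.slope_lv == 1.5
        d1 = base_params.model_dump()
        d2 = p2.model_dump()
        d1["fs"].pop("slope_lv"), d2["fs"].pop("slope_lv")
        assert d1 == d2

    def test_halved_lv_contractility_congests_left_atrium(self, presets,
                                                          steady_states):
        """Weaker LV at fixed SVR: LAP rises, mAoP falls (SV configuration)."""
        params, _ = presets["normal"]
        start = steady_states["normal"]
        p_sv = start.params.with_configuration("SV")
        base = m.find_steady_state(p_sv, start.final_state, max_beats=150)
        b = summarize_trajectory(base.trajectory).mean
        weak = set_contractility(p_sv, "left", "scale_e_max", 0.5)
        res = m.find_steady_state(weak, base.final_state, max_beats=200)
        w = summarize_trajectory(res.trajectory).mean
        assert w.lap > b.lap
        assert w.maop < b.maop

    def test_reduced_fs_slope_lowers_steady_lvesp(self, presets, steady_states):
        params, _ = presets["normal"]
        start = steady_states["normal"]
        weak = set_contractility(start.params, "left", "fs_slope",
                                 start.params.fs.slope_lv * 0.5)
        res = m.find_steady_state(weak, start.final_state, max_beats=200)
        b = summarize_trajectory(start.trajectory).mean
        w = summarize_trajectory(res.trajectory).mean
        assert w.lvesp < b.lvesp
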