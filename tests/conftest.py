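"""Shared fixtures: a compact generic loop for unit tests plus the shipped,
calibrated presets (session-scoped, re-simulated once)."""

import numpy as np
import pytest

import mclsim as m
from mclsim.io import load_preset


def build_params(**overrides) -> m.CircuitParams:
    """A small, fast, physiologically sensible loop for unit tests."""
    kwargs = dict(
        configuration="BVFS",
        left=m.VentricleParams(side="left", e_max=0.30, e_min=0.025, v0=20.0),
        right=m.VentricleParams(side="right", e_max=0.12, e_min=0.02, v0=20.0),
        coupling=m.CouplingParams(alpha_rl=0.2, alpha_lr=0.07),
        vascular=m.VascularParams(
            r_upper_body=1.7, r_lower_body=1.7, r_pulmonary=0.2,
            r_venous_return=0.05, r_pulm_venous=0.015, c_la=14.0, c_ra=3.5),
        aoc=m.WindkesselChamber(air_volume_ref=1200.0, water_volume=893.0,
                                water_volume_ref=800.0),
        svc=m.WindkesselChamber(air_volume_ref=2200.0, water_volume=826.0,
                                water_volume_ref=800.0),
        pac=m.WindkesselChamber(air_volume_ref=8000.0, water_volume=965.0,
                                water_volume_ref=800.0),
        pvc=m.WindkesselChamber(air_volume_ref=10000.0, water_volume=968.0,
                                water_volume_ref=800.0),
        fs=m.FsParams(enabled=True, slope_lv=4.0, intercept_lv=35.0,
                      slope_rv=2.0, intercept_rv=15.0),
    )
    kwargs.update(overrides)
    return m.CircuitParams(**kwargs)


@pytest.fixture()
def base_params() -> m.CircuitParams:
    return build_params()


@pytest.fixture()
def base_initial(base_params) -> m.StateVector:
    init = m.default_initial_state(base_params)
    init.v_lv, init.v_rv = 400.0, 300.0
    return init


PRESET_NAMES = ("normal", "lvf", "rvf", "bvf")


@pytest.fixture(scope="session")
def presets():
    """(params, committed steady initial state) for each shipped preset."""
    return {name: load_preset(name) for name in PRESET_NAMES}


@pytest.fixture(scope="session")
def steady_states(presets):
    """Deterministic steady-state runs of every preset (BVFS, ECMO off)."""
    out = {}
    for name, (params, initial) in presets.items():
        res = m.find_steady_state(params, initial, max_beats=120)
        out[name] = res
    return out


@pytest.fixture(scope="session")
def normal_steady(steady_states):
    return steady_states["normal"]


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
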