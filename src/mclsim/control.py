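"""Elastance waveform, contractility handles and the Frank-Starling controller.

The ventricles are driven by a shared normalised double-Hill activation
waveform e_n(t) in [0, 1]; instantaneous elastance is
``E(t) = e_min + (e_max - e_min) * e_n(t)``.

The Frank-Starling mechanism is a discrete per-beat feedback loop: after each
completed beat, the measured mean atrial pressure sets a target end-systolic
pressure through a linear law (the analogue of the ESPVR), and e_max is
nudged multiplicatively toward the value that realises the target. ESP is
read at the instant of outflow-valve closure; if the valve never opened
during the beat, at peak elastance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from . import _kernel as K
from .errors import ConfigurationError
from .parameters import (CircuitParams, Configuration, ElastanceWaveformParams,
                         FsParams, Side, _waveform_norm)


def normalized_elastance(t, period: float,
                         shape: ElastanceWaveformParams | None = None):
    """Normalised activation e_n(t) in [0, 1]; periodic with peak exactly 1."""
    if period <= 0.0:
        raise ConfigurationError("period must be positive")
    shape = shape or ElastanceWaveformParams()
    phi = np.asarray(t, dtype=float) / period % 1.0
    norm = _waveform_norm(shape.n1, shape.n2, shape.tau1_eff, shape.tau2_eff)
    out = K.double_hill_raw(phi, shape.n1, shape.n2, shape.tau1_eff, shape.tau2_eff) / norm
    return float(out) if np.isscalar(t) else out


def fs_target_esp(mean_atrial_pressure: float, slope: float, intercept: float) -> float:
    """Linear atrial-pressure -> end-systolic-pressure setpoint, floored at 0."""
    return max(0.0, slope * mean_atrial_pressure + intercept)


@dataclass
class FsControllerState:
    """Controller memory carried between beats."""

    current_e_max_lv: float
    current_e_max_rv: float
    last_beat_mean_lap: float = float("nan")
    last_beat_mean_rap: float = float("nan")
    last_lvesp: float = float("nan")
    last_rvesp: float = float("nan")


def _esp_from_beat(t: np.ndarray, p_vent: np.ndarray, q_out: np.ndarray,
                   e_norm: np.ndarray) -> float:
    """ESP = ventricular pressure at outflow-valve closure; at peak elastance
    if the valve never opened during the beat."""
    open_idx = np.nonzero(q_out > 0.0)[0]
    if open_idx.size:
        return float(p_vent[open_idx[-1]])
    return float(p_vent[int(np.argmax(e_norm))])


def beat_measurements(t: np.ndarray, aux: np.ndarray) -> dict:
    """Per-beat quantities the controller acts on (means by trapezoid rule)."""
    period = t[-1] - t[0]
    lap = float(np.trapezoid(aux[:, K.A_P_LA], t) / period)
    rap = float(np.trapezoid(aux[:, K.A_P_RA], t) / period)
    lvesp = _esp_from_beat(t, aux[:, K.A_P_LV], aux[:, K.A_Q_AV], aux[:, K.A_E_NORM])
    rvesp = _esp_from_beat(t, aux[:, K.A_P_RV], aux[:, K.A_Q_PV], aux[:, K.A_E_NORM])
    return {"lap": lap, "rap": rap, "lvesp": lvesp, "rvesp": rvesp}


def _updated_e_max(e_max: float, target: float, measured: float,
                   gain: float, bounds: Tuple[float, float]) -> float:
    error = target - measured
    e_new = e_max * (1.0 + gain * error / max(measured, 1.0))
    return float(min(max(e_new, bounds[0]), bounds[1]))


def fs_beat_update(ctrl: FsControllerState, fs: FsParams,
                   measured) -> FsControllerState:
    """One discrete controller step from a completed beat's measurements.

    ``measured`` needs attributes/keys lap, rap, lvesp, rvesp (mmHg).
    """
    if not fs.enabled:
        raise ConfigurationError("Frank-Starling controller is disabled")
    get = measured.get if isinstance(measured, dict) else lambda k: getattr(measured, k)
    lap, rap = float(get("lap")), float(get("rap"))
    lvesp, rvesp = float(get("lvesp")), float(get("rvesp"))
    tgt_l = fs_target_esp(lap, fs.slope_lv, fs.intercept_lv)
    tgt_r = fs_target_esp(rap, fs.slope_rv, fs.intercept_rv)
    return FsControllerState(
        current_e_max_lv=_updated_e_max(ctrl.current_e_max_lv, tgt_l, lvesp,
                                        fs.gain, fs.e_max_bounds),
        current_e_max_rv=_updated_e_max(ctrl.current_e_max_rv, tgt_r, rvesp,
                                        fs.gain, fs.e_max_bounds),
        last_beat_mean_lap=lap, last_beat_mean_rap=rap,
        last_lvesp=lvesp, last_rvesp=rvesp,
    )


def fs_beat_update_packed(P: np.ndarray, fs: FsParams, t: np.ndarray,
                          aux: np.ndarray) -> Tuple[np.ndarray, dict]:
    """Controller step operating directly on the packed parameter vector
    (used by the simulation driver at beat boundaries). e_max is additionally
    floored just above the diastolic elastance: the controller can weaken a
    ventricle to near-passivity but never invert the elastance swing."""
    m = beat_measurements(t, aux)
    ctrl = FsControllerState(current_e_max_lv=float(P[K.I_EMAX_LV]),
                             current_e_max_rv=float(P[K.I_EMAX_RV]))
    new = fs_beat_update(ctrl, fs, m)
    P = P.copy()
    P[K.I_EMAX_LV] = max(new.current_e_max_lv, P[K.I_EMIN_LV] * 1.001)
    P[K.I_EMAX_RV] = max(new.current_e_max_rv, P[K.I_EMIN_RV] * 1.001)
    rec = dict(m)
    rec["target_lvesp"] = fs_target_esp(m["lap"], fs.slope_lv, fs.intercept_lv)
    rec["target_rvesp"] = fs_target_esp(m["rap"], fs.slope_rv, fs.intercept_rv)
    rec["e_max_lv"] = new.current_e_max_lv
    rec["e_max_rv"] = new.current_e_max_rv
    return P, rec


def set_contractility(params: CircuitParams, side: Side | str, mode: str,
                      value: float) -> CircuitParams:
    """Set one contractility knob, leaving everything else untouched.

    Modes: ``scale_e_max`` (multiply e_max; legal in any configuration),
    ``fs_slope`` / ``fs_intercept`` (set the Frank-Starling law; legal only
    when the controller is active, i.e. the BVFS configuration).
    """
    side = Side(side)
    out = params.model_copy(deep=True)
    if mode == "scale_e_max":
        vent = out.left if side is Side.left else out.right
        vent.e_max = vent.e_max * value
        return out
    if mode not in ("fs_slope", "fs_intercept"):
        raise ConfigurationError(f"unknown contractility mode {mode!r}")
    if params.configuration is not Configuration.BVFS or not params.fs.enabled:
        raise ConfigurationError(
            f"{mode} requires the Frank-Starling controller (BVFS configuration)")
    attr = ("slope_" if mode == "fs_slope" else "intercept_") + \
        ("lv" if side is Side.left else "rv")
    setattr(out.fs, attr, value)
    return out
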