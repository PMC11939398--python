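"""Circuit topology operations, simulation driver and steady-state finder.

The loop is integrated with a deterministic fixed-step classical RK4 scheme
(default step 0.25 ms). The Frank-Starling controller, when active, acts
discretely at beat boundaries; scheduled events (clamp steps, pump-speed
changes) are applied at the first step boundary at or after their stated
time.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _kernel as K
from .control import fs_beat_update_packed
from .errors import (ConfigurationError, DegenerateChamberError,
                     InstabilityError, IntegrationError)
from .parameters import (ATM_MMHG, CircuitParams, StateVector, ValveParams,
                         WindkesselChamber, pack)

DEFAULT_DT = 2.5e-4  # s
INSTABILITY_FACTOR = 10.0

Event = Tuple[float, Callable[[CircuitParams], CircuitParams]]


def chamber_pressure(chamber: WindkesselChamber) -> float:
    """Gauge pressure of a sealed gas-column compliance chamber [mmHg].

    Isothermal compression of the trapped air column:
    ``P_abs = p_abs_ref * air_ref / (air_ref - dW)``, gauge = P_abs - 760.
    """
    d_water = chamber.water_volume - chamber.water_volume_ref
    air = chamber.air_volume_ref - d_water
    if air <= 0.0:
        raise DegenerateChamberError(
            f"chamber flooded: air column {air:.1f} mL (water {chamber.water_volume:.1f} mL)"
        )
    return chamber.pressure_abs_ref * chamber.air_volume_ref / air - ATM_MMHG


def valve_flow(p_upstream: float, p_downstream: float, valve: ValveParams) -> float:
    """Ideal-diode valve: forward flow only, linear in the pressure drop."""
    dp = p_upstream - p_downstream
    return dp / valve.resistance if dp > 0.0 else 0.0


def _eval_state(t: float, state: StateVector, params: CircuitParams,
                P: Optional[np.ndarray] = None) -> Tuple[np.ndarray, np.ndarray]:
    if P is None:
        P = pack(params)
    dy = np.empty(K.N_STATE)
    aux = np.empty(K.N_AUX)
    K._eval(t, state.as_array(), P, dy, aux)
    return dy, aux


def ventricular_pressures(state: StateVector, t: float,
                          params: CircuitParams) -> Tuple[float, float]:
    """Coupled ventricular pressures (free-wall elastance + septal cross-talk
    + optional pericardial constraint)."""
    _, aux = _eval_state(t, state, params)
    return float(aux[K.A_P_LV]), float(aux[K.A_P_RV])


def circuit_rhs(t: float, state: StateVector, params: CircuitParams) -> np.ndarray:
    """Time derivative of the state vector (node volume balances)."""
    dy, _ = _eval_state(t, state, params)
    if not np.all(np.isfinite(dy)):
        bad = [StateVector.FIELDS[i] for i in np.where(~np.isfinite(dy))[0]]
        raise IntegrationError(f"non-finite derivative in component(s): {', '.join(bad)}")
    return dy


@dataclass
class Trajectory:
    """Fixed-step record of a simulation: states plus derived pressures/flows."""

    t: np.ndarray            # (n,)
    y: np.ndarray            # (n, 9)
    aux: np.ndarray          # (n, N_AUX)
    dt: float
    period: float
    params: CircuitParams    # parameter set at the end of the run
    events_log: List[str] = field(default_factory=list)
    fs_trace: List[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.t)

    def signal(self, name: str) -> np.ndarray:
        if name in K.AUX_NAMES:
            return self.aux[:, K.AUX_NAMES.index(name)]
        if name in StateVector.FIELDS:
            return self.y[:, StateVector.FIELDS.index(name)]
        raise KeyError(name)

    def __getattr__(self, name: str):
        try:
            return self.signal(name)
        except KeyError:
            raise AttributeError(name) from None

    @property
    def final_state(self) -> StateVector:
        return StateVector.from_array(self.y[-1])

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"time_s": self.t}
        for name in ("p_lv", "p_rv", "p_la", "p_ra", "p_ao", "p_pa", "p_pv"):
            cols[name] = self.signal(name)
        cols["q_systemic"] = self.signal("q_vr") * 0.06   # L/min, at the RA inflow
        cols["q_ecmo"] = self.signal("q_ecmo") * 0.06     # L/min
        cols["q_aortic_valve"] = self.signal("q_av") * 0.06
        for name in StateVector.FIELDS[:8]:
            cols[name] = self.signal(name)
        return pd.DataFrame(cols)


def _steps_per_beat(period: float, dt: float) -> int:
    spb = period / dt
    if abs(spb - round(spb)) > 1e-9:
        raise ConfigurationError(
            f"time step {dt} s must divide the beat period {period} s")
    return int(round(spb))


def _check_sane(y: np.ndarray, total_fluid: float) -> None:
    if not np.all(np.isfinite(y)):
        bad = [StateVector.FIELDS[i] for i in np.where(~np.isfinite(y[-1] if y.ndim > 1 else y))[0]]
        raise IntegrationError(f"non-finite state in component(s): {', '.join(bad)}")
    vols = y[..., :8]
    if np.any(np.abs(vols) > INSTABILITY_FACTOR * total_fluid):
        raise InstabilityError(
            f"volume exceeded {INSTABILITY_FACTOR:g}x total fluid ({total_fluid:.0f} mL): "
            "integration unstable")


def simulate(params: CircuitParams, initial: StateVector, duration: float,
             dt: float = DEFAULT_DT,
             event_schedule: Optional[Sequence[Event]] = None,
             t0: float = 0.0) -> Trajectory:
    """Integrate the loop for ``duration`` seconds.

    ``event_schedule`` is a sequence of ``(time, mutator)`` pairs; each mutator
    maps a CircuitParams to an updated copy and is applied at the first step
    boundary at or after its time. The Frank-Starling controller (if the
    configuration enables it) updates e_max at every beat boundary.
    """
    if dt > 1e-3:
        raise ConfigurationError("dt must be <= 1 ms")
    period = params.period
    n_total = int(round(duration / dt))
    P = pack(params)
    y = initial.as_array()
    total_fluid = float(np.sum(y[:8]))

    if n_total == 0:
        _, aux0 = _eval_state(t0, initial, params, P)
        return Trajectory(t=np.array([t0]), y=y[None, :], aux=aux0[None, :],
                          dt=dt, period=period, params=params)

    events = sorted(event_schedule or [], key=lambda e: e[0])
    # segment boundaries (step indices): beats (for FS), events, end of run
    bounds = {n_total}
    fs_on = params.fs_active
    spb = _steps_per_beat(period, dt)
    if fs_on:
        bounds.update(range(spb, n_total, spb))
    ev_steps = []
    for t_ev, mut in events:
        i_ev = max(0, math.ceil(round((t_ev - t0) / dt, 9)))
        if i_ev <= n_total:
            ev_steps.append((i_ev, t_ev, mut))
            bounds.add(i_ev)
    bounds = sorted(b for b in bounds if 0 < b <= n_total)

    t_arr = t0 + dt * np.arange(n_total + 1)
    y_all = np.empty((n_total + 1, K.N_STATE))
    aux_all = np.empty((n_total + 1, K.N_AUX))
    y_all[0] = y
    log: List[str] = []
    fs_trace: List[dict] = []
    work = params
    i_prev = 0
    beat_start = 0
    for i_next in bounds:
        for i_ev, t_ev, mut in ev_steps:
            if i_ev == i_prev:
                work = mut(work)
                P = pack(work)
                log.append(f"t={t_arr[i_prev]:.4f}s: event applied")
        seg = K.integrate_rk4(y_all[i_prev], t_arr[i_prev], dt, i_next - i_prev, P)
        y_all[i_prev:i_next + 1] = seg
        aux_all[i_prev:i_next + 1] = K.derive_trajectory(
            t_arr[i_prev:i_next + 1], seg, P)
        _check_sane(seg[-1], total_fluid)
        if fs_on and (i_next - beat_start) == spb:
            P, rec = fs_beat_update_packed(
                P, work.fs, t_arr[beat_start:i_next + 1],
                aux_all[beat_start:i_next + 1])
            work = _sync_emax(work, P)
            fs_trace.append(rec)
            beat_start = i_next
        i_prev = i_next
    # trailing event exactly at the end of the run
    for i_ev, t_ev, mut in ev_steps:
        if i_ev == n_total:
            work = mut(work)
            log.append(f"t={t_arr[-1]:.4f}s: event applied")
    _check_sane(y_all, total_fluid)
    return Trajectory(t=t_arr, y=y_all, aux=aux_all, dt=dt, period=period,
                      params=work, events_log=log, fs_trace=fs_trace)


def _sync_emax(params: CircuitParams, P: np.ndarray) -> CircuitParams:
    out = params.model_copy(deep=True)
    out.left.e_max = float(P[K.I_EMAX_LV])
    out.right.e_max = float(P[K.I_EMAX_RV])
    return out


@dataclass
class SteadyStateResult:
    converged: bool
    n_beats: int
    trajectory: Trajectory           # trailing (<= keep_beats) beats
    final_state: StateVector
    params: CircuitParams            # with controller-adapted e_max
    beat_mean_history: np.ndarray    # (n_beats, 6): p_lv p_rv p_la p_ra p_ao p_pa
    fs_trace: List[dict] = field(default_factory=list)


_MEAN_COLS = (K.A_P_LV, K.A_P_RV, K.A_P_LA, K.A_P_RA, K.A_P_AO, K.A_P_PA)


def find_steady_state(params: CircuitParams, initial: StateVector,
                      max_beats: int = 120, tolerance: float = 0.1,
                      dt: float = DEFAULT_DT, keep_beats: int = 10,
                      consecutive: int = 3) -> SteadyStateResult:
    """Run beat-by-beat until all beat-mean pressures settle.

    Convergence: every monitored beat-mean pressure changes by less than
    ``tolerance`` mmHg between consecutive beats, for ``consecutive``
    consecutive beat pairs. Returns the trailing ``keep_beats`` beats either
    way, with the convergence flag reporting whether the tolerance was met.
    """
    if max_beats < 1:
        raise ConfigurationError("max_beats must be >= 1")
    period = params.period
    spb = _steps_per_beat(period, dt)
    P = pack(params)
    y = initial.as_array()
    total_fluid = float(np.sum(y[:8]))
    fs_on = params.fs_active

    history: deque = deque(maxlen=keep_beats)
    means_hist: List[np.ndarray] = []
    fs_trace: List[dict] = []
    prev_means: Optional[np.ndarray] = None
    streak = 0
    converged = False
    n_done = 0
    work = params
    for b in range(max_beats):
        tb = b * period
        t_seg = tb + dt * np.arange(spb + 1)
        seg = K.integrate_rk4(y, tb, dt, spb, P)
        _check_sane(seg[-1], total_fluid)
        aux = K.derive_trajectory(t_seg, seg, P)
        history.append((t_seg, seg, aux))
        w = np.trapezoid(aux[:, _MEAN_COLS], t_seg, axis=0) / period
        means_hist.append(w)
        if fs_on:
            P, rec = fs_beat_update_packed(P, work.fs, t_seg, aux)
            fs_trace.append(rec)
        y = seg[-1]
        n_done = b + 1
        if prev_means is not None:
            if np.max(np.abs(w - prev_means)) < tolerance:
                streak += 1
            else:
                streak = 0
            if streak >= consecutive:
                converged = True
                prev_means = w
                break
        prev_means = w

    work = _sync_emax(work, P) if fs_on else work
    t_cat = np.concatenate([h[0][:-1] for h in history] + [history[-1][0][-1:]])
    y_cat = np.concatenate([h[1][:-1] for h in history] + [history[-1][1][-1:]])
    a_cat = np.concatenate([h[2][:-1] for h in history] + [history[-1][2][-1:]])
    traj = Trajectory(t=t_cat, y=y_cat, aux=a_cat, dt=dt, period=period,
                      params=work, fs_trace=fs_trace)
    return SteadyStateResult(converged=converged, n_beats=n_done, trajectory=traj,
                             final_state=StateVector.from_array(y), params=work,
                             beat_mean_history=np.array(means_hist),
                             fs_trace=fs_trace)
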