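"""Named, reproducible experiment protocols.

Each protocol mirrors one of the bench procedures: the right-atrial-inflow
clamp test for ventricular interaction, the graded-clamp Frank-Starling
test, reproduction of the four cardiac states, and the VA-ECMO sweeps
(pump speed at constant mAoP, mAoP at constant speed, the contractility x
speed grid, and the antegrade/retrograde return comparison). "Holding mAoP
constant" is actuated by trimming the systemic vascular resistance with a
bisection loop, the 0D analogue of adjusting the bench tubing clamps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .circuit import SteadyStateResult, find_steady_state, simulate
from .control import set_contractility
from .ecmo import configure_ecmo, zero_ecmo_flow
from .errors import ConfigurationError, InfeasibleTargetError, MclError
from .metrics import SteadySummary, summarize_trajectory
from .parameters import (CircuitParams, Configuration, StateVector,
                         default_initial_state)
from .stats import AnovaResult, RegressionResult, linear_regression_f, one_way_anova

CLAMP_STRONG = 1000.0
CLAMP_BLANKING_S = 2.0
CLAMP_WINDOW_S = 10.0
FS_CLAMP_STEPS = (1.0, 2.0, 5.0, 10.0, 50.0)

# Target ranges for the four reproducible cardiac states: (mAoP, LAP, RAP,
# flow), each a (direction, value) pair with direction +1 for "greater than".
STATE_TARGET_BOUNDS: Dict[str, Dict[str, Tuple[int, float]]] = {
    "normal": {"maop": (+1, 60.0), "lap": (-1, 15.0), "rap": (-1, 10.0),
               "systemic_flow": (+1, 4.0)},
    "lvf": {"maop": (+1, 60.0), "lap": (+1, 25.0), "rap": (-1, 10.0),
            "systemic_flow": (-1, 3.0)},
    "rvf": {"maop": (+1, 60.0), "lap": (-1, 15.0), "rap": (+1, 25.0),
            "systemic_flow": (-1, 3.0)},
    "bvf": {"maop": (+1, 60.0), "lap": (+1, 25.0), "rap": (+1, 25.0),
            "systemic_flow": (-1, 3.0)},
}


@dataclass
class OperatingPoint:
    value: float | str
    summary: SteadySummary
    converged: bool
    meta: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"value": self.value, "converged": self.converged,
                "meta": self.meta, "summary": self.summary.as_dict()}


@dataclass
class ExperimentResult:
    experiment_name: str
    configuration: str
    preset_name: str
    swept_name: str
    swept_values: List
    points: List[OperatingPoint]
    stats: Dict[str, RegressionResult | AnovaResult] = field(default_factory=dict)
    events: List[str] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def lap_values(self) -> np.ndarray:
        return np.array([p.summary.mean.lap for p in self.points])

    def as_dict(self) -> dict:
        return {
            "experiment_name": self.experiment_name,
            "configuration": self.configuration,
            "preset_name": self.preset_name,
            "swept_name": self.swept_name,
            "swept_values": [v for v in self.swept_values],
            "points": [p.as_dict() for p in self.points],
            "stats": {k: v.as_dict() for k, v in self.stats.items()},
            "events": self.events,
            "extras": self.extras,
        }


def _prep(params: CircuitParams, configuration: str | Configuration | None,
          ecmo_off: bool = False, fs_off: bool = False) -> CircuitParams:
    out = params.model_copy(deep=True)
    if configuration is not None:
        out.configuration = Configuration(configuration)
    if ecmo_off:
        out.ecmo.enabled = False
    if fs_off and out.configuration is Configuration.BVFS:
        out.configuration = Configuration.BV
    return out


def _steady(params: CircuitParams, initial: Optional[StateVector],
            **kw) -> SteadyStateResult:
    # experiment operating points are compared at sub-mmHg resolution, so the
    # harness converges deeper than the interactive default
    kw.setdefault("tolerance", 0.02)
    kw.setdefault("max_beats", 300)
    if initial is None:
        initial = default_initial_state(params)
    return find_steady_state(params, initial, **kw)


@dataclass
class ClampTestResult:
    configuration: str
    baseline: SteadySummary
    delta_rap: float
    delta_lap: float
    ratio: float                 # ΔLAP / ΔRAP over the post-blanking window
    delta_rap_early: float       # first 3 s after the clamp
    delta_lap_early: float
    recovered: bool              # baseline recovered within 1 mmHg after release
    events: List[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {"experiment_name": "clamp_test",
                "configuration": self.configuration,
                "baseline": self.baseline.as_dict(),
                "delta_rap": self.delta_rap, "delta_lap": self.delta_lap,
                "ratio": self.ratio,
                "delta_rap_early": self.delta_rap_early,
                "delta_lap_early": self.delta_lap_early,
                "recovered": self.recovered, "events": self.events}


def run_clamp_test(params: CircuitParams, configuration: str = "BV",
                   initial: Optional[StateVector] = None,
                   clamp_factor: float = CLAMP_STRONG,
                   early_window_s: float = 3.0) -> ClampTestResult:
    """Step the venous-return clamp and measure the immediate transmission of
    the RAP drop to the left atrium (direct ventricular interaction)."""
    if Configuration(configuration) not in (Configuration.SV, Configuration.BV):
        raise ConfigurationError("clamp test runs in the SV or BV configuration")
    p = _prep(params, configuration, ecmo_off=True, fs_off=True)
    base = _steady(p, initial)
    if not base.converged:
        raise MclError("clamp test aborted: baseline did not converge")
    base_sum = summarize_trajectory(base.trajectory)
    rap0, lap0 = base_sum.mean.rap, base_sum.mean.lap

    clamped = p.model_copy(deep=True)
    clamped.vascular.clamp_factor = clamp_factor
    horizon = CLAMP_BLANKING_S + CLAMP_WINDOW_S
    traj = simulate(clamped, base.final_state, horizon)
    sel = traj.t >= traj.t[0] + CLAMP_BLANKING_S
    d_rap = float(np.mean(traj.p_ra[sel])) - rap0
    d_lap = float(np.mean(traj.p_la[sel])) - lap0
    early = traj.t <= traj.t[0] + early_window_s
    d_rap_e = float(np.mean(traj.p_ra[early])) - rap0
    d_lap_e = float(np.mean(traj.p_la[early])) - lap0
    ratio = d_lap / d_rap if d_rap != 0.0 else float("nan")

    recov = find_steady_state(p, traj.final_state, max_beats=90)
    recov_sum = summarize_trajectory(recov.trajectory)
    recovered = (abs(recov_sum.mean.rap - rap0) < 1.0
                 and abs(recov_sum.mean.lap - lap0) < 1.0)
    events = [f"clamp x{clamp_factor:g} at t=0", f"release at t={horizon:g}s"]
    return ClampTestResult(configuration=str(configuration), baseline=base_sum,
                           delta_rap=d_rap, delta_lap=d_lap, ratio=ratio,
                           delta_rap_early=d_rap_e, delta_lap_early=d_lap_e,
                           recovered=recovered, events=events)


def run_fs_validation(params: CircuitParams, configuration: str = "BV",
                      initial: Optional[StateVector] = None,
                      clamp_factors: Sequence[float] = FS_CLAMP_STEPS,
                      preset_name: str = "") -> ExperimentResult:
    """Graded venous-return clamping; records steady LVESP and LV outflow per
    step and their relative drops from baseline (Frank-Starling probe)."""
    if Configuration(configuration) not in (Configuration.BV, Configuration.BVFS):
        raise ConfigurationError("FS validation runs in BV or BVFS")
    p = _prep(params, configuration, ecmo_off=True)
    points: List[OperatingPoint] = []
    state = initial
    run_params = p
    for cf in clamp_factors:
        q = run_params.model_copy(deep=True)
        q.vascular.clamp_factor = float(cf)
        res = _steady(q, state)
        if not res.converged:
            raise MclError(f"FS validation: no convergence at clamp x{cf:g}")
        summ = summarize_trajectory(res.trajectory)
        points.append(OperatingPoint(value=float(cf), summary=summ,
                                     converged=res.converged))
        state = res.final_state
        run_params = res.params  # carry adapted e_max forward (BVFS)
    lvesp = np.array([pt.summary.mean.lvesp for pt in points])
    # LV outflow through the aortic valve, L/min
    outflow = np.array([pt.summary.mean.lv_stroke_volume for pt in points]) \
        * p.heart_rate / 1000.0
    rel_esp_drop = (lvesp[0] - lvesp) / lvesp[0]
    rel_out_drop = (outflow[0] - outflow) / outflow[0]
    extras = {
        "lvesp": lvesp.tolist(), "lv_outflow_lpm": outflow.tolist(),
        "rel_lvesp_drop": rel_esp_drop.tolist(),
        "rel_outflow_drop": rel_out_drop.tolist(),
        "rel_lvesp_drop_strongest": float(rel_esp_drop[-1]),
        "rel_outflow_drop_strongest": float(rel_out_drop[-1]),
    }
    return ExperimentResult("fs_validation", str(configuration), preset_name,
                            "clamp_factor", list(clamp_factors), points,
                            extras=extras)


def run_cardiac_state(params: CircuitParams, state_name: str,
                      initial: Optional[StateVector] = None) -> ExperimentResult:
    """Steady summary of one cardiac-state preset (BVFS, ECMO off), checked
    against its target bounds."""
    key = state_name.lower()
    if key not in STATE_TARGET_BOUNDS:
        raise ConfigurationError(f"unknown cardiac state {state_name!r}")
    p = _prep(params, "BVFS", ecmo_off=True)
    res = _steady(p, initial)
    summ = summarize_trajectory(res.trajectory)
    checks = {}
    for metric, (sign, bound) in STATE_TARGET_BOUNDS[key].items():
        val = getattr(summ.mean, metric)
        checks[metric] = {"bound": bound,
                          "direction": ">" if sign > 0 else "<",
                          "value": val,
                          "passed": bool(val > bound if sign > 0 else val < bound)}
    pt = OperatingPoint(value=key, summary=summ, converged=res.converged)
    return ExperimentResult("cardiac_state", "BVFS", key, "state", [key], [pt],
                            extras={"bound_checks": checks,
                                    "all_passed": all(c["passed"] for c in checks.values()),
                                    "converged": res.converged})


SVR_TRIM_BOUNDS = (0.2, 5.0)


def hold_maop_trim(params: CircuitParams, target_maop: float,
                   tolerance: float = 0.5, max_iter: int = 25,
                   initial: Optional[StateVector] = None
                   ) -> Tuple[CircuitParams, float, dict]:
    """Scale the systemic branch resistances by a common factor (bisection)
    until the steady mAoP matches the target. Returns (trimmed params,
    achieved mAoP, info dict with factor / iterations / final steady state)."""
    base = params.model_copy(deep=True)
    r_up0, r_low0 = base.vascular.r_upper_body, base.vascular.r_lower_body
    state = initial if initial is not None else default_initial_state(base)

    def evaluate(factor: float, state0: StateVector):
        q = base.model_copy(deep=True)
        q.vascular.r_upper_body = r_up0 * factor
        q.vascular.r_lower_body = r_low0 * factor
        res = _steady(q, state0)
        return q, res, summarize_trajectory(res.trajectory).mean.maop

    lo, hi = SVR_TRIM_BOUNDS
    q, res, achieved = evaluate(1.0, state)
    n_iter = 1
    if abs(achieved - target_maop) <= tolerance:
        return q, achieved, {"factor": 1.0, "iterations": n_iter, "steady": res}
    # bracket (mAoP increases with SVR)
    f_lo, f_hi = lo, hi
    if achieved < target_maop:
        f_lo = 1.0
        _, res_hi, m_hi = evaluate(f_hi, res.final_state)
        n_iter += 1
        if m_hi < target_maop - tolerance:
            raise InfeasibleTargetError(
                f"target mAoP {target_maop:g} unreachable: max achievable "
                f"{m_hi:.1f} mmHg at SVR x{f_hi:g}", achieved=m_hi)
    else:
        f_hi = 1.0
        _, res_lo, m_lo = evaluate(f_lo, res.final_state)
        n_iter += 1
        if m_lo > target_maop + tolerance:
            raise InfeasibleTargetError(
                f"target mAoP {target_maop:g} unreachable: min achievable "
                f"{m_lo:.1f} mmHg at SVR x{f_lo:g}", achieved=m_lo)
    warm = res.final_state
    factor = 1.0
    while n_iter < max_iter:
        factor = 0.5 * (f_lo + f_hi)
        q, res, achieved = evaluate(factor, warm)
        warm = res.final_state
        n_iter += 1
        if abs(achieved - target_maop) <= tolerance:
            break
        if achieved < target_maop:
            f_lo = factor
        else:
            f_hi = factor
    if abs(achieved - target_maop) > tolerance:
        raise InfeasibleTargetError(
            f"SVR trim did not reach mAoP {target_maop:g} within {max_iter} "
            f"iterations (achieved {achieved:.2f})", achieved=achieved)
    return q, achieved, {"factor": factor, "iterations": n_iter, "steady": res}


def default_speed_grid(n: int = 14) -> np.ndarray:
    return np.linspace(1800.0, 4000.0, n)


def run_speed_sweep(params: CircuitParams, configuration: str,
                    preset_name: str = "",
                    speeds: Optional[Sequence[float]] = None,
                    hold_maop: bool = True,
                    target_maop: Optional[float] = None,
                    initial: Optional[StateVector] = None) -> ExperimentResult:
    """Sweep ECMO pump speed; optionally hold mAoP constant by SVR trim.
    Attaches the LAP-on-speed regression when >= 3 points succeed."""
    speeds = np.asarray(speeds if speeds is not None else default_speed_grid(),
                        dtype=float)
    p = _prep(params, configuration)
    p = configure_ecmo(p, enabled=True, speed=float(speeds[0]))
    state = initial if initial is not None else default_initial_state(p)
    if hold_maop and target_maop is None:
        res0 = _steady(p, state)
        target_maop = summarize_trajectory(res0.trajectory).mean.maop
        state = res0.final_state
    points: List[OperatingPoint] = []
    events: List[str] = []
    for s in speeds:
        q = configure_ecmo(p, speed=float(s))
        try:
            if hold_maop:
                q, achieved, info = hold_maop_trim(q, target_maop, initial=state)
                res = info["steady"]
                meta = {"achieved_maop": achieved, "svr_factor": info["factor"]}
            else:
                res = _steady(q, state)
                meta = {}
            summ = summarize_trajectory(res.trajectory)
            points.append(OperatingPoint(value=float(s), summary=summ,
                                         converged=res.converged, meta=meta))
            state = res.final_state
        except MclError as exc:
            events.append(f"speed {s:g} RPM infeasible: {exc}")
    result = ExperimentResult("speed_sweep", str(configuration), preset_name,
                              "ecmo_speed_rpm",
                              [pt.value for pt in points], points,
                              events=events,
                              extras={"hold_maop": hold_maop,
                                      "target_maop": target_maop})
    if len(points) >= 3:
        x = np.array([pt.value for pt in points])
        result.stats["lap_vs_speed"] = linear_regression_f(
            x, result.lap_values(), units="mmHg per RPM")
        result.extras["lap_total_change"] = float(
            result.stats["lap_vs_speed"].slope * (x[-1] - x[0]))
    return result


def run_maop_sweep(params: CircuitParams, configuration: str,
                   preset_name: str = "",
                   maop_targets: Sequence[float] = (55.0, 60.0, 65.0, 70.0, 75.0),
                   speed: float = 2600.0,
                   initial: Optional[StateVector] = None) -> ExperimentResult:
    """Sweep mAoP (via SVR trim) at fixed ECMO speed and contractility."""
    p = _prep(params, configuration)
    p = configure_ecmo(p, enabled=True, speed=speed)
    state = initial if initial is not None else default_initial_state(p)
    points: List[OperatingPoint] = []
    events: List[str] = []
    for tgt in maop_targets:
        try:
            q, achieved, info = hold_maop_trim(p, float(tgt), initial=state)
            res = info["steady"]
            summ = summarize_trajectory(res.trajectory)
            points.append(OperatingPoint(value=float(tgt), summary=summ,
                                         converged=res.converged,
                                         meta={"achieved_maop": achieved,
                                               "svr_factor": info["factor"]}))
            state = res.final_state
        except MclError as exc:
            events.append(f"mAoP target {tgt:g} infeasible: {exc}")
    result = ExperimentResult("maop_sweep", str(configuration), preset_name,
                              "maop_target_mmhg",
                              [pt.value for pt in points], points,
                              events=events, extras={"ecmo_speed": speed})
    if len(points) >= 3:
        x = np.array([pt.meta["achieved_maop"] for pt in points])
        result.stats["lap_vs_maop"] = linear_regression_f(
            x, result.lap_values(), units="mmHg per mmHg")
        result.extras["lap_total_change"] = float(
            result.lap_values()[-1] - result.lap_values()[0])
    return result


def _apply_contractility_scale(params: CircuitParams, scale: float) -> CircuitParams:
    """LV contractility scaling: in BVFS the controller owns e_max, so the
    scale acts on the Frank-Starling law (slope and intercept together, i.e.
    the whole ESPVR analogue); otherwise it acts on e_max directly."""
    if params.fs_active:
        q = set_contractility(params, "left", "fs_slope",
                              params.fs.slope_lv * scale)
        return set_contractility(q, "left", "fs_intercept",
                                 params.fs.intercept_lv * scale)
    return set_contractility(params, "left", "scale_e_max", scale)


def run_contractility_grid(params: CircuitParams, configuration: str,
                           preset_name: str = "",
                           e_max_scales: Sequence[float] = (0.6, 0.8, 1.0),
                           speeds: Sequence[float] = (1800.0, 2600.0, 3400.0, 4000.0),
                           initial: Optional[StateVector] = None) -> ExperimentResult:
    """Full (contractility scale x pump speed) grid at fixed SVR (no trim)."""
    p = _prep(params, configuration)
    points: List[OperatingPoint] = []
    events: List[str] = []
    lap_grid = np.full((len(e_max_scales), len(speeds)), np.nan)
    maop_grid = np.full_like(lap_grid, np.nan)
    state0 = initial if initial is not None else default_initial_state(p)
    for i, scale in enumerate(e_max_scales):
        q_scale = _apply_contractility_scale(p, float(scale))
        state = state0
        for j, s in enumerate(speeds):
            q = configure_ecmo(q_scale, enabled=True, speed=float(s))
            try:
                res = _steady(q, state)
                summ = summarize_trajectory(res.trajectory)
                points.append(OperatingPoint(
                    value=f"scale={scale:g},speed={s:g}", summary=summ,
                    converged=res.converged,
                    meta={"scale": float(scale), "speed": float(s)}))
                lap_grid[i, j] = summ.mean.lap
                maop_grid[i, j] = summ.mean.maop
                state = res.final_state
            except MclError as exc:
                events.append(f"scale {scale:g} speed {s:g}: {exc}")
    lap_range = np.nanmax(lap_grid, axis=0) - np.nanmin(lap_grid, axis=0)
    flat = np.nanargmin(lap_grid)
    i_min, j_min = np.unravel_index(flat, lap_grid.shape)
    extras = {
        "scales": list(map(float, e_max_scales)),
        "speeds": list(map(float, speeds)),
        "lap_grid": lap_grid.tolist(),
        "maop_grid": maop_grid.tolist(),
        "lap_range_by_speed": lap_range.tolist(),
        "min_lap_speed": float(speeds[j_min]),
        "min_lap_scale": float(e_max_scales[i_min]),
    }
    return ExperimentResult("contractility_grid", str(configuration), preset_name,
                            "scale_x_speed",
                            [pt.value for pt in points], points,
                            events=events, extras=extras)


def run_direction_comparison(params: CircuitParams, configuration: str,
                             preset_name: str = "",
                             speeds: Optional[Sequence[float]] = None,
                             initial: Optional[StateVector] = None
                             ) -> ExperimentResult:
    """Antegrade (aortic) vs retrograde (femoral) ECMO return at matched
    speeds; one-way ANOVA of LAP grouped by return direction."""
    speeds = np.asarray(speeds if speeds is not None
                        else np.linspace(1800.0, 4000.0, 7), dtype=float)
    p = _prep(params, configuration)
    points: List[OperatingPoint] = []
    groups: Dict[str, List[float]] = {}
    state0 = initial if initial is not None else default_initial_state(p)
    for direction in ("antegrade_aorta", "retrograde_femoral"):
        state = state0
        laps = []
        for s in speeds:
            q = configure_ecmo(p, enabled=True, speed=float(s),
                               return_site=direction)
            res = _steady(q, state)
            summ = summarize_trajectory(res.trajectory)
            points.append(OperatingPoint(
                value=f"{direction}@{s:g}", summary=summ,
                converged=res.converged,
                meta={"direction": direction, "speed": float(s)}))
            laps.append(summ.mean.lap)
            state = res.final_state
        groups[direction] = laps
    anova = one_way_anova(list(groups.values()), labels=list(groups.keys()))
    per_speed = [abs(a - r) for a, r in zip(*groups.values())]
    extras = {"speeds": speeds.tolist(),
              "lap_by_direction": groups,
              "lap_abs_diff_by_speed": per_speed,
              "max_lap_abs_diff": float(max(per_speed))}
    return ExperimentResult("direction_comparison", str(configuration),
                            preset_name, "return_site_x_speed",
                            [pt.value for pt in points], points,
                            stats={"lap_by_direction": anova}, extras=extras)
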