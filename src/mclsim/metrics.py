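"""Beat segmentation and extraction of reported hemodynamic quantities.

Pressures are beat-averaged by trapezoidal integration at the transducer
sites of the physical loop: mAoP at the aortic compliance node, LAP/RAP at
the atrial nodes, mPAP at the pulmonary arterial compliance node. Systemic
flow is measured at the venous return into the right atrium (where the bench
clamp-on probe sits); ECMO flow on the pump branch. Stroke volumes integrate
the outflow-valve flows.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import List, Sequence, Tuple

import numpy as np

from . import _kernel as K
from .circuit import Trajectory
from .control import _esp_from_beat
from .errors import InsufficientDataError
from .parameters import MLPS_TO_LPM


@dataclass
class BeatMetrics:
    maop: float              # mmHg
    lap: float               # mmHg
    rap: float               # mmHg
    mpap: float              # mmHg
    lvesp: float             # mmHg
    rvesp: float             # mmHg
    systemic_flow: float     # L/min
    ecmo_flow: float         # L/min
    lv_stroke_volume: float  # mL
    rv_stroke_volume: float  # mL
    aortic_valve_opened: bool

    _NUMERIC = ("maop", "lap", "rap", "mpap", "lvesp", "rvesp",
                "systemic_flow", "ecmo_flow", "lv_stroke_volume",
                "rv_stroke_volume")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def segment_beats(trajectory: Trajectory, period: float | None = None
                  ) -> List[Tuple[int, int]]:
    """Index windows [i0, i1] aligned to elastance-cycle boundaries
    (t mod period == 0); a partial trailing beat is discarded."""
    period = period or trajectory.period
    t = trajectory.t
    spb = int(round(period / trajectory.dt))
    # first sample on a beat boundary
    phase = t[0] / period
    offset = (np.ceil(phase - 1e-9) - phase) * period
    i0 = int(round(offset / trajectory.dt))
    windows = []
    while i0 + spb < len(t):
        windows.append((i0, i0 + spb))
        i0 += spb
    return windows


def beat_metrics(window: Tuple[int, int], trajectory: Trajectory,
                 params=None) -> BeatMetrics:
    """Metrics of a single full beat window (inclusive index pair)."""
    i0, i1 = window
    t = trajectory.t[i0:i1 + 1]
    aux = trajectory.aux[i0:i1 + 1]
    span = t[-1] - t[0]

    def mean(col: int) -> float:
        return float(np.trapezoid(aux[:, col], t) / span)

    q_av = aux[:, K.A_Q_AV]
    q_pv = aux[:, K.A_Q_PV]
    return BeatMetrics(
        maop=mean(K.A_P_AO),
        lap=mean(K.A_P_LA),
        rap=mean(K.A_P_RA),
        mpap=mean(K.A_P_PA),
        lvesp=_esp_from_beat(t, aux[:, K.A_P_LV], q_av, aux[:, K.A_E_NORM]),
        rvesp=_esp_from_beat(t, aux[:, K.A_P_RV], q_pv, aux[:, K.A_E_NORM]),
        systemic_flow=mean(K.A_Q_VR) * MLPS_TO_LPM,
        ecmo_flow=mean(K.A_Q_EC) * MLPS_TO_LPM,
        lv_stroke_volume=float(np.trapezoid(q_av, t)),
        rv_stroke_volume=float(np.trapezoid(q_pv, t)),
        aortic_valve_opened=bool(np.any(q_av > 0.0)),
    )


def trajectory_beat_metrics(trajectory: Trajectory) -> List[BeatMetrics]:
    return [beat_metrics(w, trajectory) for w in segment_beats(trajectory)]


@dataclass
class SteadySummary:
    """Fieldwise mean and standard deviation over the trailing steady beats."""

    mean: BeatMetrics
    std: BeatMetrics
    n_beats: int

    def as_dict(self) -> dict:
        return {"n_beats": self.n_beats,
                "mean": self.mean.as_dict(), "std": self.std.as_dict()}


def steady_summary(beats: Sequence[BeatMetrics]) -> SteadySummary:
    if len(beats) < 3:
        raise InsufficientDataError(
            f"steady summary needs >= 3 beats, got {len(beats)}")
    mean_kw, std_kw = {}, {}
    for name in BeatMetrics._NUMERIC:
        vals = np.array([getattr(b, name) for b in beats], dtype=float)
        mean_kw[name] = float(vals.mean())
        std_kw[name] = float(vals.std(ddof=0))
    opened = any(b.aortic_valve_opened for b in beats)
    return SteadySummary(
        mean=BeatMetrics(**mean_kw, aortic_valve_opened=opened),
        std=BeatMetrics(**std_kw, aortic_valve_opened=opened),
        n_beats=len(beats),
    )


def summarize_trajectory(trajectory: Trajectory) -> SteadySummary:
    return steady_summary(trajectory_beat_metrics(trajectory))
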