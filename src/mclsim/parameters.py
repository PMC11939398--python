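"""Parameter and state containers for the lumped-parameter circulatory loop.

The loop mirrors a bench mock circulation: two pneumatic ventricles (modelled
as time-varying elastances), four gas-column Windkessel compliance chambers
(aortic AoC, systemic venous SVC, pulmonary arterial PAC, pulmonary venous
PVC), passive linear atria, upper/lower-body systemic branches, a pulmonary
branch, and an optional veno-arterial ECMO circuit draining the right atrium
and returning to either the proximal aorta (antegrade) or the femoral segment
of the lower-body branch (retrograde).

All internal units are mL, s, mmHg; flows cross the public interface in L/min.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from typing import Optional, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import _kernel as K
from .errors import ConfigurationError

ATM_MMHG = 760.0
MLPS_TO_LPM = 0.06  # mL/s -> L/min

ECMO_SPEED_MIN = 1800.0  # RPM, operating envelope of the centrifugal pump
ECMO_SPEED_MAX = 4000.0


class Configuration(str, Enum):
    """Heart-model configuration of the loop."""

    SV = "SV"      # separate ventricles: no septal coupling, no Frank-Starling
    BV = "BV"      # biventricular: septal/pericardial coupling, fixed contractility
    BVFS = "BVFS"  # biventricular + per-beat Frank-Starling controller


class Side(str, Enum):
    left = "left"
    right = "right"


class ReturnSite(str, Enum):
    antegrade_aorta = "antegrade_aorta"
    retrograde_femoral = "retrograde_femoral"


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class WindkesselChamber(_Model):
    """Sealed air-over-water compliance chamber (isothermal gas column).

    Gauge pressure is ``p_abs_ref * air_ref / (air_ref - dW) - 760`` where
    ``dW = water_volume - water_volume_ref``: pushing water in compresses the
    trapped air column and raises pressure.
    """

    air_volume_ref: float = Field(gt=0.0, description="air column at reference [mL]")
    pressure_abs_ref: float = Field(default=ATM_MMHG, gt=0.0,
                                    description="absolute pressure at reference [mmHg]")
    water_volume: float = Field(ge=0.0, description="current stored fluid [mL]")
    water_volume_ref: float = Field(default=0.0, ge=0.0,
                                    description="water level at the reference pressure [mL]")

    @model_validator(mode="after")
    def _air_positive(self) -> "WindkesselChamber":
        if self.air_volume_ref - (self.water_volume - self.water_volume_ref) <= 0.0:
            raise ValueError("chamber flooded: non-positive air volume")
        return self


class ValveParams(_Model):
    name: str
    resistance: float = Field(gt=0.0, description="mmHg*s/mL")


class VentricleParams(_Model):
    side: Side
    e_max: float = Field(gt=0.0, description="end-systolic elastance [mmHg/mL]")
    e_min: float = Field(gt=0.0, description="diastolic elastance [mmHg/mL]")
    v0: float = Field(default=0.0, ge=0.0, description="unstressed volume [mL]")

    @model_validator(mode="after")
    def _ordered(self) -> "VentricleParams":
        if not self.e_max > self.e_min:
            raise ValueError("e_max must exceed e_min")
        return self


class CouplingParams(_Model):
    """Direct ventricular interaction: additive pressure cross-talk through the
    shared septum plus an optional linear pericardial constraint."""

    alpha_rl: float = Field(default=0.0, ge=0.0, lt=1.0,
                            description="fraction of RV free-wall pressure added to LV")
    alpha_lr: float = Field(default=0.0, ge=0.0, lt=1.0,
                            description="fraction of LV free-wall pressure added to RV")
    pericardial_enabled: bool = False
    pericardial_stiffness: float = Field(default=0.0, ge=0.0, description="mmHg/mL")
    pericardial_v0: float = Field(default=450.0, ge=0.0, description="mL")


class VascularParams(_Model):
    r_upper_body: float = Field(gt=0.0)
    r_lower_body: float = Field(gt=0.0)
    r_pulmonary: float = Field(gt=0.0, description="PVR [mmHg*s/mL]")
    r_venous_return: float = Field(gt=0.0, description="SVC->RA segment (clampable)")
    r_pulm_venous: float = Field(gt=0.0, description="PVC->LA segment")
    c_la: float = Field(gt=0.0, description="left atrial compliance [mL/mmHg]")
    c_ra: float = Field(gt=0.0, description="right atrial compliance [mL/mmHg]")
    v_la0: float = Field(default=0.0, ge=0.0, description="LA unstressed volume [mL]")
    v_ra0: float = Field(default=0.0, ge=0.0, description="RA unstressed volume [mL]")
    clamp_factor: float = Field(default=1.0, ge=1.0,
                                description="multiplier on r_venous_return (1 = open)")
    femoral_position: float = Field(default=0.1, gt=0.0, lt=1.0,
                                    description="fraction of the lower-body "
                                    "resistance proximal to the femoral "
                                    "ECMO return site")

    @property
    def svr(self) -> float:
        """Effective SVR: upper and lower body branches in parallel."""
        return 1.0 / (1.0 / self.r_upper_body + 1.0 / self.r_lower_body)


class EcmoParams(_Model):
    enabled: bool = False
    speed: float = Field(default=3000.0, ge=0.0, description="RPM")
    return_site: ReturnSite = ReturnSite.retrograde_femoral
    c0: float = Field(default=2.6e-5, gt=0.0, description="mmHg/RPM^2")
    c1: float = Field(default=0.0, le=0.0, description="mmHg/(RPM * L/min)")
    c2: float = Field(default=-4.0, lt=0.0, description="mmHg/(L/min)^2")
    r_drainage: float = Field(default=2.8, gt=0.0, description="mmHg*s/mL")
    r_return: float = Field(default=2.8, gt=0.0, description="mmHg*s/mL")
    inertance: float = Field(default=0.05, gt=0.0, description="mmHg*s^2/mL")

    @model_validator(mode="after")
    def _speed_in_envelope(self) -> "EcmoParams":
        if self.enabled and not (ECMO_SPEED_MIN <= self.speed <= ECMO_SPEED_MAX):
            raise ValueError(
                f"ECMO speed {self.speed:g} RPM outside the pump envelope "
                f"[{ECMO_SPEED_MIN:g}, {ECMO_SPEED_MAX:g}] RPM"
            )
        return self


class FsParams(_Model):
    """Per-beat Frank-Starling law: target ESP = slope * atrial pressure + intercept,
    enforced by a multiplicative integral controller on e_max."""

    enabled: bool = False
    slope_lv: float = Field(default=4.0, ge=0.0)
    intercept_lv: float = Field(default=40.0, description="mmHg")
    slope_rv: float = Field(default=2.0, ge=0.0)
    intercept_rv: float = Field(default=8.0, description="mmHg")
    gain: float = Field(default=0.3, gt=0.0, description="per beat")
    e_max_bounds: Tuple[float, float] = (0.05, 12.0)

    @model_validator(mode="after")
    def _bounds_ordered(self) -> "FsParams":
        lo, hi = self.e_max_bounds
        if not 0.0 < lo < hi:
            raise ValueError("e_max_bounds must be ordered and positive")
        return self


class ElastanceWaveformParams(_Model):
    """Normalised double-Hill activation waveform (peak exactly 1 per beat)."""

    systolic_fraction: float = Field(default=0.3, gt=0.0, lt=1.0)
    n1: float = Field(default=1.9, gt=0.0)
    n2: float = Field(default=21.9, gt=1.0)
    tau1: Optional[float] = Field(default=None, gt=0.0, lt=1.0,
                                  description="rise time constant, fraction of period")
    tau2: Optional[float] = Field(default=None, gt=0.0, lt=1.0,
                                  description="decay time constant, fraction of period")

    @property
    def tau1_eff(self) -> float:
        return self.tau1 if self.tau1 is not None else 0.9 * self.systolic_fraction

    @property
    def tau2_eff(self) -> float:
        return self.tau2 if self.tau2 is not None else 1.5 * self.systolic_fraction


class CircuitParams(_Model):
    """Complete parameterisation of the loop.

    ``configuration`` gates the interaction physics: ``SV`` forces the coupling
    terms to zero and disables the Frank-Starling controller; ``BV`` keeps the
    coupling but fixes contractility; ``BVFS`` enables both.
    """

    heart_rate: float = Field(default=60.0, gt=0.0, description="beats/min")
    configuration: Configuration = Configuration.BVFS
    left: VentricleParams
    right: VentricleParams
    coupling: CouplingParams = CouplingParams()
    mitral: ValveParams = ValveParams(name="mitral", resistance=0.02)
    aortic: ValveParams = ValveParams(name="aortic", resistance=0.05)
    tricuspid: ValveParams = ValveParams(name="tricuspid", resistance=0.02)
    pulmonary: ValveParams = ValveParams(name="pulmonary", resistance=0.04)
    vascular: VascularParams
    aoc: WindkesselChamber
    svc: WindkesselChamber
    pac: WindkesselChamber
    pvc: WindkesselChamber
    ecmo: EcmoParams = EcmoParams()
    fs: FsParams = FsParams()
    waveform: ElastanceWaveformParams = ElastanceWaveformParams()
    total_fluid_volume: Optional[float] = Field(default=None, gt=0.0, description="mL")

    @property
    def period(self) -> float:
        return 60.0 / self.heart_rate

    @property
    def fs_active(self) -> bool:
        return self.fs.enabled and self.configuration is Configuration.BVFS

    def with_configuration(self, configuration: Configuration | str) -> "CircuitParams":
        """Return a copy switched to another configuration (gating applied at
        pack time; parameter values themselves are untouched)."""
        configuration = Configuration(configuration)
        out = self.model_copy(deep=True)
        out.configuration = configuration
        return out

    def copy_deep(self) -> "CircuitParams":
        return self.model_copy(deep=True)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True,
                             separators=(",", ":"))
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class StateVector:
    """Instantaneous fluid volumes of all compliant nodes + ECMO branch flow."""

    v_lv: float
    v_rv: float
    v_la: float
    v_ra: float
    water_aoc: float
    water_svc: float
    water_pac: float
    water_pvc: float
    q_ecmo: float = 0.0  # mL/s

    FIELDS = ("v_lv", "v_rv", "v_la", "v_ra",
              "water_aoc", "water_svc", "water_pac", "water_pvc", "q_ecmo")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self.FIELDS], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "StateVector":
        return cls(*(float(v) for v in y))

    def total_fluid(self) -> float:
        """Total loop fluid excluding the constant ECMO tubing hold-up."""
        return float(sum(getattr(self, f) for f in self.FIELDS[:8]))


@lru_cache(maxsize=64)
def _waveform_norm(n1: float, n2: float, tau1: float, tau2: float) -> float:
    """Peak of the raw double-Hill activation over one period (for normalisation)."""
    phi = np.linspace(0.0, 1.0, 8193)
    raw = K.double_hill_raw(phi, n1, n2, tau1, tau2)
    i = int(np.argmax(raw))
    lo = phi[max(i - 1, 0)]
    hi = phi[min(i + 1, len(phi) - 1)]
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(lambda x: -K.double_hill_raw(np.array([x]), n1, n2, tau1, tau2)[0],
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    return float(max(-res.fun, raw[i]))


def pack(params: CircuitParams) -> np.ndarray:
    """Flatten CircuitParams into the kernel parameter vector, applying the
    configuration gating (SV: coupling zeroed + FS off; BV: FS off)."""
    cfg = params.configuration
    couple = cfg in (Configuration.BV, Configuration.BVFS)

    P = np.zeros(K.N_PARAMS)
    P[K.I_PERIOD] = params.period
    P[K.I_EMAX_LV] = params.left.e_max
    P[K.I_EMIN_LV] = params.left.e_min
    P[K.I_V0_LV] = params.left.v0
    P[K.I_EMAX_RV] = params.right.e_max
    P[K.I_EMIN_RV] = params.right.e_min
    P[K.I_V0_RV] = params.right.v0
    if couple:
        P[K.I_ALPHA_RL] = params.coupling.alpha_rl
        P[K.I_ALPHA_LR] = params.coupling.alpha_lr
        P[K.I_PERI_ON] = 1.0 if params.coupling.pericardial_enabled else 0.0
        P[K.I_PERI_K] = params.coupling.pericardial_stiffness
        P[K.I_PERI_V0] = params.coupling.pericardial_v0
    P[K.I_R_MV] = params.mitral.resistance
    P[K.I_R_AV] = params.aortic.resistance
    P[K.I_R_TV] = params.tricuspid.resistance
    P[K.I_R_PV] = params.pulmonary.resistance
    v = params.vascular
    P[K.I_R_UP] = v.r_upper_body
    P[K.I_R_LOW] = v.r_lower_body
    P[K.I_R_PULM] = v.r_pulmonary
    P[K.I_R_VR] = v.r_venous_return
    P[K.I_R_PVEN] = v.r_pulm_venous
    P[K.I_C_LA] = v.c_la
    P[K.I_C_RA] = v.c_ra
    P[K.I_VLA0] = v.v_la0
    P[K.I_VRA0] = v.v_ra0
    P[K.I_CLAMP] = v.clamp_factor
    P[K.I_FEM_POS] = v.femoral_position
    for base, ch in ((K.I_AOC, params.aoc), (K.I_SVC, params.svc),
                     (K.I_PAC, params.pac), (K.I_PVC, params.pvc)):
        P[base] = ch.air_volume_ref
        P[base + 1] = ch.pressure_abs_ref
        P[base + 2] = ch.water_volume_ref
    e = params.ecmo
    P[K.I_EC_ON] = 1.0 if e.enabled else 0.0
    P[K.I_EC_SPEED] = e.speed
    P[K.I_EC_C0] = e.c0
    P[K.I_EC_C1] = e.c1
    P[K.I_EC_C2] = e.c2
    P[K.I_EC_RD] = e.r_drainage
    P[K.I_EC_RR] = e.r_return
    P[K.I_EC_L] = e.inertance
    P[K.I_EC_ANTE] = 1.0 if e.return_site is ReturnSite.antegrade_aorta else 0.0
    w = params.waveform
    P[K.I_N1] = w.n1
    P[K.I_N2] = w.n2
    P[K.I_TAU1] = w.tau1_eff
    P[K.I_TAU2] = w.tau2_eff
    P[K.I_ENORM] = _waveform_norm(w.n1, w.n2, w.tau1_eff, w.tau2_eff)
    return P


def default_initial_state(params: CircuitParams) -> StateVector:
    """A physiologically sensible starting state: chamber waters from the
    parameter set, atria at ~10/6 mmHg, ventricles mid-diastole."""
    v = params.vascular
    return StateVector(
        v_lv=130.0, v_rv=130.0,
        v_la=v.v_la0 + 10.0 * v.c_la,
        v_ra=v.v_ra0 + 6.0 * v.c_ra,
        water_aoc=params.aoc.water_volume,
        water_svc=params.svc.water_volume,
        water_pac=params.pac.water_volume,
        water_pvc=params.pvc.water_volume,
        q_ecmo=0.0,
    )


def check_total_fluid(params: CircuitParams, initial: StateVector,
                      tol: float = 1.0) -> None:
    """If the parameter set declares a total fluid volume, the initial state
    must agree with it (conservation makes the two redundant)."""
    if params.total_fluid_volume is not None:
        if abs(initial.total_fluid() - params.total_fluid_volume) > tol:
            raise ConfigurationError(
                f"initial state holds {initial.total_fluid():.1f} mL but "
                f"total_fluid_volume declares {params.total_fluid_volume:.1f} mL"
            )
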