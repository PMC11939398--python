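"""Centrifugal-pump characteristic and ECMO branch configuration.

The pump is a fixed-speed centrifugal device with a quadratic head-flow map
``H = c0*s^2 + c1*s*f + c2*f*|f|`` (s in RPM, f in L/min, H in mmHg); the
``f*|f|`` form keeps the curve monotonically decreasing through zero flow so
that transient backflow (there is no check valve in the circuit) remains
well-behaved. The drainage cannula draws from the right atrium; the return
cannula feeds either the aortic compliance node (antegrade, central) or the
femoral segment of the lower-body branch (retrograde, peripheral). A small
branch inertance makes pump flow a differential state, avoiding an algebraic
loop.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import _kernel as K
from .circuit import _eval_state
from .errors import ConfigurationError
from .parameters import (ECMO_SPEED_MAX, ECMO_SPEED_MIN, CircuitParams,
                         EcmoParams, ReturnSite, StateVector)


def pump_head(speed: float, flow: float, p: EcmoParams) -> float:
    """Pump pressure head [mmHg] at a given speed [RPM] and flow [L/min]."""
    if speed < 0.0:
        raise ConfigurationError("pump speed must be non-negative")
    if p.enabled and not (ECMO_SPEED_MIN <= speed <= ECMO_SPEED_MAX):
        raise ConfigurationError(
            f"enabled pump speed {speed:g} RPM outside [{ECMO_SPEED_MIN:g}, "
            f"{ECMO_SPEED_MAX:g}] RPM")
    return p.c0 * speed ** 2 + p.c1 * speed * flow + p.c2 * flow * abs(flow)


def ecmo_flow_rhs(state: StateVector, params: CircuitParams, t: float = 0.0) -> float:
    """dq_ecmo/dt [mL/s^2]: momentum balance over the ECMO branch."""
    if not params.ecmo.enabled:
        raise ConfigurationError("ECMO branch is disabled")
    dy, _ = _eval_state(t, state, params)
    return float(dy[K.IQ_EC])


def steady_flow_balance(params: CircuitParams, p_ra: float, p_return: float,
                        f_max_lpm: float = 20.0) -> float:
    """Steady pump flow [L/min] solving ``head(f) = p_return - p_ra + R*f``
    by bisection on the algebraic force balance (independent of the ODE)."""
    e = params.ecmo
    r_tot = (e.r_drainage + e.r_return) / 0.06  # mmHg per L/min

    def resid(f: float) -> float:
        return pump_head(e.speed, f, e) - (p_return - p_ra) - r_tot * f

    lo, hi = -f_max_lpm, f_max_lpm
    if resid(lo) < 0.0 or resid(hi) > 0.0:
        raise ConfigurationError("steady pump flow outside the bisection bracket")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if resid(mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def configure_ecmo(params: CircuitParams, enabled: Optional[bool] = None,
                   speed: Optional[float] = None,
                   return_site: Optional[ReturnSite | str] = None) -> CircuitParams:
    """Return a copy with only the named ECMO fields changed."""
    out = params.model_copy(deep=True)
    if enabled is not None:
        out.ecmo.enabled = enabled
    if speed is not None:
        out.ecmo.speed = float(speed)
    if return_site is not None:
        out.ecmo.return_site = ReturnSite(return_site)
    if out.ecmo.enabled and not (ECMO_SPEED_MIN <= out.ecmo.speed <= ECMO_SPEED_MAX):
        raise ConfigurationError(
            f"ECMO speed {out.ecmo.speed:g} RPM outside "
            f"[{ECMO_SPEED_MIN:g}, {ECMO_SPEED_MAX:g}] RPM")
    return out


def zero_ecmo_flow(state: StateVector) -> StateVector:
    """State with the pump branch flow zeroed (applied when disabling ECMO)."""
    y = state.as_array()
    y[K.IQ_EC] = 0.0
    return StateVector.from_array(y)
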