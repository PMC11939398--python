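# Methods

`mclsim` is a 0D (lumped-parameter) digital twin of a bench mock circulatory
loop (MCL) built around a biventricular silicone heart: two pneumatically
driven ventricles sharing a septum and pericardial enclosure, four sealed
air-over-water Windkessel compliance chambers, upper- and lower-body systemic
branches, a pulmonary branch, passive atria, and a veno-arterial ECMO circuit
with a centrifugal pump that drains the right atrium and returns flow either
to the proximal aorta (central, antegrade) or to a femoral segment of the
lower-body branch (peripheral, retrograde). The twin exists to study how
pump speed, arterial pressure, LV contractility and return direction shape
left atrial pressure (LAP) — the operative surrogate for pulmonary
congestion — in the presence or absence of ventricular interaction and a
Frank–Starling mechanism.

## Governing model

The loop hardware is described mechanically, not mathematically, so the twin
uses the standard 0D idiom; every element is the simplest form that can
express the reported behaviours.

**Ventricles.** Time-varying elastance with a shared normalised double-Hill
activation waveform e_n(t) ∈ [0, 1] (shape exponents n1 = 1.9, n2 = 21.9;
rise/decay time constants 0.9 and 1.5 times the systolic fraction, default
0.3 of the beat). Instantaneous free-wall pressure:

    p_free = [e_min + (e_max − e_min) · e_n(t)] · (V − V0)

The waveform is numerically normalised so its peak is exactly 1 per beat;
e_max is the contractility handle, e_min the diastolic stiffness. The
calibrated normal ventricles operate at roughly anatomic volumes (LV
end-diastole ≈ 140 mL at e_min,lv = 0.10 mmHg/mL); the failure presets vary
the diastolic stiffness of the failing side, exactly as the bench altered
compliances and drive per state.

**Ventricular interaction.** Switchable by configuration:

* `SV` (separate ventricles): no interaction, no controller.
* `BV`: septal pressure cross-talk plus a pericardial volume constraint.
  The septum transmits a fraction of the *actively generated* pressure of the
  opposite ventricle, p_lv = p_lv,free + α_rl · (E_rv(t) − e_min,rv)(V_rv −
  V0,rv) (and symmetrically with α_lr): systolic squeeze crosses the septum,
  while passive diastolic distension does not — a statically transmitting
  septum would pin each atrial pressure to the opposite ventricle's diastolic
  pressure, which the bench's measured failure states rule out. Passive
  diastolic interaction instead couples through the shared pericardial term
  p_peri = k_peri · max(0, V_lv+V_rv − V_peri,0), added to both ventricular
  pressures. Only ventricular volume loads the pericardium: the bench
  pericardium is the sealed box around the dual-chambered ventricular
  diaphragm, and the atria live outside it. The calibrated coupling is
  strongly asymmetric (α_lr ≪ α_rl): the clamp protocol constrains only the
  right-to-left direction.
* `BVFS`: BV plus the per-beat Frank–Starling controller.

The configuration gates the physics at parameter-packing time, so an `SV`
run is bit-identical to a `BV` run with the coupling zeroed.

**Valves.** Ideal diodes: q = max(0, ΔP)/R. No inertia, no regurgitation —
the bench uses mechanical bi-leaflet valves whose reverse leak is not
reported.

**Compliances.** The four Windkessel chambers are isothermal trapped-gas
columns: P_abs = P_ref · V_air,ref / (V_air,ref − ΔV_water), reported as
gauge pressure. Small-signal compliance at the reference point is
V_air,ref/P_ref, so chamber stiffness is set by the committed air volume,
exactly as the bench sets it with a syringe. Atria are passive linear
compliances (P = (V − V0)/C) distinct from the venous chambers; the hardware
leaves this ambiguous and the linear-atrium reading is the simpler one.

**ECMO.** Quadratic centrifugal-pump characteristic
H = c0·s² + c1·s·f + c2·f·|f| (s in RPM, f in L/min). The f·|f| form keeps
the map monotone through zero flow, since the circuit has no check valve and
transient backflow must stay well-behaved. A small branch inertance makes
pump flow a state variable (momentum balance over drainage cannula, pump and
return cannula), avoiding an algebraic loop. Defaults c0 = 2.2×10⁻⁵
mmHg/RPM², c1 = 0, c2 = −2.0 mmHg/(L/min)², cannula resistances 1.0
mmHg·s/mL each: an HVAD-like head of ~71 mmHg at 1800 RPM and ~350 mmHg at
4000 RPM with realistic cannula-dominated droop, giving positive pump flow
across the whole 1800–4000 RPM envelope against a ~60 mmHg arterial head and
~5–6 L/min at full speed. These are calibration targets, not data sheet
values; the published head-flow map of the bench pump is not reported.
The committed coefficients (c0 = 2.6×10⁻⁵, c2 = −4.0, cannula resistances
2.8 mmHg·s/mL each) describe a high-resistance oxygenator circuit: ~0.3
L/min at 1800 RPM rising to ~3 L/min at 4000 RPM against a failing-heart
arterial pressure, which keeps mAoP in the measured range at full support.
The retrograde return site sits 10% of the way down the lower-body branch —
the return cannula enters the conduit femoral artery upstream of the
arteriolar resistance — which is why return direction barely affects LAP.

**Integration.** Fixed-step classical RK4, dt = 0.25 ms (the step must
divide the beat period). Determinism and exact reproducibility are preferred
over adaptive speed. Volume conservation holds to machine precision by
construction (every flow enters one node balance positively and one
negatively), and drifts < 0.01 mL over 60 s. The kernel is written against a
flat parameter vector and compiled with numba; a pure-Python fallback of the
same code path keeps the package importable without a compiler.

## Frank–Starling controller

The bench algorithm maps mean atrial pressure to a target end-systolic
pressure (ESP) through a linear law — the analogue of the ESPVR — and
actuates ventricular drive. The twin implements this as discrete per-beat
feedback: after each completed beat,

    target = max(0, slope · mean_atrial_pressure + intercept)
    e_max ← clip(e_max · (1 + gain · (target − ESP)/max(ESP, 1)), bounds)

ESP is read at the outflow-valve-closure instant (at peak elastance if the
valve never opened). The multiplicative-relative form is scale-free and
stable; gain 0.3/beat. The published controller gives the setpoint law but
neither gains nor update rate, so per-beat integral control is a design
choice. Contractility in `BVFS` is changed through the law (slope or
intercept, or both scaled together as "the ESPVR"); in `SV`/`BV` it scales
e_max directly — mirroring the two actuation modes of the bench.

A practical stability point: end-systolic pressure at valve closure is
largely pinned by the downstream circuit (aortic or pulmonary systolic
pressure), so a setpoint above what the circuit can support shows up as
slow e_max drift toward the clip bound rather than a fixed point.
Calibration therefore derives the setpoints from the calibrated operating
point itself and verifies the interior fixed point by perturbation; the
controller additionally floors e_max just above e_min so it can weaken a
ventricle to near-passivity but never invert the elastance swing.

## Shipped presets and calibration

Four cardiac states (normal, LVF, RVF, BVF) are committed as JSON presets:
full parameter set plus the steady state they converge to (so downstream
runs and tests start at the fixed point; they re-simulate but never
re-calibrate). Calibration is two-phase. Phase A fits the hydraulics in the
controller-free BV configuration — per-side e_max and e_min, SVR/PVR
scales, circulating fluid volume, and (jointly with the normal preset) the
pericardial stiffness and slack volume — by Nelder–Mead in bound-normalised
coordinates against the measured state table, with the normal-state
objective also containing the clamp-test transmission ratio (0.47) and the
uncoupled early-transmission bound (< 10% of the RAP response in the first
3 s). Phase B then chooses each state's Frank–Starling law to pass exactly
through that fixed point (intercept = ESP − slope·atrial pressure), so the
BVFS equilibrium coincides with the calibrated BV state; the slopes are the
remaining free contractility-law choice per state (normal 18/2, LVF 12/12,
RVF and BVF 4/2 for LV/RV), picked so the controller reproduces the
Frank–Starling and ECMO findings. Every committed preset is verified to sit
at a locally stable interior controller fixed point (a 20% e_max
perturbation returns to it; a setpoint reachable only at the clip bound
would instead drift — see below). The interaction parameters are frozen
across states; in the committed presets the septal α terms calibrate to
zero and the measured 0.47 transmission is carried by the pericardial
coupling, with the transient buffering of the large pulmonary-venous
chamber setting the uncoupled floor.

The steady-state finder runs beat by beat until every beat-mean pressure
changes by < 0.1 mmHg (calibration uses 0.002 mmHg over five) over three consecutive
beats and returns the trailing ten beats; summaries are trapezoidal
beat-averages at the transducer sites of the rig (mAoP at the aortic
chamber, LAP/RAP at the atria, mPAP at the pulmonary arterial chamber,
systemic flow at the venous return into the RA, where the clamp-on probe
sits).

## Experiment protocols

* **Clamp test (ventricular interaction).** From steady state, the venous
  return resistance is multiplied by 1000 (a step to 1000×, not infinity,
  keeps the ODE nonstiff). ΔRAP and ΔLAP are means over a 10 s window after
  a 2 s blanking period, relative to the pre-clamp baseline; the
  transmission ratio is ΔLAP/ΔRAP. The clamp is then released and recovery
  to within 1 mmHg of baseline is verified. The bench reports only the
  "immediate effect"; the 2 s + 10 s window is a design choice.
* **Frank–Starling probe.** Graded clamps (×1, 2, 5, 10, 50), each run to
  steady state; LVESP and LV outflow are compared with baseline. Without the
  controller the response is outflow-dominant; with it, ESP tracks outflow.
* **Cardiac states.** Each preset is run to steady state and checked against
  its target-range row (mAoP, LAP, RAP, flow bounds).
* **Speed sweep.** 14 speeds evenly spaced over 1800–4000 RPM (so the
  LAP-on-speed regression has df (1, 12), matching the bench's reported
  statistics), holding mAoP constant. "Holding mAoP constant" is actuated by
  scaling both systemic branch resistances by a common factor found by
  bisection (≤ 25 iterations, 0.5 mmHg tolerance) — the 0D analogue of
  adjusting the bench tubing clamps; how the bench actually held mAoP is
  unstated.
* **mAoP sweep.** Targets 55–75 mmHg via the same trim at fixed speed
  (default 2600 RPM) and fixed contractility.
* **Contractility grid.** LV contractility scales × pump speeds at fixed SVR
  (no trim), recording the LAP and mAoP surfaces.
* **Direction comparison.** 7 matched speeds per return site (14
  observations, ANOVA df (1, 12)).

Statistics (simple OLS with the slope F-test, one-way ANOVA, multiple OLS)
are computed with closed-form decompositions; F tail probabilities come from
the regularized-incomplete-beta relation and are verified against numerical
integration of the F density. On a near-noiseless simulator the p-values
mirror the bench's reporting format but carry no sampling meaning, so
experiment-level checks assert signs and magnitudes, never p-values.

## Known limitation: the contractility grid at maximal support

One bench observation is not reproduced: in the coupled Frank–Starling
model the bench found LV-contractility effects on LAP abolished at pump
speeds ≥ 3400 RPM, with the grid-minimum LAP at 4000 RPM. In this twin the
corresponding grid corners (weak LV, maximal speed, fixed SVR) converge —
uniquely, including from pre-drained left-heart starts — to a dilated,
congested equilibrium: once the aortic valve closes against the
ECMO-pressurised aorta, the closed loop gives the left heart no outlet, so
LAP holds at its trapped-volume level and contractility sensitivity grows
with speed instead of vanishing. A pneumatically driven diaphragm is a
near-pressure-source whose end-systolic pressure is insensitive to load,
which is what lets the bench shed left-heart volume in that corner; a
time-varying-elastance ventricle is a volume-coupled source and cannot do
so at these operating points. The corresponding acceptance test is left
failing by design rather than weakened.

## What the twin does and does not claim

The presets are calibrated to beat-averaged operating points and the
interaction calibration to one transmission ratio; waveform morphology
(pressure wave shapes, valve timing details), fluid rheology, tubing wave
propagation and the oxygenator are not modelled, and mPAP is an emergent,
uncalibrated quantity. Passing tests show that a minimal lumped model with
one frozen interaction setting reproduces the bench's directional findings
(LAP vs speed, pressure, contractility, return site) across cardiac states;
they do not validate the twin against human physiology, and the ventricular
volumes at which it operates are diaphragm-like rather than anatomical.

### Numerical choices

dt = 0.25 ms RK4 (halving dt moves beat means < 0.05 mmHg); steady-state
tolerance 0.1 mmHg over 3 beats (interactive default), 0.02 in the
experiment harness, 0.002 over 5 in calibration;
clamp steps ×1000; SVR trim bracket [0.2, 5]×; instability guard aborts when
any volume exceeds 10× total fluid; pump envelope enforced at 1800–4000 RPM
when enabled; negative RA pressure below −5 mmHg logs a warning (no suction
model — the bench reports no suction events). Problem sizes in tests (beat
counts, sweep lengths, grid sizes) are the protocol defaults above; the
acceptance script re-simulates every preset from its committed state in a
few seconds on one core.
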