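# Methods

## Model

The circulation is a closed electrical-analog loop with six storage
elements: the single ventricle (SV) and single atrium (SA) as
time-varying elastance chambers, and four linear capacitors — systemic
arterial (C_a,s), systemic venous (C_v,s), pulmonary arterial (C_a,p) and
pulmonary venous (C_v,p). The netlist is

```
SV ──(AV diode + R_AV + R_c,s)── C_a,s ──R_a,s── C_v,s
C_v,s ──(R_v,s + R_c,p)── C_a,p ──R_a,p── C_v,p ──R_v,p── SA
C_v,s ──fenestration── SA
SA ──(AVV diode + R_AVV)── SV
```

Chamber pressure interpolates between the exponential end-diastolic
relation and the linear end-systolic relation through the raised-cosine
activation e(t) (zero outside 0 < t < 2·T_es); the atrium runs 0.02·T_c
ahead of the ventricle. Valves are ideal diodes with a small series
resistance; all other branches are linear resistors. The fenestration is
a simplified-Bernoulli orifice: ΔP = 64 Q_f²/(π² D⁴) with ΔP in mmHg,
Q_f in ml/s, D in mm, integrated in inverted form
Q_f = sign(ΔP)·(πD²/8)·√|ΔP|. The orifice is bidirectional; the equation
is symmetric and the physiological operating points examined here keep
the gradient right-to-left throughout the cycle anyway.

Internal units are mmHg, ml, s. Configuration files use the tabulated
display units (ms, beats/min) and are converted at the boundary.

### Measurement conventions

Two observables are *sites*, not states, and the choice matters at the
0.5-mmHg level the results are read at:

* **Arterial pressure (SBP/DBP)** is taken at the aortic root — the node
  between the aortic valve and the characteristic impedance,
  P_root = P(C_a,s) + Q_AV·R_c,s. This is the location an arterial line
  or cuff corresponds to; during diastole the valve is closed and the
  root rides on C_a,s, so DBP is site-independent.
* **CVP** is the cycle mean of the TCPC conduit pressure, the resistive
  divider point between R_v,s and R_c,p. In a Fontan the catheter sits
  in the conduit, where conduit and pulmonary-artery pressure coincide;
  with this convention the root→CVP pressure drop spans exactly
  R_c,s + R_a,s + R_v,s (the SVR sum) and the CVP→atrium drop spans
  R_c,p + R_a,p + R_v,p (the PVR sum), matching the clinical index
  definitions. P(C_v,s) itself sits Q_pa·R_v,s above CVP.

Cardiac index is the cycle-mean aortic valve flow over BSA; Q_p is the
cycle-mean flow entering the pulmonary arterial capacitor; Q_f the
cycle-mean orifice flow. At periodic steady state Q_s = Q_p + Q_f to
within the convergence tolerance (asserted at 0.5%).

### Oxygen balance

Arterial and mixed-venous saturations solve the two-equation system of
atrial mixing (pulmonary venous blood at S_pv_O₂ = 0.99 plus fenestration
blood at venous saturation) and whole-body consumption
(CVO₂ = 185 ml O₂·min⁻¹·m⁻², Hb = 14 g/dl, BSA = 0.58 m²). Closed form:
with k = CVO₂·BSA/(1.34·Hb·10·Q_s), SaO₂ = S_pv_O₂ − k·Q_f/Q_p and
SvO₂ = SaO₂ − k. Without intrapulmonary shunting, SpO₂ equals 99.0%
exactly when the fenestration is closed. A non-positive SvO₂ raises an
error (the configuration cannot transport the prescribed consumption)
rather than being clamped.

## Numerics

* Fixed-step classical RK4 at dt = 0.1 ms (7500 steps per 750-ms beat).
  The right-hand side is continuous but non-smooth (diode switches,
  square-root orifice), so a small fixed step replaces event detection
  and keeps every run bit-for-bit deterministic. The beat kernel is
  numba-compiled; a test pins it to the pure-Python reference equations
  at 1e-12.
* The orifice square root is linearized below |ΔP| = 1e-3 mmHg
  (√|ΔP| → |ΔP|/√ε) so the slope at ΔP = 0 is finite; the blend is
  continuous and the effect on cycle means is far below reported
  precision.
* **Steady state**: beats are integrated until the end-of-beat state
  changes < 1e-3 ml in every component (cap 200 beats). Baseline-like
  configurations converge in well under 50 beats. Total volume is
  conserved by construction (the derivative components sum to zero
  identically); a run aborts if it drifts > 1e-6 relative, or on NaN or
  runaway-negative volumes.
* **Initialization** distributes the stressed blood volume at a common
  pressure across all compartments (capacitors linearly, chambers by the
  inverted relaxed EDPVR, root-solved with Brent's method so the sum is
  exact). The periodic cycle is independent of the initializer; warm
  starts from neighbouring configurations are used only to accelerate
  convergence.
* Halving dt or tightening the periodicity tolerance tenfold changes no
  reported scalar at its printed precision (asserted at SBP/CVP < 0.05
  mmHg, others < 0.1%).

## Protocols

Every configuration is compared at a fixed systolic pressure of
87.2 mmHg: stressed blood volume is tuned on a 1-ml grid anchored at
integer multiples of the step (so the result is independent of the
starting guess). Systolic pressure is strictly increasing in SBV —
verified over every evaluation — so the tuner brackets the target by
doubling steps and bisects on the grid; this selects the same grid point
a unit-step walk would, in logarithmically many steady-state solves.
Ties between equally close grid points break toward the smaller volume.
The baseline SBV is an output of this tuning, not an input.

Sweep grids (exact decimal steps): fenestration diameter 0–4.5 mm by
0.5 mm; R_a,p 0.0001–0.5251 by 0.075 (PVRI 1.11–6.18 WU·m², paired at
0, 2.0 and 2.5 mm); E_es 13.1–3.2 by −3.3; stiffness B 0.075–0.120 by
0.015 (the baseline itself uses the tabulated 0.0753); R_a,s 0.8–5.0 by
0.7 (SVRI 9.16–49.8 WU·m²). Pathophysiology sweeps pair a 2.5-mm
fenestrated model with a non-fenestrated one at every grid value; the
non-fenestrated column is independent of which pairing was requested.

Wood-unit indices use the exact conversion 1000/60 mmHg·s/ml per Wood
unit times BSA, not the rounded coefficient sometimes quoted; the exact
factor reproduces the tabulated baseline PVRI of 1.83 WU·m².

## What the acceptance run shows — and limits

`scripts/acceptance.py` recomputes, from the built-in parameters only:
the elevated-PVR sweep (conduit pressure, stressed volume, cardiac index,
saturation, paired 0/2.5 mm), the 4.0-mm diameter configuration, and the
systolic-dysfunction (E_es = 3.2) and elevated-SVR (R_a,s = 3.6)
configurations. Everything is deterministic; `--seed` only seeds an
unused RNG for interface uniformity.

Known limitations of the reproduction:

* The source circuit is published as a figure, not a netlist; the series
  placements adopted here were selected because they reproduce the
  calibrated baseline (conduit pressure, diastolic pressure, saturation)
  from the tabulated parameters. Residual offsets remain at matched
  systolic pressure — diastolic pressure ~1.5 mmHg low, cardiac index
  ~0.1–0.2 L/min/m² high, tuned volume 2–5% low, large-orifice
  saturations a few points high. Their correlated pattern is what a
  series inertance in the aortic branch would produce (flatter, longer
  ejection); no inertial element is described in the source text, so
  none is modeled.
* One parameter at a time is varied; real physiology couples them.
* No valve regurgitation, no intrapulmonary shunts or collaterals (hence
  SpO₂ = 99% exactly when the fenestration is closed), no exercise or
  time-varying parameter schedules.
* The model is calibrated to average, not patient-specific, physiology
  of a small single-ventricle cohort (BSA 0.58 m², HR 80).
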