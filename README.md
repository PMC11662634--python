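# fontansim

A lumped-parameter (0D) hemodynamic model of the **fenestrated Fontan
circulation**, for researchers and clinicians studying when a fenestration
— a surgically created orifice between the total cavopulmonary connection
(TCPC) conduit and the single atrium — actually improves univentricular
physiology.

In a Fontan circulation the systemic venous return crosses the lungs
passively, without a subpulmonary ventricle. A fenestration acts as a
right-to-left pressure pop-off: it can decompress the systemic veins and
boost ventricular preload, at the cost of arterial desaturation. This
package implements the closed-loop circuit model of that physiology and
the experiment protocols that map out when the trade-off is favourable.

## The model

Six volume states evolve under flow balance `dV/dt = ΣQ_in − ΣQ_out`:

* **Chambers** (single ventricle SV, single atrium SA): time-varying
  elastance. Instantaneous pressure interpolates between the linear
  end-systolic relation `P_es = E_es (V − V_0)` and the exponential
  end-diastolic relation `P_ed = A (e^{B(V−V_0)} − 1)` through the
  activation `e(t) = ½(1 − cos(πt/T_es))` for `0 < t < 2T_es`, else 0.
  The atrium leads the ventricle by `DT = 0.02 T_c`.
* **Vasculature**: two modified three-element Windkessel circuits
  (characteristic impedance `R_c`, arterial resistance `R_a` and
  capacitance `C_a`, venous resistance `R_v` and capacitance `C_v`) for
  the systemic and pulmonary beds, joined in one loop.
* **Valves**: ideal diodes with small forward resistances (aortic, AV).
* **Fenestration**: a Bernoulli orifice between the systemic venous
  compartment and the atrium, `ΔP = 64 Q_f² / (π² D⁴)` (ΔP in mmHg, Q_f
  in ml/s, D in mm), integrated as `Q_f = sign(ΔP)·(πD²/8)·√|ΔP|`.
* **Oxygen**: a Fick/shunt balance couples the cycle-mean flows to the
  arterial and venous saturations:
  `SaO₂ Q_s = S_pv_O₂ Q_p + SvO₂ Q_f` and
  `CVO₂·BSA = 1.34·Hb·10·Q_s (SaO₂ − SvO₂)`.

The system is integrated with fixed-step RK4 (0.1 ms) beat by beat until
the cycle is periodic; every experiment then reduces the converged cycle
to clinical scalars (SBP/DBP at the aortic root, CVP at the TCPC conduit,
cardiac index, Q_p/Q_s/Q_f, SpO₂, and Wood-unit resistance indices).

The experiment protocols hold systolic pressure at 87.2 mmHg by tuning
the stressed blood volume (SBV) on a 1-ml grid, then sweep one parameter
at a time: fenestration diameter (0–4.5 mm), pulmonary arteriolar
resistance (PVRI 1.11–6.18 WU·m²), ventricular end-systolic elastance
(13.1–3.2 mmHg/ml), ventricular stiffness constant (0.075–0.120 /ml),
and systemic arteriolar resistance (SVRI 9.16–49.8 WU·m²), each paired
fenestrated / non-fenestrated.

## Worked example

```sh
fontansim baseline
```

tunes the built-in baseline parameter set (80 bpm, BSA 0.58 m², 2.5 mm
fenestration) to the systolic target and prints:

```
  SBP =   87.172 mmHg
  DBP =   42.657 mmHg
  CVP =   11.721 mmHg
   CI =    3.002 L/min/m^2
  Q_s =    1.741 L/min
  Q_p =    1.402 L/min
  Q_f =    0.339 L/min
 SpO2 =   91.059 %
 SvO2 =   58.212 %
  SBV =  428.000 ml
 PVRI =    1.834 WU.m^2
 SVRI =   15.926 WU.m^2
```

Read: at a stressed blood volume of 428 ml the model holds a systolic
pressure of 87.2 mmHg; the conduit (central venous) pressure is 11.7 mmHg;
about 0.34 L/min of systemic venous blood crosses the 2.5 mm fenestration
into the atrium, which brings arterial saturation down from 99% (the
closed-fenestration value) to 91%.

Other subcommands: `fontansim diameter-sweep --out d.csv`,
`fontansim scenario --name pvr --out pvr.csv` (also `ees`, `b`, `svr`),
`fontansim compare --name pvr --at 0.3001`, and
`fontansim dump-defaults` to write the commented baseline configuration
(YAML; any field can be overridden and passed back with `--config`).

The same functionality is available as a library:

```python
from fontansim import default_parameters, run_scenario, compare_fenestration

result = run_scenario(default_parameters(), "pvr")
print(compare_fenestration(result, at_value=0.3001))   # fen − no-fen deltas
```

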