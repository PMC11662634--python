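"""Reduction of a converged cycle to clinically reported scalars.

Pressures: systolic/diastolic BP are the max/min of the aortic-root
pressure over the cycle — the node between the aortic valve and the
characteristic impedance, ``P_Ca,s + Q_AV * R_c,s``, which is the point
the clinical cuff/arterial-line values correspond to (during diastole the
valve is closed and the root rides on the arterial capacitor, so DBP is
unaffected by the choice).  CVP is the time-average of the systemic
venous / TCPC conduit node.  Flows are
cycle means converted to L/min.  Oxygen saturations come from a Fick
balance: fenestration blood entering the atrium carries systemic venous
saturation, and the arterio-venous difference carries the whole-body O2
consumption.  Resistance sums convert to Wood units (mmHg per L/min) via
the exact factor 1000/60 and are indexed by body surface area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import FontanModelError, ModelParameters
from .simulate import BeatSeries

__all__ = [
    "OxygenParams",
    "HemodynamicSummary",
    "OxygenError",
    "oxygen_saturations",
    "resistance_index",
    "pvri",
    "svri",
    "summarize",
    "ML_S_TO_L_MIN",
    "WOOD_PER_MMHG_S_ML",
]

#: ml/s -> L/min
ML_S_TO_L_MIN = 0.06
#: mmHg·s/ml -> Wood units (mmHg per L/min)
WOOD_PER_MMHG_S_ML = 1000.0 / 60.0
#: steady-state continuity tolerance for Q_s = Q_p + Q_f, relative
FLOW_BALANCE_RTOL = 5e-3


class OxygenError(FontanModelError):
    """The oxygen balance has no physiological solution at these flows."""


@dataclass(frozen=True)
class OxygenParams:
    """Constants of the oxygen-saturation balance.

    S_pv_O2 : pulmonary venous saturation (fraction; no intrapulmonary
    shunt, so this is also SpO2 without a fenestration).  CVO2 : whole-body
    oxygen consumption, ml O2/min/m^2.  Hb : hemoglobin, g/dl.  BSA : body
    surface area, m^2.  hb_o2_capacity (ml O2 per g Hb) and dl_per_l are
    the usual content-conversion constants.
    """

    S_pv_O2: float = 0.99
    CVO2: float = 185.0
    Hb: float = 14.0
    BSA: float = 0.58
    hb_o2_capacity: float = 1.34
    dl_per_l: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.S_pv_O2 <= 1):
            raise ValueError("S_pv_O2 must be in (0, 1]")
        for name in ("CVO2", "Hb", "BSA", "hb_o2_capacity", "dl_per_l"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class HemodynamicSummary:
    """Per-configuration scalars in the units they are reported in."""

    SBP: float    # mmHg
    DBP: float    # mmHg
    CVP: float    # mmHg
    CI: float     # L/min/m^2
    Q_s: float    # L/min
    Q_p: float    # L/min
    Q_f: float    # L/min
    SpO2: float   # percent
    SvO2: float   # percent
    SBV: float    # ml
    PVRI: float   # Wood units * m^2
    SVRI: float   # Wood units * m^2

    def to_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def oxygen_saturations(
    Q_s: float, Q_p: float, Q_f: float, ox: OxygenParams | None = None
) -> tuple[float, float]:
    """Solve the shunt-mixing / Fick system for (SaO2, SvO2), fractions.

    The atrium mixes pulmonary venous blood (saturation ``S_pv_O2``) with
    fenestration blood at systemic venous saturation, and the whole-body
    consumption fixes the arterio-venous difference::

        SaO2 * Q_s = S_pv_O2 * Q_p + SvO2 * Q_f
        CVO2 * BSA = 1.34 * Hb * 10 * Q_s * (SaO2 - SvO2)

    Flows in L/min with ``Q_s = Q_p + Q_f``.  Closed form: with
    ``k = CVO2*BSA / (1.34*Hb*10*Q_s)``, ``SaO2 = S_pv_O2 - k*Q_f/Q_p`` and
    ``SvO2 = SaO2 - k``.  Net left-to-right shunting (Q_f < 0) removes the
    venous admixture, so SaO2 = S_pv_O2 there.  A non-positive SvO2 means
    the configuration cannot transport the prescribed consumption and is
    reported as an error rather than clamped.
    """
    ox = ox or OxygenParams()
    if Q_s <= 0 or Q_p <= 0:
        raise OxygenError("Q_s and Q_p must be positive")
    if abs(Q_s - (Q_p + Q_f)) > FLOW_BALANCE_RTOL * Q_s:
        raise OxygenError(
            f"flow continuity violated: Q_s={Q_s:.4f} vs Q_p+Q_f={Q_p + Q_f:.4f} L/min"
        )
    k = ox.CVO2 * ox.BSA / (ox.hb_o2_capacity * ox.Hb * ox.dl_per_l * Q_s)
    SaO2 = ox.S_pv_O2 - k * (Q_f / Q_p if Q_f > 0 else 0.0)
    SvO2 = SaO2 - k
    if SvO2 <= 0:
        raise OxygenError("oxygen transport infeasible at this flow")
    return SaO2, SvO2


def resistance_index(R_sum: float, BSA: float) -> float:
    """Indexed vascular resistance, Wood units * m^2.

    Converts a resistance sum in mmHg·s/ml to Wood units with the exact
    factor 1000/60 and multiplies by BSA.  Linear in both arguments.
    """
    if R_sum <= 0:
        raise ValueError("R_sum must be > 0")
    return R_sum * WOOD_PER_MMHG_S_ML * BSA


def pvri(params: ModelParameters) -> float:
    """Pulmonary vascular resistance index of a parameter set."""
    return resistance_index(params.pulmonary.total_resistance, params.BSA)


def svri(params: ModelParameters) -> float:
    """Systemic vascular resistance index of a parameter set."""
    return resistance_index(params.systemic.total_resistance, params.BSA)


def aortic_root_pressure(beat: BeatSeries, params: ModelParameters) -> np.ndarray:
    """Pressure at the aortic root (between AV valve and R_c,s), mmHg.

    Equals the systemic arterial capacitor pressure plus the ejection
    flow's drop across the characteristic impedance; identical to the
    capacitor pressure whenever the valve is closed.
    """
    return beat.pressure("P_Ca_s") + beat.flow("Q_AV") * params.systemic.R_c


def summarize(
    beat: BeatSeries,
    params: ModelParameters,
    ox: OxygenParams | None = None,
) -> HemodynamicSummary:
    """Reduce a converged beat to the reported scalar set.

    By default the oxygen constants use the model's BSA; pass ``ox``
    explicitly to decouple them.
    """
    if not beat.converged:
        raise FontanModelError("refusing to summarize a non-converged beat")
    if ox is None:
        ox = OxygenParams(BSA=params.BSA)

    P_art = aortic_root_pressure(beat, params)
    Q_s = beat.cycle_mean(beat.flow("Q_AV")) * ML_S_TO_L_MIN
    Q_p = beat.cycle_mean(beat.flow("Q_pa")) * ML_S_TO_L_MIN
    Q_f = beat.cycle_mean(beat.flow("Q_f")) * ML_S_TO_L_MIN
    SaO2, SvO2 = oxygen_saturations(Q_s, Q_p, Q_f, ox)
    return HemodynamicSummary(
        SBP=float(P_art.max()),
        DBP=float(P_art.min()),
        CVP=beat.cycle_mean(beat.pressure("P_TCPC")),
        CI=Q_s / params.BSA,
        Q_s=Q_s,
        Q_p=Q_p,
        Q_f=Q_f,
        SpO2=100.0 * SaO2,
        SvO2=100.0 * SvO2,
        SBV=beat.SBV,
        PVRI=pvri(params),
        SVRI=svri(params),
    )
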