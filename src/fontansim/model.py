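"""Element equations of a lumped-parameter (0D) fenestrated Fontan circulation.

The circulation is a closed electrical-analog circuit with six volume states:

* two time-varying elastance chambers — the single ventricle (SV) and single
  atrium (SA) of the univentricular heart;
* four linear capacitors — systemic arterial/venous (C_a,s / C_v,s) and
  pulmonary arterial/venous (C_a,p / C_v,p) beds of two modified
  three-element Windkessel circuits.

Connecting elements are linear resistors, two diode valves (aortic and
atrioventricular), and a Bernoulli-orifice fenestration shunting the
systemic venous node (the TCPC conduit, whose pressure is the model's CVP)
to the single atrium.

Internal units are fixed: pressure mmHg, volume ml, time s, flow ml/s,
resistance mmHg·s/ml, capacitance ml/mmHg, fenestration diameter mm.
Milliseconds and beats/min appear only at the configuration boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FontanModelError",
    "ParameterError",
    "ChamberParams",
    "WindkesselParams",
    "ValveParams",
    "FenestrationParams",
    "TimingParams",
    "ModelParameters",
    "STATE_LABELS",
    "PRESSURE_LABELS",
    "FLOW_LABELS",
    "normalized_elastance",
    "chamber_pressure",
    "capacitor_pressure",
    "valve_flow",
    "fenestration_flow",
    "tcpc_pressure",
    "compartment_pressures",
    "network_flows",
    "state_derivative",
]

#: order of the six volume states, everywhere in the package
STATE_LABELS = ("V_SV", "V_SA", "V_Ca_s", "V_Cv_s", "V_Ca_p", "V_Cv_p")
#: compartment pressures (state order) plus the TCPC conduit junction node
PRESSURE_LABELS = ("P_SV", "P_SA", "P_Ca_s", "P_Cv_s", "P_Ca_p", "P_Cv_p", "P_TCPC")
#: branch flows of the circuit
FLOW_LABELS = ("Q_AV", "Q_as", "Q_pa", "Q_ap", "Q_pv", "Q_f", "Q_AVV")

#: default regularization half-width for the orifice square root, mmHg
FENESTRATION_EPS = 1e-3


class FontanModelError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(FontanModelError, ValueError):
    """A parameter violates its physical/structural constraints."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


# ---------------------------------------------------------------------------
# parameter bundles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChamberParams:
    """Time-varying elastance chamber.

    Parameters
    ----------
    E_es : float
        End-systolic elastance (slope of the linear ESPVR), mmHg/ml.
    A : float
        Scaling factor of the exponential EDPVR, mmHg.
    B : float
        Exponent (stiffness constant) of the EDPVR, 1/ml.
    V_0 : float
        Unstressed volume at which end-systolic pressure is zero, ml.
    T_es : float
        Time from onset of systole to end systole, s.
    """

    E_es: float
    A: float
    B: float
    V_0: float
    T_es: float

    def __post_init__(self) -> None:
        _require(self.E_es > 0, f"E_es must be > 0, got {self.E_es}")
        _require(self.A >= 0, f"A must be >= 0, got {self.A}")
        _require(self.B > 0, f"B must be > 0, got {self.B}")
        _require(self.V_0 >= 0, f"V_0 must be >= 0, got {self.V_0}")
        _require(self.T_es > 0, f"T_es must be > 0, got {self.T_es}")


@dataclass(frozen=True)
class WindkesselParams:
    """Modified three-element Windkessel with an added venous compartment.

    All resistances in mmHg·s/ml; capacitances in ml/mmHg. ``R_c`` is the
    characteristic impedance proximal to the arterial capacitor, ``R_a`` the
    lumped arteriolar resistance, ``R_v`` the resistance proximal to the
    venous capacitor.
    """

    R_c: float
    R_a: float
    R_v: float
    C_a: float
    C_v: float

    def __post_init__(self) -> None:
        for name in ("R_c", "R_a", "R_v", "C_a", "C_v"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")

    @property
    def total_resistance(self) -> float:
        """R_c + R_a + R_v, the vascular-bed resistance summed for indices."""
        return self.R_c + self.R_a + self.R_v


@dataclass(frozen=True)
class ValveParams:
    """Ideal diode in series with a small forward resistance, mmHg·s/ml."""

    R_fwd: float

    def __post_init__(self) -> None:
        _require(self.R_fwd > 0, f"R_fwd must be > 0, got {self.R_fwd}")


@dataclass(frozen=True)
class FenestrationParams:
    """Bernoulli orifice between the TCPC conduit and the single atrium.

    ``D`` is the effective diameter in mm; ``D = 0`` closes the shunt.
    """

    D: float
    eps: float = FENESTRATION_EPS

    def __post_init__(self) -> None:
        _require(self.D >= 0, f"fenestration diameter must be >= 0, got {self.D}")
        _require(self.eps > 0, "regularization eps must be > 0")


@dataclass(frozen=True)
class TimingParams:
    """Cardiac timing: heart rate, cycle length and atrial lead interval.

    The atrium activates ``DT = DT_fraction * T_c`` before the ventricle.
    """

    HR: float
    T_c: float | None = None
    DT_fraction: float = 0.02

    def __post_init__(self) -> None:
        _require(self.HR > 0, f"HR must be > 0, got {self.HR}")
        derived = 60.0 / self.HR
        if self.T_c is None:
            object.__setattr__(self, "T_c", derived)
        else:
            _require(
                abs(self.T_c - derived) <= 1e-9 * derived,
                f"T_c ({self.T_c} s) inconsistent with HR {self.HR} bpm "
                f"(expected {derived} s)",
            )
        _require(0 <= self.DT_fraction < 0.5, "DT_fraction must be in [0, 0.5)")

    @property
    def DT(self) -> float:
        """Atrial activation lead time, s."""
        return self.DT_fraction * self.T_c


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter bundle of the fenestrated Fontan circuit."""

    SV: ChamberParams
    SA: ChamberParams
    AV: ValveParams
    AVV: ValveParams
    systemic: WindkesselParams
    pulmonary: WindkesselParams
    fenestration: FenestrationParams
    timing: TimingParams
    BSA: float = 0.58

    def __post_init__(self) -> None:
        _require(self.BSA > 0, f"BSA must be > 0, got {self.BSA}")
        for cc in (self.SV, self.SA):
            _require(
                2.0 * cc.T_es <= self.timing.T_c,
                f"chamber systole too long: 2*T_es={2 * cc.T_es} s exceeds "
                f"T_c={self.timing.T_c} s",
            )


# ---------------------------------------------------------------------------
# element equations
# ---------------------------------------------------------------------------

def normalized_elastance(t: float, T_es: float) -> float:
    """Normalized activation e(t) of a chamber, dimensionless in [0, 1].

    Raised-cosine during systole, zero in diastole::

        e(t) = 0.5 * (1 - cos(pi * t / T_es))   for 0 < t < 2*T_es
        e(t) = 0                                 otherwise

    ``t`` is the time since chamber activation, already reduced into one
    cardiac cycle [0, T_c); the caller is responsible for the modulo.
    Continuous everywhere (both branches vanish at t = 2*T_es), with
    e(T_es) = 1 at end systole.
    """
    if t <= 0.0 or t >= 2.0 * T_es:
        return 0.0
    return 0.5 * (1.0 - math.cos(math.pi * t / T_es))


def chamber_pressure(V: float, phase_t: float, p: ChamberParams) -> float:
    """Instantaneous chamber pressure, mmHg.

    Interpolates between the exponential end-diastolic relation
    ``P_ed = A * (exp(B*(V - V_0)) - 1)`` and the linear end-systolic
    relation ``P_es = E_es * (V - V_0)`` with the activation
    ``e(phase_t)``.  Negative pressures for ``V < V_0`` are permitted (the
    EDPVR is negative there); with the baseline ``V_0 = 0`` they cannot
    arise from nonnegative volumes.
    """
    e = normalized_elastance(phase_t, p.T_es)
    dV = V - p.V_0
    P_es = p.E_es * dV
    P_ed = p.A * math.expm1(p.B * dV)
    return e * P_es + (1.0 - e) * P_ed


def capacitor_pressure(V: float, C: float) -> float:
    """Linear capacitor: P = V / C (mmHg)."""
    return V / C


def valve_flow(P_up: float, P_down: float, R: float) -> float:
    """Ideal diode + series resistor: Q = max(0, P_up - P_down) / R (ml/s)."""
    dP = P_up - P_down
    return dP / R if dP > 0.0 else 0.0


def fenestration_flow(dP: float, D: float, eps: float = FENESTRATION_EPS) -> float:
    """Bernoulli orifice flow through the fenestration, ml/s.

    Inverts the simplified Bernoulli drop ``dP = 64 * Q_f^2 / (pi^2 * D^4)``
    (dP in mmHg, velocity in m/s) to::

        Q_f = sign(dP) * (pi * D^2 / 8) * sqrt(|dP|)

    with Q_f in ml/s when D is in mm — the unit bookkeeping works out
    because ml/s over mm^2 is numerically m/s.  Flow is bidirectional;
    positive dP (conduit above atrium) drives right-to-left flow into the
    atrium.  For ``|dP| < eps`` the square root is replaced by the linear
    blend ``|dP| / sqrt(eps)`` so the slope stays finite at dP = 0
    (continuous at the switch; the effect on cycle averages is negligible).
    """
    if D <= 0.0:
        return 0.0
    a = math.pi * D * D / 8.0
    ad = abs(dP)
    mag = a * (ad / math.sqrt(eps) if ad < eps else math.sqrt(ad))
    return math.copysign(mag, dP)


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------

def tcpc_pressure(P_Cv_s: float, P_Ca_p: float, R_v_s: float, R_c_p: float) -> float:
    """Pressure of the TCPC conduit / pulmonary artery, mmHg.

    The conduit is the storage-free point between the systemic venous
    resistance and the pulmonary characteristic impedance; the series flow
    through both resistors makes it the resistive divider

        P = (P_Cv,s / R_v,s + P_Ca,p / R_c,p) / (1/R_v,s + 1/R_c,p)

    This is where a catheter reads Fontan "CVP" (conduit = PA pressure);
    it is a derived observable, not a state.
    """
    gv, gc = 1.0 / R_v_s, 1.0 / R_c_p
    return (P_Cv_s * gv + P_Ca_p * gc) / (gv + gc)


def compartment_pressures(state: np.ndarray, t: float, params: ModelParameters) -> np.ndarray:
    """Pressures of the six storage compartments plus the TCPC node, mmHg.

    The ventricle runs on phase ``t mod T_c``; the atrium leads it by DT,
    i.e. runs on phase ``(t + DT) mod T_c``.  The seventh entry is the
    derived TCPC conduit pressure (see :func:`tcpc_pressure`).
    """
    Tc = params.timing.T_c
    tv = t % Tc
    ta = (t + params.timing.DT) % Tc
    s, p = params.systemic, params.pulmonary
    P_Cv_s = capacitor_pressure(state[3], s.C_v)
    P_Ca_p = capacitor_pressure(state[4], p.C_a)
    return np.array(
        [
            chamber_pressure(state[0], tv, params.SV),
            chamber_pressure(state[1], ta, params.SA),
            capacitor_pressure(state[2], s.C_a),
            P_Cv_s,
            P_Ca_p,
            capacitor_pressure(state[5], p.C_v),
            tcpc_pressure(P_Cv_s, P_Ca_p, s.R_v, p.R_c),
        ]
    )


def network_flows(state: np.ndarray, t: float, params: ModelParameters) -> tuple[np.ndarray, np.ndarray]:
    """Compartment pressures and the seven branch flows at time ``t``.

    Circuit topology — two modified Windkessels in one loop, with the
    fenestration shunting the systemic venous compartment into the
    atrium::

        SV --(AV diode + R_AV + R_c,s)--> C_a,s --R_a,s--> C_v,s
        C_v,s --(R_v,s + R_c,p)--> C_a,p --R_a,p--> C_v,p --R_v,p--> SA
        C_v,s --fenestration--> SA
        SA --(AVV diode + R_AVV)--> SV

    The reported CVP is not P(C_v,s) itself but the TCPC conduit pressure
    at the divider point between R_v,s and R_c,p (the catheter site in a
    Fontan, where conduit = PA pressure).  Returns ``(pressures, flows)``
    ordered as :data:`PRESSURE_LABELS` and :data:`FLOW_LABELS`.
    """
    P = compartment_pressures(state, t, params)
    s, p = params.systemic, params.pulmonary
    P_SV, P_SA, P_Ca_s, P_Cv_s, P_Ca_p, P_Cv_p, P_J = P
    Q = np.array(
        [
            valve_flow(P_SV, P_Ca_s, params.AV.R_fwd + s.R_c),
            (P_Ca_s - P_Cv_s) / s.R_a,
            (P_Cv_s - P_Ca_p) / (s.R_v + p.R_c),
            (P_Ca_p - P_Cv_p) / p.R_a,
            (P_Cv_p - P_SA) / p.R_v,
            fenestration_flow(P_Cv_s - P_SA, params.fenestration.D, params.fenestration.eps),
            valve_flow(P_SA, P_SV, params.AVV.R_fwd),
        ]
    )
    return P, Q


def state_derivative(state: np.ndarray, t: float, params: ModelParameters) -> np.ndarray:
    """dV/dt for the six compartments, ml/s (reference implementation).

    Each compartment's rate is inflow minus outflow; the components sum to
    zero identically because the circuit is closed (the fenestration moves
    volume internally).  The compiled integrator kernel in
    :mod:`fontansim.simulate` mirrors this function exactly.
    """
    _, Q = network_flows(state, t, params)
    Q_AV, Q_as, Q_pa, Q_ap, Q_pv, Q_f, Q_AVV = Q
    return np.array(
        [
            Q_AVV - Q_AV,          # single ventricle
            Q_pv + Q_f - Q_AVV,    # single atrium
            Q_AV - Q_as,           # systemic arterial
            Q_as - Q_pa - Q_f,     # systemic venous / TCPC conduit
            Q_pa - Q_ap,           # pulmonary arterial
            Q_ap - Q_pv,           # pulmonary venous
        ]
    )
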