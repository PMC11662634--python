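"""Element equations: elastance, chamber/capacitor pressures, valves,
fenestration orifice, and the assembled network derivative."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from fontansim import (
    ChamberParams,
    FenestrationParams,
    ModelParameters,
    ParameterError,
    TimingParams,
    ValveParams,
    WindkesselParams,
    chamber_pressure,
    capacitor_pressure,
    fenestration_flow,
    network_flows,
    normalized_elastance,
    state_derivative,
    valve_flow,
)
from fontansim.model import FLOW_LABELS, compartment_pressures


# ---------------------------------------------------------------------------
# normalized elastance
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "t, T_es, expected",
    [
        (0.0, 0.200, 0.0),        # activation starts from zero
        (0.200, 0.200, 1.0),      # peak at end systole
        (0.100, 0.200, 0.5),      # half-activation mid-systole
        (0.450, 0.200, 0.0),      # fully relaxed after 2*T_es
        (0.400, 0.200, 0.0),      # both branches vanish at the junction
    ],
)
def test_elastance_reference_points(t, T_es, expected):
    assert normalized_elastance(t, T_es) == pytest.approx(expected, abs=1e-12)


@given(st.floats(0.0, 0.7499), st.floats(0.05, 0.37))
@hyp_settings(derandomize=True, max_examples=200)
def test_elastance_bounded_and_continuous(t, T_es):
    e = normalized_elastance(t, T_es)
    assert 0.0 <= e <= 1.0
    # continuity at the systole/diastole junction
    h = 1e-9
    lhs = normalized_elastance(2 * T_es - h, T_es)
    rhs = normalized_elastance(2 * T_es + h, T_es)
    assert abs(lhs - rhs) < 1e-6


# ---------------------------------------------------------------------------
# chamber pressure
# ---------------------------------------------------------------------------

SV_CHAMBER = ChamberParams(E_es=13.1, A=1.15, B=0.0753, V_0=0.0, T_es=0.200)


def test_chamber_pressure_pure_espvr():
    # at end systole (e = 1) the linear relation alone applies
    assert chamber_pressure(10.0, 0.200, SV_CHAMBER) == pytest.approx(131.0)


def test_chamber_pressure_vanishes_at_unstressed_volume():
    for phase in (0.0, 0.1, 0.2, 0.5):
        assert chamber_pressure(SV_CHAMBER.V_0, phase, SV_CHAMBER) == pytest.approx(0.0)


def test_chamber_pressure_pure_edpvr():
    # relaxed chamber (e = 0): independent evaluation of the exponential law
    expected = 1.15 * (math.exp(0.0753 * 30.0) - 1.0)
    assert expected == pytest.approx(9.86, abs=5e-3)
    assert chamber_pressure(30.0, 0.500, SV_CHAMBER) == pytest.approx(expected)


@given(st.floats(0.0, 80.0), st.floats(0.0, 80.0), st.floats(0.0, 0.7499))
@hyp_settings(derandomize=True, max_examples=200)
def test_chamber_pressure_monotone_in_volume(v1, v2, phase):
    lo, hi = sorted((v1, v2))
    assert chamber_pressure(lo, phase, SV_CHAMBER) <= chamber_pressure(hi, phase, SV_CHAMBER) + 1e-12


# ---------------------------------------------------------------------------
# capacitor, valve, orifice
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("V, C, expected", [(24.2, 24.2, 1.0), (0.0, 5.0, 0.0), (3.97, 3.97, 1.0)])
def test_capacitor_pressure(V, C, expected):
    assert capacitor_pressure(V, C) == pytest.approx(expected)


@pytest.mark.parametrize(
    "up, down, R, expected",
    [(10.0, 20.0, 0.001, 0.0), (21.0, 20.0, 0.001, 1000.0), (15.0, 15.0, 0.001, 0.0)],
)
def test_valve_is_a_diode(up, down, R, expected):
    assert valve_flow(up, down, R) == pytest.approx(expected)


def test_fenestration_flow_inverts_the_orifice_law():
    q = fenestration_flow(4.0, 2.5)
    assert q == pytest.approx(math.pi * 6.25 / 8.0 * 2.0)
    assert q == pytest.approx(4.909, abs=1e-3)
    # forward check: the pressure drop recovered from the flow
    assert 64.0 * q**2 / (math.pi**2 * 2.5**4) == pytest.approx(4.0)


def test_fenestration_closed_or_balanced_is_zero():
    assert fenestration_flow(0.0, 2.5) == 0.0
    assert fenestration_flow(4.0, 0.0) == 0.0


def test_fenestration_flow_is_odd_and_regularized():
    assert fenestration_flow(-4.0, 2.5) == -fenestration_flow(4.0, 2.5)
    eps = 1e-3
    # continuous across the linear-blend boundary and finite slope at zero
    below = fenestration_flow(eps * (1 - 1e-9), 2.5, eps)
    above = fenestration_flow(eps * (1 + 1e-9), 2.5, eps)
    assert below == pytest.approx(above, rel=1e-6)
    assert fenestration_flow(1e-12, 2.5, eps) == pytest.approx(
        math.pi * 6.25 / 8.0 * 1e-12 / math.sqrt(eps)
    )


# ---------------------------------------------------------------------------
# parameter validation
# ---------------------------------------------------------------------------

def test_invalid_parameters_are_rejected(params):
    with pytest.raises(ParameterError):
        FenestrationParams(D=-1.0)
    with pytest.raises(ParameterError):
        ChamberParams(E_es=0.0, A=1.0, B=0.1, V_0=0.0, T_es=0.2)
    with pytest.raises(ParameterError):
        ValveParams(R_fwd=0.0)
    with pytest.raises(ParameterError):
        WindkesselParams(R_c=0.1, R_a=1.0, R_v=0.05, C_a=0.0, C_v=24.0)
    with pytest.raises(ParameterError):
        TimingParams(HR=80.0, T_c=0.700)  # inconsistent with 60/HR
    with pytest.raises(ParameterError):
        # chamber systole longer than half the cycle
        ModelParameters(
            SV=ChamberParams(E_es=13.1, A=1.15, B=0.0753, V_0=0.0, T_es=0.4),
            SA=params.SA, AV=params.AV, AVV=params.AVV,
            systemic=params.systemic, pulmonary=params.pulmonary,
            fenestration=params.fenestration, timing=params.timing,
        )


# ---------------------------------------------------------------------------
# assembled network
# ---------------------------------------------------------------------------

@given(st.lists(st.floats(0.5, 400.0), min_size=6, max_size=6), st.floats(0.0, 1.5))
@hyp_settings(derandomize=True, max_examples=100)
def test_derivative_conserves_volume(params, volumes, t):
    dy = state_derivative(np.array(volumes), t, params)
    assert abs(dy.sum()) < 1e-9 * max(1.0, np.max(np.abs(dy)))


def test_equal_pressures_give_zero_derivative(params):
    # all compartments at 1 mmHg during diastole, valves shut, no gradients;
    # chambers hold the relaxed volume giving exactly 1 mmHg
    s, p = params.systemic, params.pulmonary
    v_ch = [math.log1p(1.0 / c.A) / c.B for c in (params.SV, params.SA)]
    state = np.array([v_ch[0], v_ch[1], s.C_a, s.C_v, p.C_a, p.C_v])
    dy = state_derivative(state, 0.5, params)
    assert np.allclose(dy, 0.0, atol=1e-9)


def test_derivative_matches_hand_assembled_flow_balance(params, rng):
    """Oracle: re-derive every branch flow from the pressure list by hand."""
    state = rng.uniform(2.0, 120.0, size=6)
    t = 0.137
    s, p = params.systemic, params.pulmonary
    Tc = params.timing.T_c
    P_SV = chamber_pressure(state[0], t % Tc, params.SV)
    P_SA = chamber_pressure(state[1], (t + params.timing.DT) % Tc, params.SA)
    P_Ca_s, P_Cv_s = state[2] / s.C_a, state[3] / s.C_v
    P_Ca_p, P_Cv_p = state[4] / p.C_a, state[5] / p.C_v
    Q_AV = max(0.0, P_SV - P_Ca_s) / (params.AV.R_fwd + s.R_c)
    Q_as = (P_Ca_s - P_Cv_s) / s.R_a
    Q_pa = (P_Cv_s - P_Ca_p) / (s.R_v + p.R_c)
    Q_ap = (P_Ca_p - P_Cv_p) / p.R_a
    Q_pv = (P_Cv_p - P_SA) / p.R_v
    dP = P_Cv_s - P_SA
    Q_f = math.copysign(math.pi * 2.5**2 / 8.0 * math.sqrt(abs(dP)), dP)
    Q_AVV = max(0.0, P_SA - P_SV) / params.AVV.R_fwd
    expected = np.array(
        [
            Q_AVV - Q_AV,
            Q_pv + Q_f - Q_AVV,
            Q_AV - Q_as,
            Q_as - Q_pa - Q_f,
            Q_pa - Q_ap,
            Q_ap - Q_pv,
        ]
    )
    np.testing.assert_allclose(state_derivative(state, t, params), expected, rtol=1e-12)


def test_closed_fenestration_equals_removed_branch(params, rng):
    """D = 0 reproduces a hand-built model with no fenestration branch."""
    from dataclasses import replace

    closed = replace(params, fenestration=FenestrationParams(D=0.0))
    for _ in range(5):
        state = rng.uniform(1.0, 150.0, size=6)
        t = float(rng.uniform(0.0, 0.75))
        P, Q = network_flows(state, t, closed)
        assert Q[FLOW_LABELS.index("Q_f")] == 0.0
        # removed-branch model: same network with the fenestration term absent
        dy = state_derivative(state, t, closed)
        Q_AV, Q_as, Q_pa, Q_ap, Q_pv, _, Q_AVV = Q
        expected = np.array(
            [Q_AVV - Q_AV, Q_pv - Q_AVV, Q_AV - Q_as, Q_as - Q_pa, Q_pa - Q_ap, Q_ap - Q_pv]
        )
        np.testing.assert_array_equal(dy, expected)


def test_tcpc_node_is_the_series_divider(params, rng):
    state = rng.uniform(2.0, 120.0, size=6)
    P = compartment_pressures(state, 0.3, params)
    s, p = params.systemic, params.pulmonary
    gv, gc = 1 / s.R_v, 1 / p.R_c
    assert P[6] == pytest.approx((P[3] * gv + P[4] * gc) / (gv + gc), rel=1e-12)
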