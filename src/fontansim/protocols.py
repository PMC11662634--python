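"""Experiment protocols: SBV tuning and parameter sweeps.

Every experimental configuration is compared at a fixed systolic blood
pressure (87.2 mmHg by default): the stressed blood volume (SBV) is
adjusted on a 1-ml grid until systolic pressure at the systemic arterial
node matches the target as closely as the grid allows.  Systolic pressure
is strictly increasing in SBV (checked at run time), so the tuned value is
unique; the search brackets the target by doubling steps and then bisects
on the grid, which lands on the same grid point as a unit-step walk.

Sweeps reproduce the study's four pathophysiology scenarios plus the
fenestration-diameter sweep, each run for fenestrated and non-fenestrated
model variants at matched swept values:

* ``pvr``      — pulmonary arteriolar resistance R_a,p from 0.0001 to
                 0.5251 mmHg·s/ml in 0.075 steps (PVRI 1.11 to 6.18 WU·m²)
* ``ees``      — ventricular end-systolic elastance 13.1 down to 3.2
                 mmHg/ml in 3.3 steps (systolic dysfunction)
* ``b``        — ventricular stiffness constant 0.075 to 0.120 /ml in
                 0.015 steps (diastolic dysfunction)
* ``svr``      — systemic arteriolar resistance R_a,s from 0.8 to 5.0
                 mmHg·s/ml in 0.7 steps (SVRI 9.16 to 49.8 WU·m²)
* ``diameter`` — fenestration diameter 0 to 4.5 mm in 0.5 mm steps
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model import FontanModelError, ModelParameters
from .report import (
    HemodynamicSummary,
    OxygenParams,
    aortic_root_pressure,
    pvri,
    summarize,
    svri,
)
from .simulate import BeatSeries, IntegratorSettings, run_to_steady_state

__all__ = [
    "TuningSpec",
    "TuningError",
    "ProtocolError",
    "ScenarioGrid",
    "SweepResult",
    "SCENARIO_NAMES",
    "tune_sbv",
    "standard_grid",
    "set_swept_parameter",
    "run_scenario",
    "compare_fenestration",
    "baseline",
]

logger = logging.getLogger(__name__)

SCENARIO_NAMES = ("diameter", "pvr", "ees", "b", "svr")

#: default SBV starting guess for the tuner, ml; the tuned result does not
#: depend on it (the grid is anchored at integer multiples of the step)
DEFAULT_START_SBV = 450.0


class TuningError(FontanModelError):
    """SBV tuning failed (non-monotone response or iteration budget)."""


class ProtocolError(FontanModelError):
    """A sweep or comparison request is inconsistent."""


@dataclass(frozen=True)
class TuningSpec:
    """Target and grid of the SBV-tuning loop."""

    target_SBP: float = 87.2   # mmHg
    step: float = 1.0          # ml
    max_iters: int = 200       # steady-state evaluations allowed per tune

    def __post_init__(self) -> None:
        if self.target_SBP <= 0:
            raise ValueError("target_SBP must be > 0")
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.max_iters < 4:
            raise ValueError("max_iters must be >= 4")


@dataclass(frozen=True)
class ScenarioGrid:
    """A named sweep: the parameter values and the paired diameters."""

    name: str
    values: tuple[float, ...]
    fenestration_diameters: tuple[float, ...] = (0.0, 2.5)

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ProtocolError(f"unknown scenario {self.name!r}; expected one of {SCENARIO_NAMES}")
        v = self.values
        if len(v) == 0:
            raise ProtocolError("scenario values must be nonempty")
        d = np.diff(v)
        if len(v) > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ProtocolError("scenario values must be strictly monotone")


@dataclass
class SweepResult:
    """Tidy table of one :class:`HemodynamicSummary` per grid cell."""

    scenario: str
    table: pd.DataFrame

    def row(self, value: float, D: float) -> pd.Series:
        t = self.table
        sel = t[(np.isclose(t["value"], value)) & (np.isclose(t["D_mm"], D))]
        if len(sel) != 1:
            raise ProtocolError(
                f"no unique row for value={value}, D={D} in scenario {self.scenario!r}"
            )
        return sel.iloc[0]


def standard_grid(name: str) -> ScenarioGrid:
    """The study's sweep grid for a scenario, with exact decimal steps."""
    if name == "diameter":
        return ScenarioGrid("diameter", tuple(round(0.5 * k, 1) for k in range(10)))
    if name == "pvr":
        return ScenarioGrid(
            "pvr",
            tuple(round(0.0001 + 0.075 * k, 4) for k in range(8)),
            fenestration_diameters=(0.0, 2.0, 2.5),
        )
    if name == "ees":
        return ScenarioGrid("ees", tuple(round(13.1 - 3.3 * k, 1) for k in range(4)))
    if name == "b":
        return ScenarioGrid("b", tuple(round(0.075 + 0.015 * k, 3) for k in range(4)))
    if name == "svr":
        return ScenarioGrid("svr", tuple(round(0.8 + 0.7 * k, 1) for k in range(7)))
    raise ProtocolError(f"unknown scenario {name!r}")


def set_swept_parameter(
    base: ModelParameters, name: str, value: float, D: float | None = None
) -> ModelParameters:
    """Clone ``base`` with the scenario's parameter (and diameter) set."""
    p = base
    if name == "diameter":
        D = value
    elif name == "pvr":
        p = replace(p, pulmonary=replace(p.pulmonary, R_a=value))
    elif name == "ees":
        p = replace(p, SV=replace(p.SV, E_es=value))
    elif name == "b":
        p = replace(p, SV=replace(p.SV, B=value))
    elif name == "svr":
        p = replace(p, systemic=replace(p.systemic, R_a=value))
    else:
        raise ProtocolError(f"unknown scenario {name!r}")
    if D is not None:
        p = replace(p, fenestration=replace(p.fenestration, D=D))
    return p


# ---------------------------------------------------------------------------
# SBV tuning
# ---------------------------------------------------------------------------

def tune_sbv(
    params: ModelParameters,
    spec: TuningSpec | None = None,
    start_SBV: float = DEFAULT_START_SBV,
    settings: IntegratorSettings | None = None,
) -> tuple[float, BeatSeries]:
    """Find the SBV grid point whose systolic pressure is closest to target.

    The SBV grid is the integer multiples of ``spec.step``.  Each candidate
    is run to periodic steady state (warm-started from the nearest already
    evaluated candidate, which only accelerates convergence — the periodic
    cycle is independent of the initializer).  Monotonicity of SBP in SBV
    is verified over all evaluated points; ties between two equally close
    grid points break toward the smaller SBV.
    """
    spec = spec or TuningSpec()
    if start_SBV <= 0:
        raise ValueError("start_SBV must be > 0")
    step = spec.step
    k0 = max(1, round(start_SBV / step))

    evals: dict[int, tuple[float, BeatSeries]] = {}
    budget = spec.max_iters

    def sbp(k: int) -> float:
        nonlocal budget
        if k in evals:
            return evals[k][0]
        if budget <= 0:
            trace = {ki * step: round(v[0], 3) for ki, v in sorted(evals.items())}
            raise TuningError(f"max_iters exceeded; SBP trace: {trace}")
        budget -= 1
        s = k * step
        if evals:
            near = min(evals, key=lambda ki: abs(ki - k))
            y0 = evals[near][1].states[-1].copy()
            y0[3] += s - near * step  # park the volume delta on C_v,s
            beat = (
                run_to_steady_state(params, SBV=s, settings=settings)
                if y0[3] <= 0
                else run_to_steady_state(params, settings=settings, state0=y0)
            )
        else:
            beat = run_to_steady_state(params, SBV=s, settings=settings)
        value = float(aortic_root_pressure(beat, params).max())
        evals[k] = (value, beat)
        return value

    def f(k: int) -> float:
        return sbp(k) - spec.target_SBP

    # bracket by doubling in the direction that approaches the target
    f0 = f(k0)
    if f0 == 0.0:
        lo = hi = k0
    else:
        direction = 1 if f0 < 0 else -1
        width, prev_k = 1, k0
        while True:
            nxt = prev_k + direction * width
            if nxt < 1:
                nxt = 1
            fn = f(nxt)
            if fn == 0.0 or fn * f0 < 0:
                lo, hi = sorted((prev_k, nxt))
                break
            if nxt == 1 and fn > 0:
                raise TuningError(
                    "SBP exceeds target even at the smallest positive SBV"
                )
            prev_k = nxt
            width *= 2
        # bisect the integer bracket down to adjacent grid points
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if f(mid) < 0:
                lo = mid
            else:
                hi = mid

    # closest of the bracket endpoints; ties break toward the smaller SBV
    best = min(sorted({lo, hi}), key=lambda k: (abs(f(k)), k))

    ks = sorted(evals)
    for a, b in zip(ks, ks[1:]):
        if evals[b][0] < evals[a][0] - 5e-3:
            raise TuningError(
                f"SBP not monotone in SBV: SBP({a * step:.0f} ml) = "
                f"{evals[a][0]:.3f} > SBP({b * step:.0f} ml) = {evals[b][0]:.3f}"
            )
    sbv = best * step
    logger.info(
        "tuned SBV = %.0f ml (SBP %.2f mmHg, target %.2f, %d evaluations)",
        sbv, evals[best][0], spec.target_SBP, len(evals),
    )
    return sbv, evals[best][1]


# ---------------------------------------------------------------------------
# sweeps and comparisons
# ---------------------------------------------------------------------------

_SWEEP_COLUMNS = ("scenario", "value", "D_mm") + tuple(
    HemodynamicSummary.__dataclass_fields__
)


def run_scenario(
    base: ModelParameters,
    grid: ScenarioGrid | str,
    spec: TuningSpec | None = None,
    settings: IntegratorSettings | None = None,
    start_SBV: float = DEFAULT_START_SBV,
    ox: OxygenParams | None = None,
) -> SweepResult:
    """Run a sweep: tune SBV and summarize every (value, diameter) cell.

    For the ``diameter`` scenario the swept value *is* the diameter, so the
    paired-diameter list is ignored.  Within a diameter column the tuner is
    warm-started from the previous value's tuned SBV.
    """
    if isinstance(grid, str):
        grid = standard_grid(grid)
    spec = spec or TuningSpec()
    columns: tuple[float | None, ...]
    columns = (None,) if grid.name == "diameter" else grid.fenestration_diameters
    rows = []
    for D in columns:
        start = start_SBV
        for value in grid.values:
            p = set_swept_parameter(base, grid.name, value, D)
            try:
                sbv, beat = tune_sbv(p, spec, start, settings)
            except FontanModelError as err:
                raise ProtocolError(
                    f"scenario {grid.name!r} failed at value={value}, "
                    f"D={p.fenestration.D}: {err}"
                ) from err
            # report the tuned grid SBV exactly (the beat total matches it
            # to float accumulation error)
            summ = replace(summarize(beat, p, ox), SBV=sbv)
            rows.append(
                {"scenario": grid.name, "value": value, "D_mm": p.fenestration.D,
                 **summ.to_dict()}
            )
            start = sbv
    table = pd.DataFrame(rows, columns=_SWEEP_COLUMNS)
    return SweepResult(scenario=grid.name, table=table)


def compare_fenestration(
    result: SweepResult, at_value: float, diameter: float | None = None
) -> dict[str, float]:
    """Paired deltas (fenestrated minus non-fenestrated) at one swept value.

    ``diameter`` selects the fenestrated column (default: the largest
    nonzero diameter present).  Returns ``dCVP, dSBV, dCI, dSpO2, dDBP``.
    """
    t = result.table
    sel = t[np.isclose(t["value"], at_value)]
    if sel.empty:
        raise ProtocolError(f"swept value {at_value} not present in sweep")
    if diameter is None:
        nonzero = sorted(d for d in sel["D_mm"].unique() if d > 0)
        if not nonzero:
            raise ProtocolError("no fenestrated column in sweep")
        diameter = nonzero[-1]
    fen = result.row(at_value, diameter)
    ref = result.row(at_value, 0.0)
    return {
        "dCVP": float(fen["CVP"] - ref["CVP"]),
        "dSBV": float(fen["SBV"] - ref["SBV"]),
        "dCI": float(fen["CI"] - ref["CI"]),
        "dSpO2": float(fen["SpO2"] - ref["SpO2"]),
        "dDBP": float(fen["DBP"] - ref["DBP"]),
    }


def baseline(
    params: ModelParameters,
    spec: TuningSpec | None = None,
    settings: IntegratorSettings | None = None,
    start_SBV: float = DEFAULT_START_SBV,
    ox: OxygenParams | None = None,
) -> tuple[HemodynamicSummary, BeatSeries]:
    """Tune the given parameter set to the target SBP and summarize it."""
    sbv, beat = tune_sbv(params, spec, start_SBV, settings)
    return replace(summarize(beat, params, ox), SBV=sbv), beat
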