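"""Configuration: packaged defaults, YAML/JSON loading, validation, dumping.

The configuration file uses the display units the model parameters are
usually tabulated in (ms for times, beats/min for heart rate, mm for the
fenestration diameter, mmHg·s/ml and ml/mmHg for the circuits); they are
converted to the package's internal second-based units at load time.
Unknown keys are rejected rather than ignored, so typos cannot silently
fall back to defaults.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml

from .model import (
    ChamberParams,
    FontanModelError,
    FenestrationParams,
    ModelParameters,
    TimingParams,
    ValveParams,
    WindkesselParams,
)
from .protocols import TuningSpec
from .report import OxygenParams
from .simulate import IntegratorSettings

__all__ = [
    "ConfigError",
    "Configuration",
    "default_parameters",
    "default_config",
    "load_config",
    "dump_config",
    "DEFAULTS_YAML",
]


class ConfigError(FontanModelError):
    """A configuration document is malformed or inconsistent."""


def default_parameters() -> ModelParameters:
    """The packaged baseline parameter set of the fenestrated Fontan model.

    Chamber, valve and vascular constants of a 0.58 m² Fontan patient at
    80 bpm with a 2.5 mm fenestration; the stressed blood volume is *not*
    part of this set — it is tuned to the systolic-pressure target by the
    protocols layer.
    """
    return ModelParameters(
        SV=ChamberParams(E_es=13.1, A=1.15, B=0.0753, V_0=0.0, T_es=0.200),
        SA=ChamberParams(E_es=1.64, A=0.197, B=0.865, V_0=0.0, T_es=0.120),
        AV=ValveParams(R_fwd=0.001),
        AVV=ValveParams(R_fwd=0.001),
        systemic=WindkesselParams(R_c=0.0984, R_a=1.5, R_v=0.0491, C_a=0.61, C_v=24.2),
        pulmonary=WindkesselParams(R_c=0.0655, R_a=0.075, R_v=0.0492, C_a=3.97, C_v=2.52),
        fenestration=FenestrationParams(D=2.5),
        timing=TimingParams(HR=80.0),
        BSA=0.58,
    )


class Configuration:
    """A validated bundle of model, oxygen, integrator and tuning settings."""

    def __init__(
        self,
        parameters: ModelParameters,
        oxygen: OxygenParams,
        integrator: IntegratorSettings,
        tuning: TuningSpec,
        start_SBV: float = 450.0,
    ):
        self.parameters = parameters
        self.oxygen = oxygen
        self.integrator = integrator
        self.tuning = tuning
        self.start_SBV = start_SBV

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Configuration):
            return NotImplemented
        return (
            self.parameters == other.parameters
            and self.oxygen == other.oxygen
            and self.integrator == other.integrator
            and self.tuning == other.tuning
            and self.start_SBV == other.start_SBV
        )


def default_config() -> Configuration:
    p = default_parameters()
    return Configuration(
        parameters=p,
        oxygen=OxygenParams(BSA=p.BSA),
        integrator=IntegratorSettings(),
        tuning=TuningSpec(),
    )


# ---------------------------------------------------------------------------
# document <-> objects
# ---------------------------------------------------------------------------

def _to_document(cfg: Configuration) -> dict[str, Any]:
    p = cfg.parameters
    return {
        "model": {
            "fenestration": {"D_mm": p.fenestration.D},
            "timing": {
                "HR_bpm": p.timing.HR,
                "T_c_ms": p.timing.T_c * 1000.0,
                "DT_fraction": p.timing.DT_fraction,
            },
            "SV": _chamber_doc(p.SV),
            "SA": _chamber_doc(p.SA),
            "valves": {"R_AV": p.AV.R_fwd, "R_AVV": p.AVV.R_fwd},
            "systemic": _wk_doc(p.systemic),
            "pulmonary": _wk_doc(p.pulmonary),
            "BSA_m2": p.BSA,
        },
        "oxygen": {
            "S_pv_O2": cfg.oxygen.S_pv_O2,
            "CVO2": cfg.oxygen.CVO2,
            "Hb": cfg.oxygen.Hb,
            "BSA_m2": cfg.oxygen.BSA,
        },
        "integrator": {
            "dt_ms": cfg.integrator.dt * 1000.0,
            "max_beats": cfg.integrator.max_beats,
            "periodicity_tol_ml": cfg.integrator.periodicity_tol,
        },
        "tuning": {
            "target_SBP": cfg.tuning.target_SBP,
            "step_ml": cfg.tuning.step,
            "max_iters": cfg.tuning.max_iters,
            "start_SBV_ml": cfg.start_SBV,
        },
    }


def _chamber_doc(c: ChamberParams) -> dict[str, float]:
    return {"E_es": c.E_es, "A": c.A, "B": c.B, "V_0": c.V_0, "T_es_ms": c.T_es * 1000.0}


def _wk_doc(w: WindkesselParams) -> dict[str, float]:
    return {"R_c": w.R_c, "R_a": w.R_a, "R_v": w.R_v, "C_a": w.C_a, "C_v": w.C_v}


def _merge(defaults: dict, user: Any, path: str) -> dict:
    if user is None:
        return defaults
    if not isinstance(user, dict):
        raise ConfigError(f"{path or 'document'}: expected a mapping, got {type(user).__name__}")
    out = dict(defaults)
    for key, val in user.items():
        if key not in defaults:
            raise ConfigError(f"unknown key {(path + '.' if path else '') + str(key)!r}")
        if isinstance(defaults[key], dict):
            out[key] = _merge(defaults[key], val, f"{path}.{key}" if path else str(key))
        else:
            if not isinstance(val, (int, float)) or isinstance(val, bool):
                raise ConfigError(
                    f"{(path + '.' if path else '')}{key}: expected a number, got {val!r}"
                )
            out[key] = float(val)
    return out


def _from_document(doc: dict[str, Any]) -> Configuration:
    base = _to_document(default_config())
    merged = _merge(base, doc, "")
    m = merged["model"]
    try:
        timing = TimingParams(
            HR=m["timing"]["HR_bpm"],
            T_c=m["timing"]["T_c_ms"] / 1000.0,
            DT_fraction=m["timing"]["DT_fraction"],
        )
        params = ModelParameters(
            SV=_chamber_from(m["SV"]),
            SA=_chamber_from(m["SA"]),
            AV=ValveParams(R_fwd=m["valves"]["R_AV"]),
            AVV=ValveParams(R_fwd=m["valves"]["R_AVV"]),
            systemic=WindkesselParams(**m["systemic"]),
            pulmonary=WindkesselParams(**m["pulmonary"]),
            fenestration=FenestrationParams(D=m["fenestration"]["D_mm"]),
            timing=timing,
            BSA=m["BSA_m2"],
        )
        ox = merged["oxygen"]
        oxygen = OxygenParams(S_pv_O2=ox["S_pv_O2"], CVO2=ox["CVO2"], Hb=ox["Hb"], BSA=ox["BSA_m2"])
        it = merged["integrator"]
        integrator = IntegratorSettings(
            dt=it["dt_ms"] / 1000.0,
            max_beats=int(it["max_beats"]),
            periodicity_tol=it["periodicity_tol_ml"],
        )
        tu = merged["tuning"]
        tuning = TuningSpec(
            target_SBP=tu["target_SBP"], step=tu["step_ml"], max_iters=int(tu["max_iters"])
        )
    except (ValueError, FontanModelError) as err:
        raise ConfigError(f"invalid configuration: {err}") from err
    return Configuration(params, oxygen, integrator, tuning, start_SBV=tu["start_SBV_ml"])


def _chamber_from(d: dict[str, float]) -> ChamberParams:
    return ChamberParams(E_es=d["E_es"], A=d["A"], B=d["B"], V_0=d["V_0"], T_es=d["T_es_ms"] / 1000.0)


def load_config(path: str | Path | None = None) -> Configuration:
    """Load a YAML (or JSON) configuration; omitted fields take defaults.

    ``None`` or an empty document yields the packaged defaults exactly.
    """
    if path is None:
        return default_config()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as err:
        raise ConfigError(f"cannot parse {path}: {err}") from err
    return _from_document(doc or {})


def dump_config(cfg: Configuration, path: str | Path | None = None) -> str:
    """Serialize a configuration to YAML; round-trips through load_config."""
    text = yaml.safe_dump(_to_document(cfg), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


#: the packaged default configuration as a commented, copy-paste friendly
#: document; parses to exactly ``default_config()``
DEFAULTS_YAML = """\
# Baseline fenestrated Fontan model configuration.
# Units: resistances mmHg.s/ml, capacitances ml/mmHg, elastances mmHg/ml,
#        times ms, pressures mmHg, volumes ml, diameter mm.
model:
  fenestration:
    D_mm: 2.5            # effective fenestration diameter (0 = none)
  timing:
    HR_bpm: 80.0         # heart rate
    T_c_ms: 750.0        # cardiac cycle length (= 60000 / HR)
    DT_fraction: 0.02    # atrial systole lead as a fraction of T_c (15 ms)
  SV:                    # single ventricle
    E_es: 13.1           # end-systolic elastance, mmHg/ml
    A: 1.15              # EDPVR scaling factor, mmHg
    B: 0.0753            # EDPVR stiffness constant, 1/ml
    V_0: 0.0             # unstressed volume, ml
    T_es_ms: 200.0       # time to end systole
  SA:                    # single atrium
    E_es: 1.64
    A: 0.197
    B: 0.865
    V_0: 0.0
    T_es_ms: 120.0
  valves:
    R_AV: 0.001          # aortic valve forward resistance
    R_AVV: 0.001         # atrioventricular valve forward resistance
  systemic:
    R_c: 0.0984          # characteristic impedance
    R_a: 1.5             # arteriolar resistance
    R_v: 0.0491          # venous resistance
    C_a: 0.61            # arterial capacitance
    C_v: 24.2            # venous capacitance
  pulmonary:
    R_c: 0.0655
    R_a: 0.075
    R_v: 0.0492
    C_a: 3.97
    C_v: 2.52
  BSA_m2: 0.58           # body surface area
oxygen:
  S_pv_O2: 0.99          # pulmonary venous O2 saturation, fraction
  CVO2: 185.0            # whole-body O2 consumption, ml O2/min/m^2
  Hb: 14.0               # hemoglobin, g/dl
  BSA_m2: 0.58
integrator:
  dt_ms: 0.1             # RK4 step
  max_beats: 200
  periodicity_tol_ml: 0.001
tuning:
  target_SBP: 87.2       # systolic pressure target, mmHg
  step_ml: 1.0           # SBV tuning grid
  max_iters: 200
  start_SBV_ml: 450.0    # tuner starting guess (result is independent of it)
"""
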