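import numpy as np
import pytest

from fontansim import (
    IntegratorSettings,
    OxygenParams,
    default_parameters,
    run_to_steady_state,
    summarize,
    tune_sbv,
)


@pytest.fixture(scope="session")
def params():
    """Packaged baseline parameter set (2.5 mm fenestration, 80 bpm)."""
    return default_parameters()


@pytest.fixture(scope="session")
def ox():
    return OxygenParams()


@pytest.fixture(scope="session")
def settings():
    return IntegratorSettings()


@pytest.fixture(scope="session")
def baseline_beat(params):
    """One converged cycle of the untuned baseline at SBV = 450 ml."""
    return run_to_steady_state(params, SBV=450.0)


@pytest.fixture(scope="session")
def tuned_baseline(params):
    """Baseline tuned to the systolic target: (SBV, beat, summary)."""
    sbv, beat = tune_sbv(params)
    return sbv, beat, summarize(beat, params)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240321)
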