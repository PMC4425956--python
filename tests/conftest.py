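import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from mbwsigh import LungSpec, ModelParams
from mbwsigh.washout import BreathRecord, PHASE_WASHIN, PHASE_WASHOUT

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def ideal_spec() -> LungSpec:
    """Homogeneous infant lung, no dead space, no noise: washout ratio 2/3."""
    return LungSpec(frc=0.1, vt=0.05, dead_space=0.0, noise_sd=0.0)


@pytest.fixture
def lci_params() -> ModelParams:
    """Replicate-model parameters for LCI at the magnitudes seen in infant
    SF6 washout cohorts (residual SD roughly doubled for washout sighs)."""
    return ModelParams(
        mu=6.82,
        alpha={"none": 0.0, "washin-pre": -0.135, "washout-pre": 0.362},
        omega=0.296,
        tau=0.186,
        sigma={"none": 0.437, "washin-pre": 0.823 * 0.437, "washout-pre": 2.04 * 0.437},
    )


def make_breaths(v_exps, phase=PHASE_WASHOUT, c_ets=None, v_insps=None):
    """Build a BreathRecord list from expired volumes (test helper)."""
    v_exps = list(v_exps)
    n = len(v_exps)
    c_ets = list(c_ets) if c_ets is not None else [0.0] * n
    v_insps = list(v_insps) if v_insps is not None else v_exps
    phases = [phase] * n if isinstance(phase, str) else list(phase)
    return [
        BreathRecord(
            index=i + 1,
            t_start=float(i),
            t_end=float(i + 1),
            v_insp=v_insps[i],
            v_exp=v_exps[i],
            c_et=c_ets[i],
            phase=phases[i],
        )
        for i in range(n)
    ]


@pytest.fixture
def breath_factory():
    return make_breaths
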