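import numpy as np
import pytest

from thromboflow import PressureTrace, SampleCondition, SimulationConfig
from thromboflow.clot_model import model_pressure_ratio


def make_model_trace(
    p0=1.0, t_g=30.0, t_s=45.0, k=1.0, t_end_min=60.0, n=2000,
    noise_cv=0.0, seed=0, **kwargs,
):
    """Noise-free (or noisy) trace sampled exactly from the pressure model."""
    t_s_axis = np.linspace(0.0, t_end_min * 60.0, n)
    p = p0 * model_pressure_ratio(t_s_axis / 60.0, t_g, t_s, k)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        p = p * np.exp(noise_cv * rng.standard_normal(n))
    return PressureTrace(times=t_s_axis, pressures=p, origin="simulated", **kwargs)


@pytest.fixture
def model_trace():
    """The representative worked-example curve: dP0=1 kPa, T_g=30, T_s=45 min."""
    return make_model_trace()


@pytest.fixture
def default_condition():
    return SampleCondition(heparin=0.5, shear_gradient=1225.0)


@pytest.fixture
def config():
    return SimulationConfig(seed=1234)
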