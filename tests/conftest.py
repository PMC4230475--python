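import numpy as np
import pytest

from coxsens.bias_engine import BinaryExposure, ScenarioSpec, UniformCensoring
from coxsens.confounder_models import BinaryConfounder
from coxsens.io_core import SurvivalSample
from coxsens.simulation import generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_sample(rng):
    """Moderately censored two-arm sample with two measured covariates."""
    n = 400
    x = (rng.random(n) < 0.5).astype(float)
    z1 = rng.standard_normal(n)
    z2 = (rng.random(n) < 0.3).astype(float)
    rate = 0.8 * np.exp(0.7 * x - 0.4 * z1 + 0.5 * z2)
    t = rng.exponential(1.0, n) / rate
    c = rng.uniform(0, 2.0, n)
    import pandas as pd
    return SurvivalSample(time=np.minimum(t, c), event=(t <= c).astype(int), exposure=x,
                          covariates=pd.DataFrame({"z1": z1, "z2": z2}))


@pytest.fixture
def confounded_scenario():
    """Binary exposure, binary confounder more prevalent in the treated arm,
    uniform censoring giving roughly half censored observations."""
    return ScenarioSpec(exposure=BinaryExposure(0.5),
                        confounder=BinaryConfounder(0.9, 0.1),
                        gamma=1.0, beta=1.0, baseline_rate=0.57,
                        censoring=UniformCensoring(1.0))


@pytest.fixture
def balanced_nocensor_scenario():
    return ScenarioSpec(exposure=BinaryExposure(0.5),
                        confounder=BinaryConfounder(0.5, 0.5),
                        gamma=2.0, beta=np.log(2.0), baseline_rate=1.0)


@pytest.fixture
def medium_dataset(confounded_scenario):
    return generate_dataset(confounded_scenario, 1500, 20240917)
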