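import numpy as np
import pytest

from capicea import datasets
from capicea.costing import compare_costs
from capicea.pipeline import PipelineInputs
from capicea.risk_effects import risk_source
from capicea.synthetic import SyntheticConfig, gen_mortality_schedule, gen_population


@pytest.fixture(scope="session")
def cost_models():
    return datasets.load_cost_models()


@pytest.fixture(scope="session")
def cost_comparison(cost_models):
    return compare_costs(cost_models["intervention"], cost_models["comparator"])


@pytest.fixture(scope="session")
def risk_grid():
    return risk_source(datasets.fixture_risk_engine)


@pytest.fixture(scope="session")
def uncertainty_params():
    return datasets.load_uncertainty_parameters()


@pytest.fixture(scope="session")
def synth_cfg():
    return SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def pipeline_inputs(synth_cfg):
    schedules = {s: gen_mortality_schedule(synth_cfg, s) for s in ("male", "female")}
    pop = gen_population(synth_cfg).astype(float)
    return PipelineInputs(schedules, pop)


@pytest.fixture(scope="session")
def published_lifetable():
    return datasets.load_published_lifetable()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
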