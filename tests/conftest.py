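import pytest

from snakevuln.pipeline import run_pipeline
from snakevuln.synthetic import ScenarioSpec, generate_scenario


@pytest.fixture(scope="session")
def scenario():
    """Default desk-scale scenario, seed 1."""
    return generate_scenario(ScenarioSpec(seed=1))


@pytest.fixture(scope="session")
def result(scenario):
    """Pipeline outputs for the default scenario."""
    return run_pipeline(scenario)
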