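import pytest
from hypothesis import settings

from netpharm import gen_scenario, load_packaged_compounds

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")
from netpharm.pipeline import PipelineConfig


@pytest.fixture(scope="session")
def packaged_table():
    return load_packaged_compounds()


@pytest.fixture(scope="session")
def scenario(tmp_path_factory):
    """One default synthetic scenario shared by the read-only tests."""
    d = tmp_path_factory.mktemp("scenario")
    manifest = gen_scenario(d, seed=11)
    return d, manifest


@pytest.fixture(scope="session")
def scenario_config(scenario):
    d, _ = scenario
    return PipelineConfig.for_scenario(d, seed=11)
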