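import pytest
from hypothesis import settings

from probevar.pipeline import PipelineConfig, run_survey

settings.register_profile("derandomized", derandomize=True)
settings.load_profile("derandomized")
from probevar.synthetic import SyntheticConfig, generate_bundle, write_fixture_bundle


@pytest.fixture(scope="session")
def small_config():
    """A compact generator configuration used by most unit tests."""
    return SyntheticConfig(seed=11, n_genes=20, n_chromosomes=2)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_bundle(small_config)


@pytest.fixture(scope="session")
def small_bundle_dir(small_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("small_bundle")
    write_fixture_bundle(small_config, out)
    return out


@pytest.fixture(scope="session")
def small_survey(small_bundle_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("small_survey")
    return run_survey(PipelineConfig.from_bundle(small_bundle_dir, out))


@pytest.fixture(scope="session")
def default_bundle_dir(tmp_path_factory):
    """The generator's default study conditions (~200 genes, 57+56 samples)."""
    out = tmp_path_factory.mktemp("default_bundle")
    write_fixture_bundle(SyntheticConfig(seed=1), out)
    return out


@pytest.fixture(scope="session")
def default_survey(default_bundle_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("default_survey")
    return run_survey(PipelineConfig.from_bundle(default_bundle_dir, out))
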