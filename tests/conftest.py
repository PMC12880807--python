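import warnings

import pytest

from conegrn.config import PipelineConfig
from conegrn.synthetic import generate_dataset


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig(seed=1)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    """The default two-species synthetic study (seed 1)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_dataset(default_config, seed=1)


@pytest.fixture(scope="session")
def pipeline_results(default_dataset, default_config):
    """Full pipeline run on the default dataset (shared across tests)."""
    from conegrn.pipeline import run_analysis

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_analysis(default_dataset, default_config, seed=1)
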