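import pytest

from circena.bsj import detect_circrnas
from circena.config import PipelineConfig
from circena.synthetic import simulate_dataset


@pytest.fixture(scope="session")
def default_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def dataset():
    """The default planted-truth fixture (error-free reads)."""
    return simulate_dataset(rng_seed=1)


@pytest.fixture(scope="session")
def detected_circrnas(dataset, default_config):
    """Detection output on the default fixture, shared across tests."""
    return detect_circrnas(
        dataset.reads, dataset.genome, dataset.annotations, default_config
    )
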