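import numpy as np
import pytest

from seegmosaic import GeneratorConfig


@pytest.fixture
def config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture
def noiseless_config() -> GeneratorConfig:
    """Generator config with technical false positives switched off."""
    return GeneratorConfig(droplet_fp_prob=0.0, amplicon_error_vaf=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230601)
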