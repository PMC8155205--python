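import numpy as np
import pytest

from chemlm.model import ModelConfig
from chemlm.synthetic import GeneratorConfig, generate_molecules


@pytest.fixture(scope="session")
def smiles_panel() -> list[str]:
    """60 deterministic synthetic molecules used across modules."""
    return generate_molecules(GeneratorConfig(n_molecules=60, seed=12345))


@pytest.fixture(scope="session")
def tiny_cfg() -> ModelConfig:
    return ModelConfig.tiny()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
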