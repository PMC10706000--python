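import numpy as np
import pytest

from graphgpt import SyntheticDatasetSpec, synth_smiles, toy_dataset


@pytest.fixture(scope="session")
def fixture_smiles():
    """1,000 deterministic grammar-built molecules."""
    return synth_smiles(SyntheticDatasetSpec(n=1000, seed=42))


@pytest.fixture(scope="session")
def toy_records():
    """Small record set with computed properties and scaffolds."""
    return toy_dataset(SyntheticDatasetSpec(n=60, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
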