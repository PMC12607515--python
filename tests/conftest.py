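import numpy as np
import pytest

from milletnir.synthetic import generate_dataset, generate_reference_chemistry


@pytest.fixture(scope="session")
def dataset():
    """Default 217-sample synthetic study: chemistry + noisy spectra."""
    return generate_dataset(n=217, seed=42)


@pytest.fixture(scope="session")
def chem217():
    return generate_reference_chemistry(n=217, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
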