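import numpy as np
import pytest

from cernet.synthetic import generate_dataset


@pytest.fixture(scope="session")
def dataset():
    """One default-parameter synthetic dataset shared across the suite."""
    return generate_dataset(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))
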