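import numpy as np
import pytest

from protride import generate_synthetic_dataset, preprocess


@pytest.fixture(scope="session")
def small_dataset():
    """Confounded fixture: 40 samples x 300 proteins, 4 batches."""
    return generate_synthetic_dataset(
        n_samples=40, n_proteins=300, latent_dim=4, batch_count=4, seed=42
    )


@pytest.fixture(scope="session")
def small_preprocessed(small_dataset):
    return preprocess(small_dataset.raw)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
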