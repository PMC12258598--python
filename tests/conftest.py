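import numpy as np
import pytest

import spatialccc as sc

# small problem sizes keep the training-based tests fast while leaving the
# spatial graph dense enough for link prediction to be meaningful


@pytest.fixture(scope="session")
def default_dataset():
    """The generator's default study conditions (200 cells, 60 genes)."""
    return sc.generate_dataset(sc.SynthParams())


@pytest.fixture(scope="session")
def default_model(default_dataset):
    return sc.CellCommunicationModel.from_synthetic(default_dataset)


@pytest.fixture(scope="session")
def default_fit(default_model):
    """One fitted results object shared by read-only tests."""
    return default_model.fit(seed=0)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A miniature dataset for tests that retrain repeatedly."""
    return sc.generate_dataset(
        sc.SynthParams(n_cells=60, n_genes=20, n_types=3, n_lr_pairs=4, seed=11)
    )


@pytest.fixture(scope="session")
def tiny_hp():
    return sc.Hyperparams(epochs=40, latent_dim=8, hidden_dim=16,
                          decoder_hidden=16)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
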