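import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from bdekit.model import BDEPredictor
from bdekit.synthetic import SyntheticOracleParams, gen_bde_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Small noiseless synthetic BDE table split by molecule."""
    params = SyntheticOracleParams(seed=11, noise_sigma=0.0)
    return gen_bde_dataset(params, n_train=120, n_dev=30, n_test=30,
                           max_heavy=7)


@pytest.fixture(scope="session")
def small_model(small_dataset):
    """A quickly trained model: good enough for plumbing and embedding
    tests, not for accuracy claims."""
    df = small_dataset
    model = BDEPredictor(state_dim=32, n_blocks=3, epochs=15, batch_size=32,
                         lr=2e-3, seed=3)
    model.fit(df[df.split == "train"], df[df.split == "dev"])
    return model
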