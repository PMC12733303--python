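import logging

import numpy as np
import pytest

from cytoqsar.consensus import build_consensus
from cytoqsar.pipeline import training_set_from_table
from cytoqsar.synth import SyntheticSpec, generate

logging.getLogger("cytoqsar").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Noisy synthetic structure-activity set with duplicates and invalid records."""
    return generate(
        SyntheticSpec(n=300, sigma=0.2, seed=7, duplicate_fraction=0.1, invalid_fraction=0.05)
    )


@pytest.fixture(scope="session")
def training_set(synthetic_dataset):
    ts, _ = training_set_from_table(synthetic_dataset.activity, "SYN-1", "IC50")
    assert ts is not None
    return ts


@pytest.fixture(scope="session")
def noise_free_training_set():
    ds = generate(SyntheticSpec(n=300, sigma=0.0, seed=11))
    ts, _ = training_set_from_table(ds.activity, "SYN-1", "IC50")
    assert ts is not None
    return ts


@pytest.fixture(scope="session")
def consensus_model(training_set):
    """Small but real consensus model (8 variants for speed)."""
    cm = build_consensus(training_set, n_variants=8, seed=3)
    assert cm is not None
    cm.consensus_rmse = 0.35  # stand-in attached for AD tests; real runs use 5-fold CV
    return cm


@pytest.fixture
def rng():
    return np.random.default_rng(42)
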