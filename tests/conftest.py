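import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cwqsar.optimizer import TargetConfig
from cwqsar.splits import random_split
from cwqsar.synth import GeneratorConfig, generate_dataset


EASY_WEIGHTS = {"C": 0.1, "N": 0.5, "O": -0.4}


def easy_config(n=40, noise_sd=0.0, seed=0, task="regression"):
    """A deliberately small generator setup for fast optimizer tests:
    three-token vocabulary, short chains, no rings or branches."""
    return GeneratorConfig(
        n=n,
        vocab=("C", "N", "O"),
        true_weights=dict(EASY_WEIGHTS),
        max_length=8,
        min_length=3,
        ring_p=0.0,
        branch_p=0.0,
        noise_sd=noise_sd,
        task=task,
        seed=seed,
    )


@pytest.fixture
def easy_dataset():
    """(ids, smiles, endpoints, labels) for a tiny noise-free regression set."""
    df = generate_dataset(easy_config(n=40, seed=3))
    ids = df["id"].tolist()
    labels = random_split(ids, seed=7).labels_for(ids)
    return ids, df["smiles"].tolist(), df["endpoint"].to_numpy(), labels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def t1_config():
    return TargetConfig(variant="T1")
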