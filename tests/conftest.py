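import numpy as np
import pytest

from wsisubtyper.cnn import TrainingConfig, train_patch_model
from wsisubtyper.synthetic import make_tissue_patch

# Desk-scale training recipe: the tiny backbone sees only ~35 Adam steps in
# 5 epochs, so it runs at lr 3e-3 instead of the 50-epoch default.
DESK_CFG = dict(epochs=5, lr0=3e-3, seed=0)


def tissue_set(n, delta, seed0, size=64):
    """n patches with alternating SCC/AC labels, one RNG stream per patch."""
    patches, labels = [], []
    for i in range(n):
        lab = "AC" if i % 2 else "SCC"
        patches.append(make_tissue_patch(lab, delta, seed=seed0 + i, size=size))
        labels.append(lab)
    return patches, labels


@pytest.fixture(scope="session")
def separable_training_set():
    return tissue_set(400, 1.0, seed0=0)


@pytest.fixture(scope="session")
def separable_eval_set():
    return tissue_set(200, 1.0, seed0=100_000)


@pytest.fixture(scope="session")
def trained_model(separable_training_set):
    patches, labels = separable_training_set
    return train_patch_model(patches, labels, TrainingConfig(**DESK_CFG))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
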