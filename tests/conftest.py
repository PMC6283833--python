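import numpy as np
import pytest

import perlinaug as pa

MASTER_SEED = 1


@pytest.fixture(scope="session")
def dataset600():
    """The default synthetic fixture dataset: 100 patches per class, 6 classes."""
    return pa.generate_dataset(n_per_class=100, size=20, seed=MASTER_SEED)


@pytest.fixture(scope="session")
def split(dataset600):
    return pa.stratified_split(dataset600, test_fraction=0.2, seed=MASTER_SEED)


def _train(split, mode):
    model = pa.build_model(pa.ModelConfig(), seed=MASTER_SEED)
    tcfg = pa.TrainConfig(max_steps=400, eval_interval=25, early_stop_patience=6,
                          seed=MASTER_SEED, augmentation_mode=mode)
    return pa.train(model, split, tcfg)


@pytest.fixture(scope="session")
def trained_perlin(split):
    """Default small model trained with mask-mixing augmentation (the long pole
    of the suite, shared session-wide)."""
    return _train(split, "perlin")


@pytest.fixture(scope="session")
def trained_conventional(split):
    return _train(split, "conventional")


@pytest.fixture()
def rng():
    return np.random.default_rng(MASTER_SEED)
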