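import numpy as np
import pytest

import chaoelm as ce


@pytest.fixture(scope="session")
def separable_split() -> ce.SplitPair:
    """Well-separated two-class table (effect = 4 sd, no label noise),
    normalized to (-1, 1) and split 7:3."""
    table = ce.generate_synthetic(
        ce.SyntheticSpec(n=400, d=8, effect=4.0, noise_sd=1.0, label_flip=0.0, seed=7)
    )
    norm = ce.fit_normalization(table)
    return ce.shuffle_split(ce.apply_normalization(table, norm), ratio=0.7, seed=7)


@pytest.fixture
def small_table() -> ce.FeatureTable:
    rng = np.random.default_rng(11)
    X = rng.uniform(-1, 1, size=(20, 3))
    y = np.where(rng.random(20) < 0.5, 1, -1)
    y[0], y[1] = 1, -1  # force both classes
    return ce.FeatureTable(X, y)
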