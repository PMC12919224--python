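import numpy as np
import pytest

import treefuse as tf


@pytest.fixture(scope="session")
def small_sim():
    """Small planted-signal dataset shared across training-level tests."""
    spec = tf.SimSpec(n=120, p=(40, 40, 40), class_count=3,
                      k_informative=(5, 5, 5), delta=2.0, seed=3)
    dataset, truth = tf.generate(spec)
    return dataset, truth


@pytest.fixture(scope="session")
def small_config():
    return tf.RunConfig(max_epochs=120, tree_count=25)


@pytest.fixture(scope="session")
def trained_small(small_sim, small_config):
    """One trained full-variant model on the small dataset."""
    dataset, _ = small_sim
    split = tf.make_splits(dataset.labels, [0])[0]
    return tf.run_split(dataset, split, small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
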