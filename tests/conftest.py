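import numpy as np
import pytest

import cryomil as cm


@pytest.fixture(scope="session")
def small_cohort():
    """A small separable cohort shared by model/pipeline tests."""
    cfg = cm.CohortConfig(
        n_patients=60, feature_dim=16, effect_size=2.5, seed=7,
        bag_size_range=(20, 40),
    )
    records, bags = cm.generate_cohort(cfg)
    return cfg, records, bags


@pytest.fixture()
def tiny_hp():
    return cm.MILHyperparams(
        feature_dim=16, attention_dim=8, mlp_dim=16, epochs=5,
        learning_rate=1e-3, seed=0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
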