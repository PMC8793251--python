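import numpy as np
import pytest

from augbin import PSAChangeDataset, SyntheticArmConfig, generate_arm


@pytest.fixture
def hofman_like_dataset() -> PSAChangeDataset:
    """A 30-patient arm with exactly 17 reductions above the 50% threshold.

    Continuous values are synthetic; only the responder pattern (17/30 at
    d = 50) mirrors the published single-arm trial used as the worked
    example.
    """
    rng = np.random.default_rng(20220126)
    responders = rng.uniform(55.0, 99.0, size=17)
    non_responders = rng.uniform(-40.0, 45.0, size=13)
    values = np.concatenate([responders, non_responders])
    rng.shuffle(values)
    return PSAChangeDataset(values=values, threshold=50.0, arm_label="hofman-like")


@pytest.fixture
def small_arm() -> PSAChangeDataset:
    """A well-behaved synthetic arm of 30 patients, response rate ~0.5."""
    return generate_arm(
        SyntheticArmConfig(n=30, mu_log=np.log(0.5), sigma_log=0.8, threshold=50.0, seed=7)
    )
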