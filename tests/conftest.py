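import numpy as np
import pytest

from fmgsampling import SyntheticConfig, default_actions, generate_dataset, normalize


@pytest.fixture(scope="session")
def small_config():
    """A reduced cohort (2 participants, 1 isometric + 1 dynamic action,
    2 trials, both straps) at the full 5 s / 1 kHz trial format."""
    actions = default_actions()
    return SyntheticConfig(
        n_participants=2,
        n_trials=2,
        actions=(actions[0], actions[3]),  # squeeze (isometric), finger_tap (dynamic)
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    recordings, metadata = generate_dataset(small_config)
    return recordings, metadata


@pytest.fixture(scope="session")
def small_normalized(small_dataset):
    recordings, _ = small_dataset
    return normalize(recordings)
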