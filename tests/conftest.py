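import numpy as np
import pytest

import reinstate
from reinstate import (
    SyntheticConfig,
    attach_bins,
    score_test_trials,
    simulate_behavior,
    simulate_localizer,
)

reinstate.TestTrial.__test__ = False  # domain record, not a pytest class


@pytest.fixture(scope="session")
def small_cfg():
    return SyntheticConfig(seed=11, n_participants=6)


@pytest.fixture(scope="session")
def behavior(small_cfg):
    """(encoding, test, ratings, truth) for a small synthetic study."""
    return simulate_behavior(small_cfg)


@pytest.fixture(scope="session")
def scored_with_bins(behavior):
    encoding, test, ratings, _ = behavior
    scored, lures = score_test_trials(test)
    return attach_bins(scored, ratings, encoding), lures


@pytest.fixture(scope="session")
def localizer(small_cfg):
    """Localizer PatternDataset plus ground-truth signal voxel indices."""
    return simulate_localizer(small_cfg)


@pytest.fixture(scope="session")
def tiny_pattern_cfg():
    """Small voxel count for fast decoding tests."""
    return SyntheticConfig(seed=29, n_voxels=120, n_signal_voxels=60)
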