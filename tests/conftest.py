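import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from safefall.features import compute_features
from safefall.io_keypoints import (
    DEFAULT_ACTIVITY_MAP,
    apply_frame_filters,
    binary_labels,
)
from safefall.simulate import SimulationConfig, simulate_trial


@pytest.fixture(scope="session")
def labels():
    return binary_labels(DEFAULT_ACTIVITY_MAP)


@pytest.fixture(scope="session")
def noiseless_cfg():
    return SimulationConfig(noise_sd=0.0, timestamp_jitter_sd=0.0)


@pytest.fixture(scope="session")
def feature_rows_factory(labels):
    """Filtered feature rows for one simulated trial of a given scenario."""

    def factory(scenario, cfg, seed=0, trial_id=None):
        seq = simulate_trial(
            scenario,
            cfg,
            np.random.default_rng(seed),
            trial_id=trial_id or scenario,
        )
        return compute_features(apply_frame_filters(seq), labels)

    return factory
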