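import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import entrofuse as ef

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


@pytest.fixture(scope="session")
def desk_epochs_high():
    """Small high-effect cohort, preprocessed and pooled (40 epochs, 6 ch)."""
    spec = ef.desk_spec(seed=7, effect_size=0.8, n_subjects=2, n_channels=6, duration_s=10.0)
    return ef.segment_recordings(ef.generate_cohort(spec))


@pytest.fixture(scope="session")
def desk_features_high(desk_epochs_high):
    return ef.extract_feature_matrix(desk_epochs_high)
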