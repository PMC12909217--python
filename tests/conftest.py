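import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mieeg.synth import DEFAULT_RESTING_COUPLING, RecordingSpec, generate_resting_recording

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def resting_recording():
    """One 60-s synthetic resting recording with 10% planted artifact epochs."""
    spec = RecordingSpec(duration=60.0, artifact_epoch_rate=0.1, seed=11)
    return generate_resting_recording(spec, coupling=DEFAULT_RESTING_COUPLING)


@pytest.fixture(scope="session")
def clean_epochs(resting_recording):
    """The same recording preprocessed to 10-region epochs."""
    from mieeg.preprocess import preprocess_recording

    return preprocess_recording(resting_recording)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
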