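import numpy as np
import pytest

from eegmap import PipelineConfig, SyntheticConfig, generate_recording, recording_to_image


@pytest.fixture(scope="session")
def default_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def synthetic_recording():
    """One default 64-channel, 1024-sample alcoholic-class recording."""
    return generate_recording(SyntheticConfig(), "alcoholic", seed=11)


@pytest.fixture(scope="session")
def heatmap(synthetic_recording, default_config):
    """The composed 1024 x 352 heat map of the synthetic recording."""
    return recording_to_image(synthetic_recording, default_config)


@pytest.fixture(scope="session")
def small_images():
    """25 random 8x8 uint8 images for oracle-equivalence checks."""
    rng = np.random.default_rng(1234)
    return [rng.integers(0, 256, size=(8, 8)).astype(np.uint8) for _ in range(25)]
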