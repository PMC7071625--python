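import numpy as np
import pytest

from affectfuse.config import PipelineConfig, StudyConfig
from affectfuse.synthetic import build_protocol, generate_study


@pytest.fixture(scope="session")
def small_config() -> StudyConfig:
    """A fast, small study: 2 participants x (6 image + 6 video) trials."""
    return StudyConfig(
        n_participants=2,
        n_image_trials=6,
        n_video_trials=6,
        video_duration_range=(10.0, 12.0),
        inter_trial_gap=6.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


@pytest.fixture(scope="session")
def small_pipeline_config(small_config) -> PipelineConfig:
    return PipelineConfig(study=small_config, seed=small_config.seed)


@pytest.fixture()
def protocol(small_config):
    return build_protocol(small_config, participant_id=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
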