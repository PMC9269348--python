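import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def separable_table():
    """400 balanced windows with well-separated class clusters."""
    from fatiguekit.synthetic import generate_training_set

    return generate_training_set(400, 0.5, seed=1)


@pytest.fixture(scope="session")
def quick_config():
    from fatiguekit.classifier import TrainingConfig

    return TrainingConfig(epochs=400, seed=0)


@pytest.fixture(scope="session")
def trained_model(separable_table, quick_config):
    from fatiguekit.classifier import train

    model, history = train(separable_table, quick_config)
    return model, history


@pytest.fixture(scope="session")
def pipeline_config():
    from fatiguekit.io import PipelineConfig

    return PipelineConfig()


@pytest.fixture(scope="session")
def stream_model(pipeline_config):
    """Classifier trained on window features of a simulated session
    (10 min awake + 10 min fatigue), as the pipelines consume it."""
    from fatiguekit.classifier import TrainingConfig, train
    from fatiguekit.pipeline import extract_window_features, series_from_landmarks
    from fatiguekit.synthetic import ScenarioSpec, generate_stream

    spec = ScenarioSpec(
        duration_s=1200,
        schedule=((0, 600, "awake"), (600, 1200, "fatigue")),
        seed=11,
    )
    stream = generate_stream(spec)
    series = series_from_landmarks(stream.landmarks, pipeline_config)
    feats = extract_window_features(series, pipeline_config)
    feats = feats.merge(stream.window_labels[["window_id", "label"]], on="window_id")
    model, _ = train(feats, TrainingConfig(epochs=600, seed=0))
    return model
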