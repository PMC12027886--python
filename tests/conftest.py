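import numpy as np
import pytest

from cugrade import (
    CucumberParams,
    GradeThresholds,
    SceneSpec,
    pipeline,
    render_scene,
)


@pytest.fixture(scope="session")
def spec() -> SceneSpec:
    return SceneSpec()


@pytest.fixture(scope="session")
def thresholds() -> GradeThresholds:
    return GradeThresholds()


@pytest.fixture(scope="session")
def straight_tube_scene(spec):
    """A straight 20 cm x 3 cm tube centered on the default board."""
    params = CucumberParams(
        arc_length_cm=20.0, bend_angle_deg=0.0, thickness_cm=3.0, center=(20.0, 15.0)
    )
    image, truth = render_scene(spec, params)
    return image, truth, params


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small balanced dataset (2 scenes per grade) for pipeline tests."""
    return pipeline.synth_dataset(2, seed=7)


@pytest.fixture(scope="session")
def tiny_model(tiny_dataset):
    """A briefly trained RGB-variant model (not accurate, just functional)."""
    return pipeline.train(tiny_dataset, steps=30, seed=0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
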