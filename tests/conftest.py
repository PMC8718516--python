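import numpy as np
import pytest

from otassess import pipeline
from otassess.synthetic import SensorNoiseModel, SeverityProfile


@pytest.fixture(scope="session")
def healthy() -> SeverityProfile:
    return SeverityProfile.from_grade(5)


@pytest.fixture(scope="session")
def grade3() -> SeverityProfile:
    return SeverityProfile.from_grade(3)


@pytest.fixture(scope="session")
def kinect_noise() -> SensorNoiseModel:
    return SensorNoiseModel.kinect_like()


@pytest.fixture(scope="session")
def imu_noise() -> SensorNoiseModel:
    return SensorNoiseModel.imu_like()


@pytest.fixture(scope="session")
def config() -> pipeline.SessionConfig:
    return pipeline.SessionConfig()


@pytest.fixture(scope="session")
def reference_library(config):
    return pipeline.make_synthetic_references(config, seed=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
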