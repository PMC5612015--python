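import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ribkin import synthetic as syn
from ribkin.pipeline import PipelineConfig, run_pipeline

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_model():
    return syn.build_ribcage()


@pytest.fixture(scope="session")
def noiseless_sim(default_model):
    script = syn.default_motion_script(default_model, seed=11, noise_sigma_mm=0.0)
    return syn.simulate_breathing(default_model, script)


@pytest.fixture(scope="session")
def noisy_sim(default_model):
    script = syn.default_motion_script(default_model, seed=11, noise_sigma_mm=0.12)
    return syn.simulate_breathing(default_model, script)


@pytest.fixture(scope="session")
def noiseless_result(default_model, noiseless_sim):
    config = PipelineConfig(frame_rate=100.0, joints=default_model.joints, zero_pose_frame="auto")
    return run_pipeline(
        config, noiseless_sim.trajectories, default_model.bodies, landmarks=default_model.landmarks
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_rotations(n: int, seed: int = 0) -> np.ndarray:
    """Uniformly distributed random rotation matrices (scipy's Haar sampler)."""
    from scipy.spatial.transform import Rotation

    return Rotation.random(n, rng=np.random.default_rng(seed)).as_matrix()
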