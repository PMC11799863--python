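import numpy as np
import pytest

from psitunnel.frames import LandmarkSet, build_frame
from psitunnel.registration import RigidTransform
from psitunnel.synthetic_femur import FemurParams, generate_femur

# Coarser polygonization than the library default keeps mesh-heavy tests fast
# without changing any geometric contract under test.
TEST_PITCH = 2.0


@pytest.fixture(scope="session")
def femur():
    """One default synthetic femur, shared across mesh tests."""
    return generate_femur(FemurParams(pitch_mm=TEST_PITCH), seed=7)


@pytest.fixture(scope="session")
def small_study():
    """One small noiseless end-to-end simulated study (2 knees per group)."""
    from psitunnel.error_simulation import simulate_study

    return simulate_study(
        n_knees_per_group=2,
        seed=11,
        femur_params=FemurParams(pitch_mm=TEST_PITCH),
        icp_sample_size=1500,
    )


@pytest.fixture
def simple_landmarks():
    """Axis-aligned right knee: +x lateral, +y anterior, +z proximal."""
    return LandmarkSet(
        medial_epicondyle=[-40.0, 0.0, 0.0],
        lateral_epicondyle=[40.0, 0.0, 0.0],
        shaft_axis_point_distal=[0.0, 0.0, 0.0],
        shaft_axis_point_proximal=[0.0, 0.0, 100.0],
        most_anterior_trochlea=[0.0, 30.0, 0.0],
    )


@pytest.fixture
def lateral_frame(simple_landmarks):
    return build_frame(simple_landmarks, "lateral", "right")


@pytest.fixture
def medial_frame(simple_landmarks):
    return build_frame(simple_landmarks, "medial", "right")


def random_rigid(rng: np.random.Generator, max_angle_deg=180.0, max_shift=50.0):
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    return RigidTransform.from_axis_angle(
        axis,
        rng.uniform(-max_angle_deg, max_angle_deg),
        rng.uniform(-max_shift, max_shift, 3),
    )
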