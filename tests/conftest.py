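import numpy as np
import pytest
from hypothesis import settings

import soundnav as sn

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def hallway():
    """Empty study hallway: 3 m wide, 20 m long, 3 m ceiling."""
    return sn.build_hallway_mesh(3.0, 20.0, 3.0)


@pytest.fixture(scope="session")
def protocol():
    return sn.ProtocolConfig()


@pytest.fixture(scope="session")
def study_layout(protocol):
    """One concrete 5-column course (seed 1)."""
    return sn.generate_course(protocol, seed=1)


@pytest.fixture(scope="session")
def course_mesh(study_layout):
    return sn.course_to_mesh(study_layout)


@pytest.fixture(scope="session")
def empty_course():
    """Obstacle-free course for clean travel-direction geometry."""
    return sn.CourseLayout(
        hallway_width=3.0, hallway_length=20.0, course_length=12.0, obstacles=[]
    )


@pytest.fixture(scope="session")
def source_config():
    return sn.default_source_config()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
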