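import numpy as np
import pytest
from hypothesis import settings

from skinaniso.angular_io import AngularProfile, Configuration
from skinaniso.simulation import ellipse_polar_radius

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

GRID_36 = np.arange(36) * 10.0


def make_elliptical_profile(
    a: float,
    b: float,
    tilt_deg: float = 0.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    configuration: Configuration = Configuration.NATURAL,
    subject_id: str = "test",
    repeat_index: int | None = None,
) -> AngularProfile:
    """Noiseless (or radially noisy) 36-angle profile of a known ellipse."""
    r = ellipse_polar_radius(a, b, tilt_deg, GRID_36)
    if noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng(0)
        r = r + rng.normal(0, noise_sd, size=r.shape)
    return AngularProfile(
        subject_id=subject_id,
        configuration=configuration,
        angles_deg=GRID_36,
        rrt=r,
        repeat_index=repeat_index,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def circle_profile():
    return make_elliptical_profile(160.0, 160.0)


@pytest.fixture
def e07_profile():
    """Noiseless profile of the study's e=0.7 reference ellipse."""
    return make_elliptical_profile(224.044, 160.0)
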