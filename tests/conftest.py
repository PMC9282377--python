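import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tibiapipe.synthetic import PhantomSpec, generate_tibia

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def coarse_spec() -> PhantomSpec:
    return PhantomSpec.coarse()


@pytest.fixture(scope="session")
def coarse_phantom(coarse_spec):
    """Default reduced-resolution tibia phantom (0.04 mm voxels), seed 1."""
    image, truth = generate_tibia(coarse_spec, seed=1)
    return coarse_spec, image, truth


@pytest.fixture(scope="session")
def fine_phantom():
    """Finer phantom (0.03 mm voxels) for ground-truth recovery checks."""
    spec = PhantomSpec.coarse(voxel_size=0.03)
    image, truth = generate_tibia(spec, seed=2)
    return spec, image, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
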