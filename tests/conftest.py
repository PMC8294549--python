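import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from depthbench.registration import MarkerSet, RigidTransform
from depthbench.synthetic import random_rigid_transform

settings.register_profile(
    "det", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("det")


@pytest.fixture
def rng():
    return np.random.default_rng(20210721)


@pytest.fixture
def tetrahedron():
    """Four labeled non-coplanar points in the reference frame."""
    return MarkerSet.from_records(
        "M",
        [
            ("a", 0.0, 0.0, 0.0),
            ("b", 10.0, 0.0, 0.0),
            ("c", 0.0, 10.0, 0.0),
            ("d", 0.0, 0.0, 10.0),
        ],
    )


def make_random_points(rng, n, frame="M", scale=50.0, prefix="p"):
    pts = rng.uniform(-scale, scale, size=(n, 3))
    return MarkerSet(frame, tuple(f"{prefix}{i}" for i in range(n)), pts)


def make_random_transform(rng) -> RigidTransform:
    return random_rigid_transform(rng)
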