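import pytest
from hypothesis import HealthCheck, settings

import foragesim as fs

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

CANONICAL = {"a": 1e-3, "r": 100.0, "z": 3.1}


@pytest.fixture(scope="session")
def canonical_env():
    """Three patches with the canonical qualities (0.75, 0.5, 0.25)."""
    return fs.make_environment([0.75, 0.5, 0.25])


@pytest.fixture(scope="session")
def canonical_target(canonical_env):
    return fs.target_distribution(canonical_env)


@pytest.fixture(scope="session")
def pos_system(canonical_env):
    return fs.build_system("positive_only", canonical_env, a=1e-3, r=100.0)


@pytest.fixture(scope="session")
def neg_system(canonical_env):
    return fs.build_system("negative_feedback", canonical_env, a=1e-3, r=100.0, z=3.1)


@pytest.fixture(scope="session")
def asocial_system(canonical_env):
    return fs.build_system("asocial", canonical_env, a=1e-3, r=100.0)
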