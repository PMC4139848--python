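import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import metaneighbor as mn

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_collection():
    """4 samples x 3 features, labeled, with easy structure."""
    return mn.ProfileCollection(
        sample_ids=("A", "B", "C", "D"),
        feature_ids=("f1", "f2", "f3"),
        counts=np.array(
            [[10.0, 0.0, 0.0], [9.0, 1.0, 0.0], [0.0, 0.0, 10.0], [0.0, 1.0, 9.0]]
        ),
        labels=("x", "x", "y", "y"),
    )


@pytest.fixture
def random_collection():
    """20 samples x 12 features of seeded random nonnegative counts."""
    rng = np.random.default_rng(123)
    counts = rng.integers(0, 50, size=(20, 12)).astype(float) + 0.5
    return mn.ProfileCollection(
        sample_ids=tuple(f"S{i:02d}" for i in range(20)),
        feature_ids=tuple(f"F{j}" for j in range(12)),
        counts=counts,
        labels=tuple("ab"[i % 2] for i in range(20)),
    )


@pytest.fixture(scope="session")
def default_scenario():
    """The generator's default habitat-structured collection (seed 42)."""
    collection, truth = mn.generate_collection(mn.SyntheticConfig())
    return collection, truth
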