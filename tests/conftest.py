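import numpy as np
import pandas as pd
import pytest

from evora.matrix import MethylationMatrix, SampleAnnotation
from evora.simulate import SimConfig, simulate_cohort


def small_config(**overrides) -> SimConfig:
    """Reduced-size cohort for unit tests: same signal structure as the
    default study conditions, fewer CpGs so tests stay fast."""
    base = dict(
        n_cpgs=3000,
        n_risk=150,
        n_age=300,
        n_vcpg=100,
        seed=0,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """A seeded small cohort with planted risk/age/variable CpGs."""
    return simulate_cohort(small_config(seed=42))


@pytest.fixture(scope="session")
def null_cohort():
    """Signal-free cohort: case and control columns are exchangeable."""
    return simulate_cohort(small_config(n_cpgs=4000, n_risk=0, n_age=0, n_vcpg=0, seed=5))


@pytest.fixture
def tiny_matrix():
    rng = np.random.default_rng(3)
    beta = rng.uniform(0.05, 0.95, size=(20, 12))
    return MethylationMatrix(beta, [f"cg{i}" for i in range(20)], [f"s{i}" for i in range(12)])


@pytest.fixture
def tiny_annotation():
    rng = np.random.default_rng(4)
    return SampleAnnotation(
        pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(12)],
                "status": ["case"] * 6 + ["control"] * 6,
                "age": rng.uniform(20, 60, 12),
                "hpv": ["positive", "negative"] * 6,
            }
        )
    )
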