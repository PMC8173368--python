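import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from stmia.simulate import SyntheticParams, generate_sc, generate_st

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def small_params(**overrides) -> SyntheticParams:
    """Scaled-down generator parameters for fast unit tests."""
    base = dict(
        n_genes=600,
        n_groups=3,
        units_per_group=80,
        markers_per_group=20,
        marker_fold_change=4.0,
        frac_low_quality=0.1,
        seed=0,
    )
    base.update(overrides)
    return SyntheticParams(**base)


@pytest.fixture(scope="session")
def st_small():
    """One small spatial dataset shared across read-only tests."""
    return generate_st(small_params(seed=1))


@pytest.fixture(scope="session")
def sc_small():
    """One small single-cell dataset shared across read-only tests."""
    return generate_sc(small_params(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
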