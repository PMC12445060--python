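import numpy as np
import pytest
from hypothesis import settings

from radonrecon.meteorology import JointFrequencyTable
from radonrecon.sector_grid import default_grid
from radonrecon.source_term import EmissionTimeline
from radonrecon.synthetic_data import MetSpec, generate_met

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def timeline() -> EmissionTimeline:
    return EmissionTimeline.default()


@pytest.fixture(scope="session")
def grid():
    return default_grid()


def make_uniform_table(month: int = 1) -> JointFrequencyTable:
    """Perfectly flat table: h_s = 1/6, g = 1/96 per (direction, speed) cell."""
    return JointFrequencyTable(
        month=month,
        class_freq=np.full(6, 1 / 6),
        cond_freq=np.full((6, 16, 6), 1 / 96),
    )


def make_delta_table(s: int, d: int, q: int, month: int = 1) -> JointFrequencyTable:
    """All wind mass in a single (stability, direction, speed) cell."""
    h = np.zeros(6)
    h[s] = 1.0
    g = np.zeros((6, 16, 6))
    g[s, d, q] = 1.0
    # empty stability classes still need a normalized conditional table
    for other in range(6):
        if other != s:
            g[other] = 1 / 96
    return JointFrequencyTable(month=month, class_freq=h, cond_freq=g)


def make_random_table(rng: np.random.Generator, month: int = 1) -> JointFrequencyTable:
    h = rng.random(6) + 1e-3
    h /= h.sum()
    g = rng.random((6, 16, 6)) + 1e-6
    g /= g.sum(axis=(1, 2), keepdims=True)
    return JointFrequencyTable(month=month, class_freq=h, cond_freq=g)


@pytest.fixture(scope="session")
def uniform_table() -> JointFrequencyTable:
    return make_uniform_table()


@pytest.fixture(scope="session")
def met12_uniform() -> list[JointFrequencyTable]:
    return [make_uniform_table(m) for m in range(1, 13)]


@pytest.fixture(scope="session")
def met12_seeded() -> list[JointFrequencyTable]:
    return generate_met(MetSpec(seed=11))
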