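import math

import numpy as np
import pytest
from hypothesis import settings

from confconv import ThermalContext, ensemble_from_barriers

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")

RT_298 = 1.987204e-3 * 298.15


def direct_boltzmann(barriers, rt=RT_298):
    """Independent oracle: unshifted direct summation of Boltzmann factors.

    Safe in double precision for the barrier ranges used in tests
    (exp(-50/RT) ~ 1e-37 at 298 K); the library path uses a shifted
    log-sum-exp instead.
    """
    terms = [math.exp(-b / rt) for b in barriers]
    return -rt * math.log(math.fsum(terms) / len(terms))


def direct_de(barriers, rt=RT_298):
    """Oracle for the disproportionate effect: drop the first minimum."""
    idx = barriers.index(min(barriers))
    reduced = barriers[:idx] + barriers[idx + 1 :]
    full = direct_boltzmann(barriers, rt)
    return 100.0 * (direct_boltzmann(reduced, rt) - full) / full


@pytest.fixture
def thermal():
    return ThermalContext()


@pytest.fixture
def make_ensemble():
    return ensemble_from_barriers


@pytest.fixture
def random_barriers():
    """Factory of seeded random barrier lists in the chemical range."""

    def _make(n, seed, low=1.0, high=50.0):
        rng = np.random.default_rng(seed)
        return rng.uniform(low, high, size=n).tolist()

    return _make
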