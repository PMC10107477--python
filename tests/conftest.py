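import numpy as np
import pytest

from aiss import FixtureSpec, Molecule, make_fixture, overrides_for
from aiss.energy import BuiltinBackend

LJ_SIGMA = 3.4
LJ_EPSILON = 0.24


@pytest.fixture
def lj_spec() -> FixtureSpec:
    return FixtureSpec("lj_atom", sigma=LJ_SIGMA, epsilon=LJ_EPSILON)


@pytest.fixture
def lj_overrides(lj_spec):
    return overrides_for(lj_spec)


@pytest.fixture
def lj_backend(lj_overrides):
    return BuiltinBackend(lj_overrides)


@pytest.fixture
def lj_dimer(lj_spec):
    """Host and mobile LJ atoms, well separated as given."""
    a = make_fixture(lj_spec)
    b = make_fixture(
        FixtureSpec("lj_atom", sigma=LJ_SIGMA, epsilon=LJ_EPSILON, center=(9.0, 0.0, 0.0))
    )
    return a, b


def random_molecule(rng: np.random.Generator, n: int = 5) -> Molecule:
    """Seeded random cluster with enforced minimum spacing."""
    coords = [rng.uniform(-4, 4, 3)]
    while len(coords) < n:
        cand = rng.uniform(-4, 4, 3)
        if all(np.linalg.norm(cand - c) >= 1.0 for c in coords):
            coords.append(cand)
    return Molecule(["C"] * n, np.array(coords))
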