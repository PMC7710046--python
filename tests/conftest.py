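import numpy as np
import pytest

from afmsim import FixtureSpec, Structure, Atom, make_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def single_atom():
    return make_fixture(FixtureSpec(kind="single_atom", element="C"))[0]


@pytest.fixture
def helix():
    return make_fixture(FixtureSpec(kind="helix", n=20, helix_radius=0.5, pitch=0.55))[0]


@pytest.fixture
def ring7():
    return make_fixture(FixtureSpec(kind="ring", n=7, ring_radius=2.0, element="S"))[0]


def random_structure(rng, n_atoms=10, box=2.0, r_range=(0.12, 0.23)):
    """Random atoms uniform in a cube of side `box` with random radii."""
    coords = rng.uniform(0.0, box, size=(n_atoms, 3))
    radii = rng.uniform(*r_range, size=n_atoms)
    atoms = [
        Atom(element="C", position=c, vdw_radius=float(r), serial=i + 1)
        for i, (c, r) in enumerate(zip(coords, radii))
    ]
    return Structure(atoms=atoms, label="random")
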