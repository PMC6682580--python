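import math

import numpy as np
import pytest

from posestab.model import Atom, Bond, BondGraph, Molecule, PoseEnsemble
from posestab.synthetic import SyntheticSpec, make_benchmark_dataset


def build_molecule(elements, coords, bonds, mol_id="m"):
    atoms = [Atom(element=e, coords=np.asarray(c, dtype=float)) for e, c in zip(elements, coords)]
    graph = BondGraph([Bond(i, j, order) for i, j, order in bonds], len(atoms))
    return Molecule(atoms=atoms, bonds=graph, id=mol_id)


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def rigid_motion(coords, rng):
    rot = random_rotation(rng)
    trans = rng.uniform(-10, 10, size=3)
    return coords @ rot.T + trans


@pytest.fixture
def rng():
    return np.random.default_rng(20180918)


@pytest.fixture
def butane():
    # heavy-atom chain C-C-C-C (zigzag in the xy-plane)
    coords = [(0.0, 0.0, 0.0), (1.5, 0.0, 0.0), (2.0, 1.4, 0.0), (3.5, 1.4, 0.0)]
    return build_molecule("CCCC", coords, [(0, 1, 1), (1, 2, 1), (2, 3, 1)], "butane")


@pytest.fixture
def ring6():
    # six-membered aromatic carbon ring, unit C-C distance 1.4 A
    coords = [
        (1.4 * math.cos(i * math.pi / 3), 1.4 * math.sin(i * math.pi / 3), 0.0) for i in range(6)
    ]
    bonds = [(i, (i + 1) % 6, "ar") for i in range(6)]
    return build_molecule("CCCCCC", coords, bonds, "ring6")


@pytest.fixture(scope="session")
def small_benchmark():
    """20-compound default-noise benchmark shared across tests."""
    return make_benchmark_dataset(SyntheticSpec(n_compounds=20, seed=7))
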