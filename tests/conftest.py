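"""Shared fixtures.

Expensive artifacts (toy dimer, its constraint network, decomposition,
templates and mode set) are session-scoped: the generators are
deterministic, and the objects are treated as read-only by the tests.
"""

import numpy as np
import pytest

from dimerflex.synth import make_toy_dimer, ToyDimerSpec
from dimerflex.enm import build_enm, compute_modes
from dimerflex.rigidity import build_constraint_network, pebble_game
from dimerflex.geosim import build_templates
from dimerflex.measures import toy_measures
from dimerflex.structures import Structure

import biotite.structure as struc


@pytest.fixture(scope="session")
def toy():
    return make_toy_dimer()


@pytest.fixture(scope="session")
def toy_modes(toy):
    return compute_modes(build_enm(toy.structure), n_modes=24)


@pytest.fixture(scope="session")
def toy_network(toy):
    return build_constraint_network(toy.structure)


@pytest.fixture(scope="session")
def toy_decomposition(toy_network):
    return pebble_game(toy_network)


@pytest.fixture(scope="session")
def toy_templates(toy, toy_decomposition, toy_network):
    return build_templates(toy.structure, toy_decomposition, toy_network)


@pytest.fixture(scope="session")
def toy_measure_set(toy):
    return toy_measures(toy)


def _strand(n_res, origin, rng):
    """One idealized extended strand: N, H, CA, C, O per residue.

    Synthetic stand-in geometry (not a real peptide conformation): bond
    lengths are physical, the backbone is flattened so that cross-strand
    N-H...O=C hydrogen bonds are near-linear.
    """
    names, elements, res_ids, coords = [], [], [], []
    ox, oy, oz = origin
    for i in range(n_res):
        x = ox + i * 3.5
        atoms = [
            ("N", "N", (x, oy, oz)),
            ("H", "H", (x, oy - 1.0, oz)),
            ("CA", "C", (x + 1.2, oy + 0.8, oz)),
            ("C", "C", (x + 2.3, oy, oz)),
            ("O", "O", (x + 2.0, oy - 1.19, oz)),
        ]
        for name, el, pos in atoms:
            names.append(name)
            elements.append(el)
            res_ids.append(i + 1)
            coords.append(pos)
    jitter = rng.uniform(-0.02, 0.02, size=(len(coords), 3))
    return names, elements, res_ids, np.asarray(coords) + jitter


@pytest.fixture(scope="session")
def peptide():
    """Synthetic all-atom two-strand sheet with cross-strand hydrogen
    bonds; exercises the atomistic (body-bar) code paths."""
    rng = np.random.default_rng(42)
    n1, e1, r1, c1 = _strand(4, (0.0, 0.0, 0.0), rng)
    # second strand below, flipped so its carbonyls accept the first
    # strand's N-H donors (N...O about 2.9 A, near-linear)
    n2, e2, r2, c2 = _strand(4, (-2.0, 0.0, 0.0), rng)
    c2 = c2.copy()
    c2[:, 1] = -4.13 - c2[:, 1]  # mirror in y, placing O at y ~ -2.9
    names = n1 + n2
    elements = e1 + e2
    res_ids = r1 + [r + 10 for r in r2]
    coords = np.vstack([c1, c2])
    atoms = struc.AtomArray(len(names))
    atoms.coord = coords.astype(np.float32)
    atoms.chain_id = np.array(["A"] * len(n1) + ["B"] * len(n2))
    atoms.res_id = np.array(res_ids)
    atoms.res_name = np.array(["ALA"] * len(names))
    atoms.atom_name = np.array(names)
    atoms.element = np.array(elements)
    atoms.hetero = np.zeros(len(names), dtype=bool)
    return Structure(struc.stack([atoms]), source_id="synthetic-sheet")
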