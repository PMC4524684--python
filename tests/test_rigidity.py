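"""Constraint detection, the pebble game and rigid decomposition."""

import numpy as np
import pytest

import biotite.structure as struc

from dimerflex.structures import Structure
from dimerflex.rigidity import (RigidityConfig, detect_covalent,
                                detect_hbonds, detect_hydrophobic,
                                build_constraint_network, pebble_game,
                                PebbleGame, _mayo_energy, Constraint,
                                ConstraintNetwork)


def _atoms(specs):
    """specs: list of (name, element, res_id, chain, xyz)."""
    atoms = struc.AtomArray(len(specs))
    atoms.coord = np.array([s[4] for s in specs], dtype=np.float32)
    atoms.atom_name = np.array([s[0] for s in specs])
    atoms.element = np.array([s[1] for s in specs])
    atoms.res_id = np.array([s[2] for s in specs])
    atoms.chain_id = np.array([s[3] for s in specs])
    atoms.res_name = np.array(["ALA"] * len(specs))
    atoms.hetero = np.zeros(len(specs), dtype=bool)
    return Structure(struc.stack([atoms]))


def _point_structure(coords):
    return _atoms([("CA", "C", i + 1, "A", tuple(c))
                   for i, c in enumerate(np.asarray(coords, dtype=float))])


# -- covalent ---------------------------------------------------------------

def test_carbon_pair_distance_rule():
    near = _atoms([("C1", "C", 1, "A", (0, 0, 0)),
                   ("C2", "C", 1, "A", (1.5, 0, 0))])
    far = _atoms([("C1", "C", 1, "A", (0, 0, 0)),
                  ("C2", "C", 1, "A", (2.5, 0, 0))])
    assert detect_covalent(near) == [(0, 1)]
    assert detect_covalent(far) == []


def test_disulfide_rule():
    ss = _atoms([("SG", "S", 1, "A", (0, 0, 0)),
                 ("SG", "S", 2, "A", (2.05, 0, 0))])
    assert detect_covalent(ss) == [(0, 1)]


def test_coarse_chain_bonds(toy):
    bonds = detect_covalent(toy.structure)
    s = toy.structure.stack
    for a, b in bonds:
        assert s.chain_id[a] == s.chain_id[b]
        assert abs(int(s.res_id[a]) - int(s.res_id[b])) == 1
    # the hinge-critical backbone path core->linker->mobile is connected
    core_hi = toy.core_range[1]
    attach = toy.attachment_res
    pairs = {(min(int(s.res_id[a]), int(s.res_id[b])),
              max(int(s.res_id[a]), int(s.res_id[b])))
             for a, b in bonds if s.chain_id[a] == "A"}
    for r in range(core_hi, attach):
        assert (r, r + 1) in pairs


# -- hydrogen bonds ---------------------------------------------------------

def test_hbond_energy_function_oracle():
    """Direct evaluation of the distance-angle energy at known
    geometries."""
    cfg = RigidityConfig()
    ideal = _mayo_energy(2.8, -1.0, cfg)       # linear, equilibrium
    assert ideal <= -2.0
    assert abs(ideal - (-cfg.hbond_well_depth)) < 1e-12
    long = _mayo_energy(4.5, -1.0, cfg)        # too long
    assert long > -2.0
    right_angle = _mayo_energy(2.8, 0.0, cfg)  # 90 degree geometry
    assert right_angle == 0.0
    # monotone penalty with bending at fixed distance
    thetas = np.linspace(np.pi, np.pi / 2, 20)
    energies = [_mayo_energy(2.8, np.cos(t), cfg) for t in thetas]
    assert all(np.diff(energies) >= 0)


def test_peptide_sheet_hbonds_detected(peptide):
    hbonds = detect_hbonds(peptide)
    assert len(hbonds) >= 3
    assert all(hbonds[i].energy <= hbonds[i + 1].energy
               for i in range(len(hbonds) - 1))
    strong = [hb for hb in hbonds if hb.energy <= -2.0]
    assert len(strong) >= 3  # the designed cross-strand bonds


def test_hbond_heavy_atom_fallback(peptide):
    """Stripping hydrogens still finds the cross-strand bonds via the
    donor-frame approximation."""
    keep = peptide.stack.element != "H"
    stripped = Structure(peptide.stack[:, keep])
    with pytest.raises(ValueError):
        detect_hbonds(stripped, heavy_atom_fallback=False)
    hbonds = detect_hbonds(stripped, heavy_atom_fallback=True)
    assert any(hb.energy <= -2.0 for hb in hbonds)


# -- hydrophobic ------------------------------------------------------------

def test_hydrophobic_rules():
    contact = 2 * 1.7 + 0.2  # vdW sum + 0.2, inside the threshold
    s = _atoms([("CB", "C", 1, "A", (0, 0, 0)),
                ("CB", "C", 2, "A", (contact, 0, 0)),
                ("N", "N", 3, "A", (0, 3.0, 0)),
                ("CG", "C", 1, "A", (0, 0, 1.5))])
    tethers = detect_hydrophobic(s)
    assert (0, 1) in tethers
    assert all(2 not in pair for pair in tethers)     # nitrogen never
    assert (0, 3) not in tethers                      # same residue


# -- network assembly -------------------------------------------------------

def test_energy_cutoff_monotonicity(peptide):
    net_strict = build_constraint_network(peptide, energy_cutoff=-2.0,
                                          config=RigidityConfig())
    net_loose = build_constraint_network(peptide, energy_cutoff=-0.5,
                                         config=RigidityConfig())
    hb_strict = set(net_strict.pairs_of_kind("hbond"))
    hb_loose = set(net_loose.pairs_of_kind("hbond"))
    assert hb_strict <= hb_loose
    net_none = build_constraint_network(peptide, energy_cutoff=-np.inf,
                                        config=RigidityConfig())
    assert net_none.pairs_of_kind("hbond") == []
    assert len(net_none.pairs_of_kind("covalent", "peptide-locked")) > 0


def test_peptide_bonds_are_six_bar(peptide):
    net = build_constraint_network(peptide)
    locked = [c for c in net.constraints if c.kind == "peptide-locked"]
    assert len(locked) == 6  # three per strand of four residues
    assert all(c.bars == 6 for c in locked)


def test_toy_network_composition(toy_network, toy):
    kinds = {c.kind for c in toy_network.constraints}
    assert kinds == {"covalent", "hydrophobic"}
    assert toy_network.mode == "coarse"
    # linkers contribute chain bonds only; the cleft is unbridged
    s = toy.structure.stack
    lo, hi = toy.mobile_range
    core_lo, core_hi = toy.core_range
    for c in toy_network.constraints:
        ri, rj = int(s.res_id[c.i]), int(s.res_id[c.j])
        mobile_core = ({ri >= lo, rj >= lo} == {True, False}
                       and min(ri, rj) <= core_hi)
        if mobile_core and c.kind == "hydrophobic":
            pytest.fail("tether bridges the cleft between mobile and core")


# -- pebble game ------------------------------------------------------------

def test_maxwell_counting_examples():
    g = PebbleGame(3, 3)
    assert g.insert_bar(0, 1)
    assert g.insert_bar(1, 2)
    assert g.floppy_modes == 3 * 3 - 6 - 2
    assert g.insert_bar(0, 2)
    assert g.floppy_modes == 0


def test_triangle_is_one_rigid_cluster():
    coords = np.array([[0.0, 0, 0], [3.0, 0.1, 0], [1.4, 2.8, 0.2]])
    net = ConstraintNetwork(
        n_atoms=3, coords=coords,
        constraints=[Constraint(0, 1, 1, "covalent"),
                     Constraint(1, 2, 1, "covalent"),
                     Constraint(0, 2, 1, "covalent")],
        mode="coarse", energy_cutoff=-2.0, config=RigidityConfig())
    dec = pebble_game(net)
    assert dec.floppy_modes == 0
    assert dec.n_clusters == 1


@pytest.mark.parametrize("batch", range(5))
def test_floppy_count_matches_jacobian_rank(batch):
    """On random generic small frameworks the game's floppy count equals
    3N - 6 - rank of the numerical rigidity matrix (SVD oracle)."""
    rng = np.random.default_rng(1000 + batch)
    for _ in range(12):
        n = int(rng.integers(4, 13))
        coords = rng.uniform(0, 10, size=(n, 3))
        all_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        m = int(rng.integers(n, min(len(all_pairs), 3 * n - 6) + 1))
        chosen = rng.choice(len(all_pairs), size=m, replace=False)
        pairs = [all_pairs[i] for i in chosen]
        game = PebbleGame(n, 3, coords=coords)
        for i, j in pairs:
            game.insert_bar(i, j)
        rows = np.zeros((m, 3 * n))
        for r, (i, j) in enumerate(pairs):
            d = coords[i] - coords[j]
            rows[r, 3 * i: 3 * i + 3] = d
            rows[r, 3 * j: 3 * j + 3] = -d
        sv = np.linalg.svd(rows, compute_uv=False)
        rank = int(np.sum(sv > 1e-6 * sv.max()))
        assert game.floppy_modes == max(3 * n - 6 - rank, 0)


def test_insertion_order_invariance(toy_network):
    rng = np.random.default_rng(3)
    ref = pebble_game(toy_network)
    for _ in range(3):
        order = rng.permutation(len(toy_network.constraints)).tolist()
        dec = pebble_game(toy_network, order=order)
        assert dec.floppy_modes == ref.floppy_modes
        assert dec.n_independent == ref.n_independent


def test_floppy_count_non_increasing():
    rng = np.random.default_rng(11)
    coords = rng.uniform(0, 8, size=(8, 3))
    game = PebbleGame(8, 3, coords=coords)
    prev = game.floppy_modes
    pairs = [(i, j) for i in range(8) for j in range(i + 1, 8)]
    rng.shuffle(pairs)
    for i, j in pairs[:18]:
        game.insert_bar(i, j)
        assert game.floppy_modes <= prev
        prev = game.floppy_modes


def test_decomposition_invariant_under_rigid_transform(toy, toy_decomposition):
    from scipy.spatial.transform import Rotation
    rot = Rotation.from_rotvec([1.0, 0.2, -0.4]).as_matrix()
    moved = toy.structure.with_coords(toy.structure.coords(0) @ rot.T
                                      + np.array([3.0, -7, 2]))
    dec2 = pebble_game(build_constraint_network(moved))
    assert dec2.floppy_modes == toy_decomposition.floppy_modes
    # identical partition up to label renaming
    ref = toy_decomposition.cluster_labels
    lab = dec2.cluster_labels
    mapping = {}
    for a, b in zip(ref, lab):
        assert mapping.setdefault(a, b) == b


def test_toy_domains_are_rigid_and_linkers_variable(toy, toy_network,
                                                    toy_decomposition):
    s = toy.structure.stack
    labels = toy_decomposition.cluster_labels
    for chain in ("A", "B"):
        for domain in ("core", "mobile"):
            res = set(toy.domain_residues(domain))
            idx = [i for i in range(toy.structure.n_atoms)
                   if s.chain_id[i] == chain and int(s.res_id[i]) in res]
            assert len({labels[i] for i in idx}) == 1
    hinge = toy.hinge_res
    variable_bonds = [(int(s.res_id[i]), int(s.res_id[j]))
                      for (i, j), lab in
                      toy_decomposition.bond_labels.items()
                      if lab == "variable"
                      and abs(int(s.res_id[i]) - int(s.res_id[j])) == 1]
    assert any(hinge in pair for pair in variable_bonds)


def test_peptide_body_bar_decomposition(peptide):
    net = build_constraint_network(peptide)
    dec = pebble_game(net)
    assert dec.floppy_modes >= 0
    # every peptide bond is interior to some rigid pairing or labelled
    labels = set(dec.bond_labels.values())
    assert labels <= {"locked", "variable"}
    # atoms partitioned
    assert len(dec.cluster_labels) == peptide.n_atoms


def test_empty_network_raises():
    net = ConstraintNetwork(n_atoms=2, coords=np.zeros((2, 3)),
                            constraints=[], mode="coarse",
                            energy_cutoff=-2.0, config=RigidityConfig())
    with pytest.raises(ValueError):
        pebble_game(net)
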