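"""Template construction, relaxation and biased geometric simulation."""

import numpy as np
import pytest

from dimerflex.rigidity import (Constraint, ConstraintNetwork,
                                RigidityConfig, pebble_game)
from dimerflex.geosim import (GeoSimConfig, build_templates, relax,
                              run_geosim, _RelaxContext)
from dimerflex.enm import build_enm, compute_modes, atomize_bias
from dimerflex.measures import toy_measures
from dimerflex.pipeline import classify_cleft_modes

import biotite.structure as struc
from dimerflex.structures import Structure


def _point_structure(coords):
    coords = np.asarray(coords, dtype=float)
    atoms = struc.AtomArray(len(coords))
    atoms.coord = coords.astype(np.float32)
    atoms.chain_id = np.array(["A"] * len(coords))
    atoms.res_id = np.arange(1, len(coords) + 1)
    atoms.res_name = np.array(["ALA"] * len(coords))
    atoms.atom_name = np.array(["CA"] * len(coords))
    atoms.element = np.array(["C"] * len(coords))
    atoms.hetero = np.zeros(len(coords), dtype=bool)
    return Structure(struc.stack([atoms]))


def _net(coords, pairs, kinds=None):
    kinds = kinds or ["covalent"] * len(pairs)
    cons = [Constraint(i, j, 1, k) for (i, j), k in zip(pairs, kinds)]
    return ConstraintNetwork(n_atoms=len(coords),
                             coords=np.asarray(coords, dtype=float),
                             constraints=cons, mode="coarse",
                             energy_cutoff=-2.0, config=RigidityConfig())


@pytest.fixture(scope="module")
def antisym_run(toy, toy_modes, toy_network, toy_decomposition,
                toy_templates, toy_measure_set):
    """One anti-symmetric-mode geosim run shared by several tests."""
    picks = classify_cleft_modes(toy_modes, toy.structure, toy_measure_set)
    mode = picks["antisymmetric"]
    assert mode is not None
    bias = atomize_bias(toy_modes.mode(mode), toy.structure, toy_modes,
                        step=0.02)
    config = GeoSimConfig(bias_step=0.02, random_step=0.01,
                          max_steps=2000, seed=0, save_interval=50)
    return run_geosim(toy.structure, bias, toy_templates, toy_network,
                      config, rigid=toy_decomposition,
                      bias_label=f"mode{mode}")


def test_fully_rigid_framework_gives_single_template():
    coords = np.array([[0.0, 0, 0], [3.0, 0.2, 0], [1.4, 2.8, 0.1],
                       [1.6, 1.0, 2.6]])
    pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
    net = _net(coords, pairs)
    dec = pebble_game(net)
    assert dec.floppy_modes == 0
    tset = build_templates(_point_structure(coords), dec, net)
    assert len(tset.indices) == 1
    assert set(tset.indices[0]) == {0, 1, 2, 3}


def test_two_clusters_share_junction_template():
    # two tetrahedra joined by one rotatable bond 3-4
    t1 = np.array([[0.0, 0, 0], [3.0, 0.2, 0], [1.4, 2.8, 0.1],
                   [1.6, 1.0, 2.6]])
    t2 = t1 + np.array([6.5, 0.3, 0.4])
    coords = np.vstack([t1, t2])
    pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
    pairs += [(i + 4, j + 4) for i, j in pairs[:6]]
    pairs.append((3, 4))
    net = _net(coords, pairs)
    dec = pebble_game(net)
    tset = build_templates(_point_structure(coords), dec, net)
    sizes = sorted(len(i) for i in tset.indices)
    assert sizes == [2, 4, 4]
    junction = [idx for idx in tset.indices if len(idx) == 2][0]
    assert set(junction) == {3, 4}


def test_template_reference_equals_input(toy, toy_templates, toy_network):
    for idx, ref in zip(toy_templates.indices, toy_templates.references):
        np.testing.assert_allclose(ref, toy_network.coords[idx])


def test_relax_recovers_small_perturbation(toy, toy_templates, toy_network,
                                           toy_decomposition):
    cfg = GeoSimConfig()
    ctx = _RelaxContext(toy.structure, toy_templates, toy_network, cfg,
                        toy_decomposition)
    pos = toy.structure.coords(0).copy()
    pos[40] += [0.05, -0.02, 0.04]
    out, converged, viol = relax(pos, ctx)
    assert converged
    assert viol <= cfg.relax_tolerance


def test_relax_separates_overlapping_atoms():
    coords = np.array([[0.0, 0, 0], [10.0, 0, 0], [0.4, 0.0, 0.1],
                       [10.0, 4.0, 0]])
    net = _net(coords, [(0, 1), (1, 3)])
    dec = pebble_game(net)
    s = _point_structure(coords)
    tset = build_templates(s, dec, net)
    cfg = GeoSimConfig()
    ctx = _RelaxContext(s, tset, net, cfg, dec)
    out, converged, viol = relax(coords.copy(), ctx)
    contact = 2 * 1.7 * cfg.steric_scale
    d = np.linalg.norm(out[0] - out[2])
    assert d >= contact - cfg.relax_tolerance - 1e-9


def test_relax_nonconvergence_flag(toy, toy_templates, toy_network,
                                   toy_decomposition):
    cfg = GeoSimConfig(max_relax_iters=1)
    ctx = _RelaxContext(toy.structure, toy_templates, toy_network, cfg,
                        toy_decomposition)
    pos = toy.structure.coords(0).copy()
    pos[5] += [10.0, 0, 0]  # atom dragged far out of its rigid cluster
    _, converged, viol = relax(pos, ctx)
    assert not converged
    assert viol > cfg.relax_tolerance


def test_zero_steps_returns_input(toy, toy_templates, toy_network,
                                  toy_decomposition):
    bias = np.zeros((toy.structure.n_atoms, 3))
    cfg = GeoSimConfig(max_steps=0)
    traj = run_geosim(toy.structure, bias, toy_templates, toy_network, cfg,
                      rigid=toy_decomposition)
    assert traj.frames.n_models == 1
    assert not traj.jammed
    np.testing.assert_allclose(traj.frames.coords(0),
                               toy.structure.coords(0))


def test_zero_bias_zero_noise_is_fixed_point(toy, toy_templates,
                                             toy_network,
                                             toy_decomposition):
    bias = np.zeros((toy.structure.n_atoms, 3))
    cfg = GeoSimConfig(random_step=0.0, max_steps=30, jam_patience=10,
                       save_interval=10)
    traj = run_geosim(toy.structure, bias, toy_templates, toy_network, cfg,
                      rigid=toy_decomposition)
    np.testing.assert_allclose(traj.frames.coords(traj.frames.n_models - 1),
                               toy.structure.coords(0), atol=1e-9)


def test_translation_bias_drifts_centroid_and_keeps_measures(
        toy, toy_templates, toy_network, toy_decomposition,
        toy_measure_set):
    field = np.tile([0.02, 0.0, 0.0], (toy.structure.n_atoms, 1))
    cfg = GeoSimConfig(bias_step=0.02, random_step=0.0, max_steps=200,
                       save_interval=100)
    traj = run_geosim(toy.structure, field, toy_templates, toy_network,
                      cfg, rigid=toy_decomposition)
    assert not traj.jammed
    drift = traj.frames.coords(traj.frames.n_models - 1).mean(axis=0) \
        - toy.structure.coords(0).mean(axis=0)
    assert drift[0] > 3.0
    df = toy_measure_set.series(traj.frames)
    for name in ("d_AB", "d_BA", "hinge_A"):
        assert df[name].std() < 0.05


def test_parallel_antiparallel_start_opposite(toy, toy_modes,
                                              toy_templates, toy_network,
                                              toy_decomposition):
    bias = atomize_bias(toy_modes.mode(7), toy.structure, toy_modes,
                        step=0.02)
    signs = []
    for direction in ("parallel", "antiparallel"):
        cfg = GeoSimConfig(bias_step=0.02, random_step=0.0, max_steps=5,
                           direction=direction, save_interval=1)
        traj = run_geosim(toy.structure, bias, toy_templates, toy_network,
                          cfg, rigid=toy_decomposition)
        delta = (traj.frames.coords(1) - toy.structure.coords(0)).ravel()
        signs.append(np.sign(delta @ bias.ravel()))
    assert signs[0] > 0 > signs[1]


def test_antisym_run_is_anticorrelated_and_jams(antisym_run,
                                                toy_measure_set):
    traj = antisym_run
    assert traj.jammed
    df = toy_measure_set.series(traj.frames)
    r = np.corrcoef(df["d_AB"], df["d_BA"])[0, 1]
    assert r < -0.5
    # one cleft closes, the other opens
    spans = (df["d_AB"].iloc[-1] - df["d_AB"].iloc[0],
             df["d_BA"].iloc[-1] - df["d_BA"].iloc[0])
    assert min(spans) < -2.0 and max(spans) > 2.0


def test_frames_respect_bonds_and_sterics(antisym_run, toy_network):
    """Along every non-jammed frame covalent distances stay within
    tolerance and nonbonded pairs stay outside contact minus tolerance."""
    from scipy.spatial import cKDTree
    cfg = antisym_run.config
    tol = cfg.relax_tolerance
    contact = 2 * 1.7 * cfg.steric_scale
    cov = toy_network.pairs_of_kind("covalent")
    d0 = {p: np.linalg.norm(toy_network.coords[p[0]]
                            - toy_network.coords[p[1]]) for p in cov}
    excluded = {c.pair() for c in toy_network.constraints}
    for f in range(antisym_run.frames.n_models):
        pos = antisym_run.frames.coords(f)
        for (i, j), ref in d0.items():
            assert abs(np.linalg.norm(pos[i] - pos[j]) - ref) <= tol + 1e-6
        tree = cKDTree(pos)
        for a, b in tree.query_pairs(r=contact):
            if (min(a, b), max(a, b)) not in excluded:
                d = np.linalg.norm(pos[a] - pos[b])
                assert d >= contact - tol - 1e-6


def test_bias_shape_mismatch_raises(toy, toy_templates, toy_network):
    with pytest.raises(ValueError):
        run_geosim(toy.structure, np.zeros((3, 3)), toy_templates,
                   toy_network, GeoSimConfig(max_steps=1))
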