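"""Coarse-grained elastic network model (ENM) and normal-mode machinery.

One site per residue is placed on the C-alpha geometry and springs of equal
stiffness connect every pair of sites within a distance cutoff (default 12 A,
crossing chain boundaries as well as within chains).  Diagonalising the
3N x 3N second-derivative matrix yields six trivial zero-frequency modes
(rigid-body translations/rotations of a connected network) followed by the
nontrivial modes; with modes numbered from 1, the lowest nontrivial mode is
mode 7.  Only mode shapes and their ordering are meaningful: the spring
constant sets an arbitrary overall eigenvalue scale.

Low-frequency modes and their normalised linear combinations, e.g.
``(e8 + e7)/sqrt(2)``, serve as bias directions for the geometric simulation
engine in :mod:`dimerflex.geosim`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial import cKDTree
from scipy.sparse.csgraph import connected_components
from scipy.sparse import coo_matrix

from .structures import Structure, SelectionSpec

__all__ = [
    "ElasticNetwork",
    "ModeSet",
    "build_enm",
    "compute_modes",
    "combine_modes",
    "atomize_bias",
    "transition_overlap",
]

TRIVIAL_TOL = 1e-8  # eigenvalue < TRIVIAL_TOL * max eigenvalue => trivial


@dataclass
class ElasticNetwork:
    """Uniform-spring elastic network over residue sites.

    Attributes
    ----------
    sites : (N, 3) float array, Angstrom
    residue_keys : list of (chain_id, res_id, ins_code), one per site
    pairs : (M, 2) int array, each i < j, one spring per row
    cutoff : interaction distance cutoff, Angstrom
    k : uniform spring constant (arbitrary units)
    """

    sites: np.ndarray
    residue_keys: list
    pairs: np.ndarray
    cutoff: float
    k: float

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def is_connected(self) -> bool:
        n = self.n_sites
        if len(self.pairs) == 0:
            return n <= 1
        data = np.ones(len(self.pairs))
        adj = coo_matrix((data, (self.pairs[:, 0], self.pairs[:, 1])),
                         shape=(n, n))
        ncomp, _ = connected_components(adj, directed=False)
        return ncomp == 1


@dataclass
class ModeSet:
    """Normal modes of an elastic network, numbered from 1.

    ``eigenvectors[:, m]`` is the unit-norm 3N displacement of mode ``m+1``;
    eigenvalues ascend, the first ``n_trivial`` (six, for a connected
    network) being numerically zero.  ``mode(7)`` is the first nontrivial
    mode.
    """

    eigenvalues: np.ndarray          # (n_modes,) ascending, >= 0
    eigenvectors: np.ndarray         # (3N, n_modes) orthonormal columns
    residue_keys: list
    n_trivial: int

    @property
    def n_sites(self) -> int:
        return self.eigenvectors.shape[0] // 3

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[1]

    def mode(self, number: int) -> np.ndarray:
        """Unit 3N eigenvector of 1-based mode ``number``."""
        if not 1 <= number <= self.n_modes:
            raise IndexError(f"mode {number} outside 1..{self.n_modes}")
        return self.eigenvectors[:, number - 1]

    def per_residue(self, vector: np.ndarray) -> np.ndarray:
        """Reshape a 3N vector to (N, 3) per-residue displacements."""
        return np.asarray(vector, dtype=float).reshape(-1, 3)

    def to_csv(self, path: str | Path) -> None:
        """Full-precision CSV export (one row per mode x residue)."""
        n = self.n_sites
        rows = []
        for m in range(self.n_modes):
            vec = self.per_residue(self.eigenvectors[:, m])
            for i, (cid, rid, ic) in enumerate(self.residue_keys):
                rows.append((m + 1, repr(float(self.eigenvalues[m])),
                             cid, rid, ic,
                             repr(float(vec[i, 0])), repr(float(vec[i, 1])),
                             repr(float(vec[i, 2]))))
        df = pd.DataFrame(rows, columns=["mode", "eigenvalue", "chain",
                                         "res_id", "ins_code", "x", "y", "z"])
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ModeSet":
        df = pd.read_csv(path, keep_default_na=False,
                         float_precision="round_trip")
        modes = sorted(df["mode"].unique())
        sub0 = df[df["mode"] == modes[0]]
        residue_keys = [(str(c), int(r), str(i)) for c, r, i in
                        zip(sub0["chain"], sub0["res_id"], sub0["ins_code"])]
        n = len(residue_keys)
        vecs = np.empty((3 * n, len(modes)))
        vals = np.empty(len(modes))
        for j, m in enumerate(modes):
            sub = df[df["mode"] == m]
            vals[j] = float(sub["eigenvalue"].iloc[0])
            vecs[:, j] = np.column_stack(
                [sub["x"].astype(float), sub["y"].astype(float),
                 sub["z"].astype(float)]).ravel()
        n_trivial = int(np.sum(vals < TRIVIAL_TOL * max(vals.max(), 1.0)))
        return cls(vals, vecs, residue_keys, n_trivial)


def build_enm(structure: Structure, cutoff: float = 12.0, k: float = 1.0,
              model: int = 0) -> ElasticNetwork:
    """Place springs between all C-alpha pairs within ``cutoff`` Angstrom.

    Residues without a C-alpha atom are skipped (absent from the network and
    from bias mapping).  Springs cross the chain interface like any other
    pair.
    """
    ca = structure.ca_indices()
    if len(ca) < 3:
        raise ValueError("need at least 3 C-alpha sites for an ENM")
    coords = structure.coords(model)[ca]
    stack = structure.stack
    ins = stack.ins_code if "ins_code" in stack.get_annotation_categories() \
        else np.full(structure.n_atoms, "")
    keys = [(str(stack.chain_id[i]), int(stack.res_id[i]), str(ins[i]))
            for i in ca]
    tree = cKDTree(coords)
    pairs = np.array(sorted(tree.query_pairs(r=cutoff)), dtype=int)
    if pairs.size == 0:
        pairs = pairs.reshape(0, 2)
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1) \
        if len(pairs) else np.array([])
    if len(d) and d.min() < 1e-6:
        raise ValueError("duplicate site coordinates in elastic network")
    return ElasticNetwork(sites=coords, residue_keys=keys, pairs=pairs,
                          cutoff=float(cutoff), k=float(k))


def hessian(enm: ElasticNetwork) -> np.ndarray:
    """Dense 3N x 3N isotropic (ANM-style) second-derivative matrix."""
    n = enm.n_sites
    h = np.zeros((3 * n, 3 * n))
    for i, j in enm.pairs:
        d = enm.sites[j] - enm.sites[i]
        r2 = d @ d
        block = -enm.k * np.outer(d, d) / r2
        sl_i, sl_j = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        h[sl_i, sl_j] += block
        h[sl_j, sl_i] += block
        h[sl_i, sl_i] -= block
        h[sl_j, sl_j] -= block
    return h


def compute_modes(enm: ElasticNetwork, n_modes: int | None = None,
                  allow_disconnected: bool = False) -> ModeSet:
    """Diagonalise the ENM Hessian.

    A connected network yields exactly six zero modes; more than six signals
    a disconnected network and raises unless ``allow_disconnected``.
    """
    if not allow_disconnected and not enm.is_connected():
        raise ValueError("elastic network is disconnected (would have more "
                         "than 6 zero modes); pass allow_disconnected=True "
                         "to override")
    h = hessian(enm)
    if n_modes is None or n_modes >= 3 * enm.n_sites:
        vals, vecs = eigh(h)
    else:
        vals, vecs = eigh(h, subset_by_index=[0, n_modes - 1])
    vals = np.clip(vals, 0.0, None)
    scale = max(vals.max(), 1.0)
    n_trivial = int(np.sum(vals < TRIVIAL_TOL * scale))
    return ModeSet(eigenvalues=vals, eigenvectors=vecs,
                   residue_keys=enm.residue_keys, n_trivial=n_trivial)


def combine_modes(modes: ModeSet, coefficients) -> np.ndarray:
    """Unit-norm weighted sum of nontrivial modes.

    ``coefficients`` is a sequence of ``(mode_number, weight)``; equal-weight
    sums of two orthonormal modes therefore carry the 1/sqrt(2) factor, e.g.
    ``combine_modes(m, [(8, 1), (7, 1)])`` is ``(e8 + e7)/sqrt(2)``.
    """
    coefficients = list(coefficients)
    if not coefficients or all(w == 0 for _, w in coefficients):
        raise ValueError("need at least one nonzero weight")
    out = np.zeros(3 * modes.n_sites)
    for number, weight in coefficients:
        if number <= modes.n_trivial:
            raise ValueError(f"mode {number} is a trivial rigid-body mode")
        out += float(weight) * modes.mode(number)
    norm = np.linalg.norm(out)
    if norm < 1e-12:
        raise ValueError("weighted mode combination cancels to zero")
    return out / norm


def atomize_bias(bias: np.ndarray, structure: Structure, modes: ModeSet,
                 step: float = 0.01, model: int = 0) -> np.ndarray:
    """Spread a per-residue 3N bias vector onto all atoms of each residue.

    Every atom of residue ``i`` receives the residue-``i`` component of the
    mode; the field is rescaled so the RMS per-atom displacement equals
    ``step`` (Angstrom).

    Raises ``KeyError`` if an atom's residue has no component in the mode
    indexing (e.g. a residue that was skipped when the network was built).
    """
    per_res = modes.per_residue(bias)
    index = {key: i for i, key in enumerate(modes.residue_keys)}
    stack = structure.stack
    ins = stack.ins_code if "ins_code" in stack.get_annotation_categories() \
        else np.full(structure.n_atoms, "")
    field = np.empty((structure.n_atoms, 3))
    for a in range(structure.n_atoms):
        key = (str(stack.chain_id[a]), int(stack.res_id[a]), str(ins[a]))
        if key not in index:
            raise KeyError(f"residue {key} has no mode component")
        field[a] = per_res[index[key]]
    rms = np.sqrt(np.mean(np.sum(field ** 2, axis=1)))
    if rms < 1e-15:
        raise ValueError("bias field is identically zero on this structure")
    return field * (step / rms)


def transition_overlap(modes: ModeSet, start: Structure, target: Structure,
                       selection: SelectionSpec | None = None) -> np.ndarray:
    """Per-mode overlap with the start->target C-alpha difference vector.

    The target is first least-squares superposed on the start over the
    selected C-alphas; the overlap of mode ``m`` is the normalised dot
    product of its eigenvector with the difference vector, in [-1, 1].
    Returns an array indexed by mode (entry 0 = mode 1).
    """
    import biotite.structure as struc

    sel = selection or SelectionSpec(atom_names=("CA",))
    idx_s = sel.resolve(start)
    idx_t = sel.resolve(target)
    idx_s = idx_s[start.stack.atom_name[idx_s] == "CA"]
    idx_t = idx_t[target.stack.atom_name[idx_t] == "CA"]
    if len(idx_s) != len(idx_t):
        raise ValueError("selections resolve to different atom counts")
    fixed = start.stack[0][idx_s]
    mobile = target.stack[0][idx_t]
    fitted, _ = struc.superimpose(fixed, mobile)
    diff = (np.asarray(fitted.coord, dtype=float)
            - np.asarray(fixed.coord, dtype=float)).ravel()
    # map selected CAs onto mode components
    key_index = {key: i for i, key in enumerate(modes.residue_keys)}
    stack = start.stack
    ins = stack.ins_code if "ins_code" in stack.get_annotation_categories() \
        else np.full(start.n_atoms, "")
    rows = []
    for a in idx_s:
        key = (str(stack.chain_id[a]), int(stack.res_id[a]), str(ins[a]))
        if key not in key_index:
            raise ValueError(f"selected residue {key} missing from mode set")
        rows.append(key_index[key])
    full_diff = np.zeros(3 * modes.n_sites)
    for r, a_i in zip(rows, range(len(idx_s))):
        full_diff[3 * r: 3 * r + 3] = diff[3 * a_i: 3 * a_i + 3]
    norm = np.linalg.norm(full_diff)
    if norm < 1e-12:
        raise ValueError("start and target coincide on the selection")
    unit = full_diff / norm
    return modes.eigenvectors.T @ unit
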