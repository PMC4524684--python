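"""Constraint networks and pebble-game rigidity analysis.

The constraint network collects covalent bonds, energy-ranked hydrogen
bonds/salt bridges and hydrophobic tethers; matching the framework's
degrees of freedom against these constraints with a pebble game yields the
floppy-mode count, the redundant constraints, and a decomposition into
rigid clusters joined by variable (rotatable) bonds.

Two resolutions are supported:

* **atomistic** -- atoms are six-degree-of-freedom bodies and constraints
  carry the standard body-bar multiplicities (rotatable covalent bond 5
  bars, peptide/locked bond 6, hydrogen bond 5, hydrophobic tether 2).
  The (6,6) pebble game is exact for generic body-bar frameworks.
* **coarse** -- C-alpha sites are 3-DOF point joints and every constraint
  is a single distance bar.  The 3D bar-joint pebble game used here
  augments the classic rule (six pebbles gathered on the bar's endpoints)
  with a seventh-pebble search over the endpoints' neighbours; this is
  exact for molecular (bond-bending) networks and a good heuristic for
  general frameworks, though pathological circuits (the classic
  double-banana) can be misclassified.

Hydrogen-bond energies use a Mayo-style distance/angle potential (well
depth 8 kcal/mol at a donor-acceptor equilibrium distance of 2.8 A,
cosine-squared angular attenuation); only bonds at or below the energy
cutoff (default -2.0 kcal/mol) enter the network.  Salt bridges are
hydrogen bonds with a fixed favourable energy.  All of these parameters
live in :class:`RigidityConfig` and are recorded with every run.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structures import Structure

__all__ = [
    "RigidityConfig",
    "HydrogenBond",
    "Constraint",
    "ConstraintNetwork",
    "RigidDecomposition",
    "detect_covalent",
    "detect_hbonds",
    "detect_hydrophobic",
    "build_constraint_network",
    "pebble_game",
    "PebbleGame",
]

COVALENT_RADII = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05,
                  "P": 1.07, "SE": 1.20}
VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
             "P": 1.80}


@dataclass
class RigidityConfig:
    """Tunable parameters of the constraint-network construction."""

    energy_cutoff: float = -2.0        # kcal/mol, hbond inclusion threshold
    covalent_slack: float = 0.45       # A beyond summed covalent radii
    hbond_well_depth: float = 8.0      # kcal/mol (Mayo-style D0)
    hbond_eq_distance: float = 2.8     # A donor-acceptor equilibrium (R0)
    hbond_max_distance: float = 3.6    # A donor-acceptor candidate cutoff
    salt_bridge_energy: float = -10.0  # kcal/mol fixed favourable energy
    hydrophobic_slack: float = 0.25    # A beyond summed vdW radii
    coarse_bond_max: float = 4.5       # A consecutive C-alpha bond cutoff
    coarse_tether_max: float = 5.5     # A nonlocal C-alpha tether cutoff
    bars_covalent: int = 5
    bars_locked: int = 6               # peptide / partial double bonds
    bars_hbond: int = 5
    bars_hydrophobic: int = 2

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class HydrogenBond:
    donor: int                 # atom index
    acceptor: int
    hydrogen: int | None
    energy: float              # kcal/mol, <= 0 for candidates

    def pair(self) -> tuple[int, int]:
        return (min(self.donor, self.acceptor),
                max(self.donor, self.acceptor))


@dataclass(frozen=True)
class Constraint:
    i: int
    j: int
    bars: int
    kind: str                  # covalent | peptide-locked | hbond | hydrophobic
    energy: float | None = None

    def pair(self) -> tuple[int, int]:
        return (min(self.i, self.j), max(self.i, self.j))


@dataclass
class ConstraintNetwork:
    """Symmetric constraint network over the atoms of one model."""

    n_atoms: int
    coords: np.ndarray                  # (n_atoms, 3)
    constraints: list[Constraint]
    mode: str                           # "atomistic" | "coarse"
    energy_cutoff: float
    config: RigidityConfig

    def pairs_of_kind(self, *kinds: str) -> list[tuple[int, int]]:
        return [c.pair() for c in self.constraints if c.kind in kinds]

    def to_csv(self, path: str | Path) -> None:
        rows = [(c.i, c.j, c.kind, c.bars,
                 "" if c.energy is None else c.energy)
                for c in self.constraints]
        pd.DataFrame(rows, columns=["i", "j", "kind", "bars", "energy"]) \
          .to_csv(path, index=False)


@dataclass
class RigidDecomposition:
    """Rigid clusters, floppy-mode count and per-bond dihedral labels."""

    cluster_labels: np.ndarray          # per-atom cluster id, 0-based
    floppy_modes: int                   # F, internal degrees of freedom
    bond_labels: dict                   # (i, j) -> "locked" | "variable"
    n_independent: int
    n_redundant: int

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_labels.max()) + 1

    def clusters(self) -> list[np.ndarray]:
        return [np.where(self.cluster_labels == c)[0]
                for c in range(self.n_clusters)]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"atom": np.arange(len(self.cluster_labels)),
                      "cluster": self.cluster_labels}).to_csv(path,
                                                              index=False)


# -- detection --------------------------------------------------------------

def _is_coarse(structure: Structure) -> bool:
    return bool(np.all(structure.stack.atom_name == "CA"))


def detect_covalent(structure: Structure, config: RigidityConfig | None = None,
                    model: int = 0) -> list[tuple[int, int]]:
    """Covalent bonds by element-pair distance rules.

    All-atom: two atoms bond when their distance is below the sum of their
    covalent radii plus a slack (default 0.45 A); >8 bonds on one atom
    signals corrupt coordinates.  Coarse (C-alpha-only) structures instead
    bond consecutive residues of a chain within 4.5 A.
    """
    config = config or RigidityConfig()
    s = structure.stack
    coords = structure.coords(model)
    if _is_coarse(structure):
        bonds = []
        for a in range(structure.n_atoms - 1):
            b = a + 1
            if (s.chain_id[a] == s.chain_id[b]
                    and abs(int(s.res_id[b]) - int(s.res_id[a])) == 1
                    and np.linalg.norm(coords[a] - coords[b])
                    < config.coarse_bond_max):
                bonds.append((a, b))
        return bonds
    radii = np.array([COVALENT_RADII.get(str(e).upper(), 0.77)
                      for e in s.element])
    tree = cKDTree(coords)
    candidates = tree.query_pairs(r=2 * radii.max() + config.covalent_slack)
    bonds = []
    counts = np.zeros(structure.n_atoms, dtype=int)
    for a, b in sorted(candidates):
        d = np.linalg.norm(coords[a] - coords[b])
        if d < radii[a] + radii[b] + config.covalent_slack and d > 0.4:
            bonds.append((a, b))
            counts[a] += 1
            counts[b] += 1
    if counts.max(initial=0) > 8:
        raise ValueError("atom with more than 8 covalent bonds: corrupt "
                         "coordinates?")
    return bonds


def _mayo_energy(r_da: float, cos_theta: float,
                 config: RigidityConfig) -> float:
    """Mayo-style hydrogen-bond energy (kcal/mol).

    ``r_da`` is the donor-acceptor distance, ``cos_theta`` the cosine of
    the bond angle (180 deg = linear = cos -1).  The angular factor is
    cos^2(theta) for theta beyond 90 deg and zero otherwise, so a right-
    angle geometry scores no energy at any distance.
    """
    ratio = config.hbond_eq_distance / r_da
    radial = config.hbond_well_depth * (5 * ratio ** 12 - 6 * ratio ** 10)
    angular = cos_theta ** 2 if cos_theta < 0.0 else 0.0
    return radial * angular


_SB_DONOR = {("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"), ("LYS", "NZ"),
             ("HIS", "ND1"), ("HIS", "NE2")}
_SB_ACCEPTOR = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"),
                ("GLU", "OE2")}


def detect_hbonds(structure: Structure, config: RigidityConfig | None = None,
                  model: int = 0, heavy_atom_fallback: bool = True
                  ) -> list[HydrogenBond]:
    """Hydrogen bonds and salt bridges with geometric energies.

    Donors and acceptors are N/O/S atoms.  With explicit hydrogens the
    bond angle is measured at the hydrogen (D-H...A); without them, and if
    ``heavy_atom_fallback`` is enabled, the donor's bonded heavy atoms
    define an approximate donor direction instead (a warning-level
    compromise inherited from working with crystal structures).  The
    returned list is sorted by energy, most favourable first.
    """
    config = config or RigidityConfig()
    if _is_coarse(structure):
        return []
    s = structure.stack
    coords = structure.coords(model)
    elements = np.array([str(e).upper() for e in s.element])
    bonds = detect_covalent(structure, config, model)
    neighbors: dict[int, list[int]] = defaultdict(list)
    for a, b in bonds:
        neighbors[a].append(b)
        neighbors[b].append(a)

    has_h = bool(np.any(elements == "H"))
    if not has_h and not heavy_atom_fallback:
        raise ValueError("no hydrogens present and heavy-atom fallback "
                         "disabled")

    polar = np.where(np.isin(elements, ["N", "O", "S"]))[0]
    donors = []
    for d in polar:
        hs = [n for n in neighbors[d] if elements[n] == "H"]
        if hs:
            donors.append((d, hs))
        elif not has_h:
            donors.append((d, []))
    acceptors = [a for a in polar
                 if elements[a] in ("O", "S")
                 or (elements[a] == "N" and len(neighbors[a]) <= 2)]

    bonded = set(map(tuple, map(sorted, bonds)))
    tree = cKDTree(coords)
    out = []
    acc_set = set(acceptors)
    for d, hs in donors:
        for a in tree.query_ball_point(coords[d], config.hbond_max_distance):
            if a == d or a not in acc_set:
                continue
            if (s.chain_id[d], s.res_id[d]) == (s.chain_id[a], s.res_id[a]):
                continue
            if tuple(sorted((d, a))) in bonded:
                continue
            r_da = float(np.linalg.norm(coords[d] - coords[a]))
            if hs:  # best hydrogen
                best = None
                for h in hs:
                    u = coords[d] - coords[h]
                    v = coords[a] - coords[h]
                    ct = float(u @ v / (np.linalg.norm(u)
                                        * np.linalg.norm(v)))
                    if best is None or ct < best[0]:
                        best = (ct, h)
                cos_theta, hyd = best
            else:   # heavy-atom fallback: donor direction from its frame
                heavy = [n for n in neighbors[d] if elements[n] != "H"]
                if heavy:
                    base = coords[heavy].mean(axis=0)
                    u = base - coords[d]
                    v = coords[a] - coords[d]
                    cos_theta = float(u @ v / (np.linalg.norm(u)
                                               * np.linalg.norm(v)))
                else:
                    cos_theta = -1.0
                hyd = None
            energy = _mayo_energy(r_da, cos_theta, config)
            key_d = (str(s.res_name[d]), str(s.atom_name[d]))
            key_a = (str(s.res_name[a]), str(s.atom_name[a]))
            if key_d in _SB_DONOR and key_a in _SB_ACCEPTOR:
                energy = min(energy, config.salt_bridge_energy)
            if energy < 0.0:
                out.append(HydrogenBond(d, a, hyd, energy))
    # one bond per unordered atom pair, keeping the most favourable energy
    best_by_pair: dict[tuple[int, int], HydrogenBond] = {}
    for hb in out:
        key = hb.pair()
        if key not in best_by_pair or hb.energy < best_by_pair[key].energy:
            best_by_pair[key] = hb
    return sorted(best_by_pair.values(), key=lambda hb: hb.energy)


def detect_hydrophobic(structure: Structure,
                       config: RigidityConfig | None = None,
                       model: int = 0) -> list[tuple[int, int]]:
    """Hydrophobic tethers: carbon/sulfur pairs of different residues in
    contact (summed van-der-Waals radii plus slack).  Coarse structures use
    a plain C-alpha distance criterion for non-consecutive residues.
    """
    config = config or RigidityConfig()
    s = structure.stack
    coords = structure.coords(model)
    tethers = []
    if _is_coarse(structure):
        tree = cKDTree(coords)
        for a, b in sorted(tree.query_pairs(r=config.coarse_tether_max)):
            same_chain = s.chain_id[a] == s.chain_id[b]
            if same_chain and abs(int(s.res_id[a]) - int(s.res_id[b])) <= 1:
                continue
            tethers.append((a, b))
        return tethers
    elements = np.array([str(e).upper() for e in s.element])
    cs = np.where(np.isin(elements, ["C", "S"]))[0]
    bonded = set(map(tuple, map(sorted,
                                detect_covalent(structure, config, model))))
    tree = cKDTree(coords[cs])
    rmax = 2 * VDW_RADII["S"] + config.hydrophobic_slack
    for ia, ib in sorted(tree.query_pairs(r=rmax)):
        a, b = int(cs[ia]), int(cs[ib])
        if (s.chain_id[a], s.res_id[a]) == (s.chain_id[b], s.res_id[b]):
            continue
        if tuple(sorted((a, b))) in bonded:
            continue
        cut = (VDW_RADII[elements[a]] + VDW_RADII[elements[b]]
               + config.hydrophobic_slack)
        if np.linalg.norm(coords[a] - coords[b]) <= cut:
            tethers.append((a, b))
    return tethers


def _peptide_bonds(structure: Structure,
                   bonds: list[tuple[int, int]]) -> set[tuple[int, int]]:
    """Backbone C(i)-N(i+1) bonds (locked, partial double-bond character)."""
    s = structure.stack
    locked = set()
    for a, b in bonds:
        na, nb = str(s.atom_name[a]), str(s.atom_name[b])
        if {na, nb} == {"C", "N"} and s.res_id[a] != s.res_id[b]:
            locked.add((min(a, b), max(a, b)))
    return locked


def build_constraint_network(structure: Structure,
                             energy_cutoff: float = -2.0,
                             config: RigidityConfig | None = None,
                             model: int = 0) -> ConstraintNetwork:
    """Assemble the full constraint network at the given energy cutoff.

    Hydrogen bonds with energy above the cutoff are excluded; making the
    cutoff more negative therefore always selects a subset of the bonds.
    """
    config = config or RigidityConfig()
    config.energy_cutoff = energy_cutoff
    coarse = _is_coarse(structure)
    coords = structure.coords(model)
    constraints: list[Constraint] = []

    bonds = detect_covalent(structure, config, model)
    if coarse:
        for a, b in bonds:
            constraints.append(Constraint(a, b, 1, "covalent"))
        for a, b in detect_hydrophobic(structure, config, model):
            constraints.append(Constraint(a, b, 1, "hydrophobic"))
    else:
        locked = _peptide_bonds(structure, bonds)
        for a, b in bonds:
            if (min(a, b), max(a, b)) in locked:
                constraints.append(Constraint(a, b, config.bars_locked,
                                              "peptide-locked"))
            else:
                constraints.append(Constraint(a, b, config.bars_covalent,
                                              "covalent"))
        for hb in detect_hbonds(structure, config, model):
            if hb.energy <= energy_cutoff:
                constraints.append(Constraint(hb.donor, hb.acceptor,
                                              config.bars_hbond, "hbond",
                                              hb.energy))
        for a, b in detect_hydrophobic(structure, config, model):
            constraints.append(Constraint(a, b, config.bars_hydrophobic,
                                          "hydrophobic"))
    return ConstraintNetwork(n_atoms=structure.n_atoms, coords=coords,
                             constraints=constraints,
                             mode="coarse" if coarse else "atomistic",
                             energy_cutoff=energy_cutoff, config=config)


# -- the pebble game --------------------------------------------------------

class PebbleGame:
    """Directed-graph pebble game over a multigraph of bars.

    ``dof_per_site`` is 6 for body-bar frameworks (atomistic) and 3 for
    point-joint frameworks (coarse).  Bars are inserted one at a time with
    :meth:`insert_bar`; the acceptance rule is the classic `l + 1 = 7`
    pebble condition for body-bar mode, and the six-plus-neighbour-pebble
    rule for 3D point frameworks.
    """

    RIGID_BODY_DOF = 6

    def __init__(self, n_sites: int, dof_per_site: int,
                 coords: np.ndarray | None = None):
        if dof_per_site not in (3, 6):
            raise ValueError("dof_per_site must be 3 or 6")
        self.n = n_sites
        self.k = dof_per_site
        self.pebbles = np.full(n_sites, dof_per_site, dtype=int)
        self.out: list[dict[int, int]] = [defaultdict(int)
                                          for _ in range(n_sites)]
        self.adjacency: list[set[int]] = [set() for _ in range(n_sites)]
        self.n_independent = 0
        self.n_redundant = 0
        # Point mode only: generic 3D bar-joint rigidity has no exact
        # counting characterization (double-banana-type circuits satisfy
        # Maxwell counting everywhere yet carry a dependency), so when site
        # coordinates are available each counting-accepted bar is vetted
        # against the span of previously accepted constraint rows.
        self.coords = None
        self._basis: np.ndarray | None = None
        self._basis_size = 0
        if coords is not None and dof_per_site == 3:
            self.coords = np.asarray(coords, dtype=float)
            self._basis = np.zeros((3 * n_sites, 3 * n_sites))

    def _numeric_independent(self, a: int, b: int) -> bool:
        d = self.coords[a] - self.coords[b]
        row = np.zeros(3 * self.n)
        row[3 * a: 3 * a + 3] = d
        row[3 * b: 3 * b + 3] = -d
        norm = np.linalg.norm(row)
        q = self._basis[:, : self._basis_size]
        # two projection passes (reorthogonalized Gram-Schmidt) keep the
        # rank decision stable against insertion order
        for _ in range(2):
            row = row - q @ (q.T @ row)
        residual = np.linalg.norm(row)
        if residual > 1e-8 * norm:
            self._basis[:, self._basis_size] = row / residual
            self._basis_size += 1
            return True
        return False

    # pebble search with path reversal
    def _find_pebble(self, root: int, forbidden: set[int]) -> bool:
        visited = set(forbidden)
        visited.add(root)
        parent: dict[int, int] = {}
        stack = [root]
        while stack:
            u = stack.pop()
            for w, cnt in list(self.out[u].items()):
                if cnt <= 0 or w in visited:
                    continue
                if self.pebbles[w] > 0:
                    self.pebbles[w] -= 1
                    cur, prev = w, u
                    while True:
                        self.out[prev][cur] -= 1
                        self.out[cur][prev] += 1
                        if prev == root:
                            break
                        cur, prev = prev, parent[prev]
                    self.pebbles[root] += 1
                    return True
                visited.add(w)
                parent[w] = u
                stack.append(w)
        return False

    def _gather(self, v: int, target: int, forbidden: set[int]) -> None:
        while self.pebbles[v] < target and self._find_pebble(v, forbidden):
            pass

    def _can_free_seventh(self, a: int, b: int) -> bool:
        """Point mode: seventh pebble on a neighbour of the bar's endpoints."""
        neigh = (self.adjacency[a] | self.adjacency[b]) - {a, b}
        if not neigh:
            return True  # isolated pair: a lone bar is always independent
        for w in neigh:
            if self.pebbles[w] > 0 or self._find_pebble(w, {a, b}):
                return True
        return False

    def test_independent(self, a: int, b: int) -> bool:
        """Would one more bar between a and b be independent?  (Mutates the
        pebble distribution, legally; does not insert anything.)"""
        if self.k == 6:
            self._gather(a, self.k, {b})
            self._gather(b, self.k, {a})
            return self.pebbles[a] + self.pebbles[b] \
                >= self.RIGID_BODY_DOF + 1
        self._gather(a, 3, {b})
        self._gather(b, 3, {a})
        if self.pebbles[a] + self.pebbles[b] < 6:
            return False
        return self._can_free_seventh(a, b)

    def insert_bar(self, a: int, b: int) -> bool:
        """Insert one bar; returns True if independent, False if redundant."""
        if a == b:
            raise ValueError("self-bars are not allowed")
        independent = self.test_independent(a, b)
        if independent and self.coords is not None:
            independent = self._numeric_independent(a, b)
        if independent:
            donor = a if self.pebbles[a] > 0 else b
            self.pebbles[donor] -= 1
            self.out[donor][b if donor == a else a] += 1
            self.n_independent += 1
        else:
            self.n_redundant += 1
        self.adjacency[a].add(b)
        self.adjacency[b].add(a)
        return independent

    def insert_constraint(self, a: int, b: int, bars: int) -> int:
        """Insert a multi-bar constraint; returns how many bars were
        independent."""
        return sum(self.insert_bar(a, b) for _ in range(bars))

    @property
    def floppy_modes(self) -> int:
        total = self.k * self.n
        return max(total - self.RIGID_BODY_DOF - self.n_independent, 0)


def _point_mode_bond_labels(network: ConstraintNetwork,
                            tol: float = 1e-6) -> dict:
    """Locked/variable labels from the numerical infinitesimal-flex space.

    A constraint is locked when the flex space restricted to its local
    environment contains only rigid-body motions (every pairwise distance
    preserved to first order).  The environment is the endpoints plus
    their *common* neighbours when any exist (the triangulated interior of
    a cluster), falling back to the union of both neighbourhoods for
    poorly connected constraints such as linker bonds.
    """
    from scipy.linalg import null_space

    coords = network.coords
    n = network.n_atoms
    pairs = sorted({c.pair() for c in network.constraints})
    rows = np.zeros((len(pairs), 3 * n))
    for r, (i, j) in enumerate(pairs):
        d = coords[i] - coords[j]
        rows[r, 3 * i: 3 * i + 3] = d
        rows[r, 3 * j: 3 * j + 3] = -d
    flex = null_space(rows, rcond=1e-10)
    # scale tolerance to coordinate magnitude
    scale = max(np.abs(coords).max(), 1.0)

    neighbors: dict[int, set[int]] = defaultdict(set)
    for i, j in pairs:
        neighbors[i].add(j)
        neighbors[j].add(i)

    labels = {}
    for (i, j) in pairs:
        common = neighbors[i] & neighbors[j]
        if common:
            u = sorted({i, j} | common)
        else:
            u = sorted({i, j} | neighbors[i] | neighbors[j])
        sub = np.array(u)
        locked = True
        p = coords[sub]
        for q in flex.T:
            v = q.reshape(n, 3)[sub]
            dp = p[:, None, :] - p[None, :, :]
            dv = v[:, None, :] - v[None, :, :]
            stretch = np.abs(np.einsum("ijk,ijk->ij", dp, dv))
            if stretch.max() > tol * scale:
                locked = False
                break
        labels[(i, j)] = "locked" if locked else "variable"
    return labels


def pebble_game(network: ConstraintNetwork,
                order: list[int] | None = None) -> RigidDecomposition:
    """Run the pebble game and decompose the framework.

    ``order`` optionally permutes constraint insertion (the floppy count is
    insertion-order independent; the option exists to demonstrate it).

    The floppy-mode count always comes from the combinatorial game.  Bond
    labels come from pebble redundancy tests in body-bar (atomistic) mode
    and from the numerical flex space in point (coarse) mode; rigid
    clusters are the connected components over locked constraints.
    """
    if not network.constraints:
        raise ValueError("empty constraint network")
    dof = 6 if network.mode == "atomistic" else 3
    game = PebbleGame(network.n_atoms, dof,
                      coords=network.coords if dof == 3 else None)
    constraints = network.constraints
    seq = order if order is not None else range(len(constraints))
    for idx in seq:
        c = constraints[idx]
        game.insert_constraint(c.i, c.j, c.bars)
    floppy = game.floppy_modes

    if network.mode == "atomistic":
        labels = {}
        for c in network.constraints:
            if c.kind in ("covalent", "peptide-locked"):
                a, b = c.pair()
                labels[(a, b)] = ("locked"
                                  if not game.test_independent(a, b)
                                  else "variable")
    else:
        labels = _point_mode_bond_labels(network)

    # rigid clusters: union-find over locked constraints
    parent = np.arange(network.n_atoms)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (a, b), lab in labels.items():
        if lab == "locked":
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    roots = {}
    cluster = np.empty(network.n_atoms, dtype=int)
    for x in range(network.n_atoms):
        r = find(x)
        if r not in roots:
            roots[r] = len(roots)
        cluster[x] = roots[r]

    return RigidDecomposition(cluster_labels=cluster, floppy_modes=floppy,
                              bond_labels=labels,
                              n_independent=game.n_independent,
                              n_redundant=game.n_redundant)


def write_cluster_pdb(structure: Structure, decomposition: RigidDecomposition,
                      path: str | Path) -> None:
    """Write the structure with the cluster index in the B-factor column."""
    from biotite.structure.io.pdb import PDBFile

    stack = structure.stack.copy()
    stack.set_annotation("b_factor",
                         decomposition.cluster_labels.astype(float))
    if "occupancy" not in stack.get_annotation_categories():
        stack.set_annotation("occupancy",
                             np.ones(stack.array_length(), dtype=float))
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))
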