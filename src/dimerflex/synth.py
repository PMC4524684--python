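"""Synthetic fixtures with known ground truth.

The central generator builds a C-alpha-resolution *toy homodimer* that
mimics the architecture of domain-swapped two-domain enzymes such as the
scavenger decapping enzyme: each chain contributes a large core domain to
the dimer body, and a small mobile domain, attached through a short
flexible linker, that hovers over the *other* chain's core.  The two
mobile domains sit side by side and pack against each other, forming a
single domain-swapped top lobe over the body -- the architecture that
makes cooperative motion possible: a see-saw rocking of the lobe closes
one binding cleft while opening the other (anti-symmetric), while a
vertical approach of the lobe closes both at once (symmetric).  Rotating
the mobile domains about their hinge residues closes the clefts.  The
structure is exactly C2-symmetric about the z axis, so the two clefts are
equivalent by construction and normal modes split into symmetric/
anti-symmetric pairs.

Sites are laid out on a jittered cubic lattice (spacing ~3.8 A, the
C-alpha virtual bond length).  The jitter breaks the non-generic
degeneracies of a perfect lattice (important for rigidity analysis) while
the designated measure sites stay in the y = 0 plane so that a hinge
rotation by phi changes the hinge-angle measure by exactly phi.

Ground truth available to tests:

* domain membership (core / linker / mobile residue ranges),
* designated measure sites (intersite pair, hinge triple, cleft tips),
* the hinge pivot and axis used by :func:`make_open_closed_pair`,
* planted directions/amplitudes for :func:`make_mode_trajectory`,
* the population correlation of :func:`make_correlated_series`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc

from .structures import Structure

__all__ = [
    "ToyDimerSpec",
    "ToyDimer",
    "make_toy_dimer",
    "make_open_closed_pair",
    "make_mode_trajectory",
    "make_correlated_series",
]


@dataclass(frozen=True)
class ToyDimerSpec:
    """Geometry of the toy homodimer (lengths in Angstrom)."""

    core_shape: tuple[int, int, int] = (5, 4, 3)   # 60 residues per core
    mobile_shape: tuple[int, int, int] = (3, 3, 3)  # 27 - 2 dropped = 25
    linker_length: int = 3
    spacing: float = 3.8
    cleft_width: float = 11.0     # mobile underside to core top
    core_gap: float = 4.6         # x gap between the two core inner faces
    lobe_gap: float = 4.8         # x gap between the two mobile inner faces
    linker_y_offset: float = 2.2  # keeps the two crossing linkers apart
    hinge_bend: float = 1.2       # kink at the hinge so the angle is < 180
    jitter: float = 0.15          # uniform lattice jitter amplitude
    seed: int = 0

    @property
    def n_core(self) -> int:
        return int(np.prod(self.core_shape))

    @property
    def n_mobile(self) -> int:
        return int(np.prod(self.mobile_shape)) - 2  # two corners dropped

    @property
    def n_per_chain(self) -> int:
        return self.n_core + self.linker_length + self.n_mobile


@dataclass
class ToyDimer:
    """Generated structure plus its site annotations (ground truth)."""

    structure: Structure
    spec: ToyDimerSpec
    core_range: tuple[int, int]
    linker_range: tuple[int, int]
    mobile_range: tuple[int, int]
    trp_res: int          # intersite residue on the core ("Trp175"-like)
    tip_res: int          # cleft tip on the mobile domain ("Asp111"-like)
    attachment_res: int   # first mobile residue (linker junction)
    hinge_res: int        # pivot residue of the hinge
    hinge_triple: tuple[int, int, int]
    drms_mobile: tuple[int, int]
    drms_core: tuple[int, int, int]

    def domain_residues(self, which: str) -> list[int]:
        lo, hi = {"core": self.core_range, "linker": self.linker_range,
                  "mobile": self.mobile_range}[which]
        return list(range(lo, hi + 1))

    def residue_domain(self, res_id: int) -> str:
        for name in ("core", "linker", "mobile"):
            lo, hi = {"core": self.core_range, "linker": self.linker_range,
                      "mobile": self.mobile_range}[name]
            if lo <= res_id <= hi:
                return name
        raise KeyError(res_id)

    def to_yaml_dict(self) -> dict:
        return {
            "core_range": list(self.core_range),
            "linker_range": list(self.linker_range),
            "mobile_range": list(self.mobile_range),
            "trp_res": self.trp_res,
            "tip_res": self.tip_res,
            "attachment_res": self.attachment_res,
            "hinge_res": self.hinge_res,
            "hinge_triple": list(self.hinge_triple),
            "drms_mobile": list(self.drms_mobile),
            "drms_core": list(self.drms_core),
        }


def _c2_about_z(coords: np.ndarray) -> np.ndarray:
    """The dimer symmetry operation: (x, y, z) -> (-x, -y, z)."""
    out = coords.copy()
    out[:, 0] *= -1
    out[:, 1] *= -1
    return out


def _chain_a_layout(spec: ToyDimerSpec, rng: np.random.Generator):
    """Build chain A site positions and bookkeeping.

    Core A occupies the -x half of the dimer body; the mobile domain of
    chain A hovers above core *B* (+x half), connected by a linker that
    climbs across the dimer midline.  Chain B is the exact C2 image.
    """
    a = spec.spacing
    nx, ny, nz = spec.core_shape
    half_x = (nx - 1) / 2 * a
    core_center_x = -(spec.core_gap / 2 + half_x)

    core_sites = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                core_sites.append((core_center_x + (i - (nx - 1) / 2) * a,
                                   (j - (ny - 1) / 2) * a,
                                   (k - (nz - 1) / 2) * a))
    core_sites = np.array(core_sites)
    core_top_z = (nz - 1) / 2 * a
    inner_x = core_center_x + half_x            # core A face nearest x = 0

    # anchor: core residue nearest the linker start; reorder so it is last
    anchor_target = np.array([inner_x, a / 2, core_top_z])
    anchor_idx = int(np.argmin(np.linalg.norm(core_sites - anchor_target,
                                              axis=1)))
    order = [i for i in range(len(core_sites)) if i != anchor_idx]
    order.append(anchor_idx)
    core_sites = core_sites[order]

    # mobile domain of chain A on the +x side of the top lobe, above core B;
    # close enough to the midline that it packs against the other chain's
    # mobile domain (the C2 image on the -x side), fusing the two into one
    # domain-swapped lobe
    mx, my, mz = spec.mobile_shape
    mob_center = np.array([spec.lobe_gap / 2 + (mx - 1) / 2 * a, 0.0,
                           core_top_z + spec.cleft_width + (mz - 1) / 2 * a])
    mob_sites = []
    for i in range(mx):
        for j in range(my):
            for k in range(mz):
                mob_sites.append(mob_center
                                 + np.array([(i - (mx - 1) / 2) * a,
                                             (j - (my - 1) / 2) * a,
                                             (k - (mz - 1) / 2) * a]))
    mob_sites = np.array(mob_sites)
    mob_bottom_z = mob_center[2] - (mz - 1) / 2 * a

    def find(target):
        return int(np.argmin(np.linalg.norm(mob_sites - target, axis=1)))

    attachment = find([mob_center[0] - a, 0.0, mob_bottom_z])
    tip = find([mob_center[0] + a, 0.0, mob_bottom_z])
    drop1 = find([mob_center[0] - a, (my - 1) / 2 * a, mob_center[2] + a])
    drop2 = find([mob_center[0] - a, -(my - 1) / 2 * a, mob_center[2] + a])
    keep = [i for i in range(len(mob_sites))
            if i not in (drop1, drop2)]
    # reorder: attachment first, tip second, rest after
    keep.remove(attachment)
    keep.remove(tip)
    mob_order = [attachment, tip] + keep
    mob_sites = mob_sites[mob_order]

    # linker: straight line from the core inner-top corner to the attachment
    # site, displaced off the y = 0 midplane so the two chains' linkers do
    # not collide where they cross.  All linker sites share one y value so
    # a hinge rotation (about the y axis) changes the hinge-angle measure
    # by exactly the rotation angle.
    start = np.array([inner_x, 0.0, core_top_z])
    end = mob_sites[0]
    n_link = spec.linker_length
    fracs = [(i + 1) / (n_link + 1) for i in range(n_link)]
    link_sites = np.array([start + f * (end - start) for f in fracs])
    link_sites[:, 1] = spec.linker_y_offset
    # kink the hinge site off the straight line (in the x-z motion plane) so
    # the open hinge angle sits below 180 deg and a closing rotation strictly
    # decreases it
    hinge_local = (n_link + 1) // 2 - 1
    axis = (end - start) / np.linalg.norm(end - start)
    perp = np.array([-axis[2], 0.0, axis[0]])
    perp /= np.linalg.norm(perp)
    link_sites[hinge_local] += spec.hinge_bend * perp

    # seeded jitter; y jitter suppressed on linker + mobile attachment/tip
    # so the hinge-angle exactness property holds
    coords = np.vstack([core_sites, link_sites, mob_sites])
    jit = rng.uniform(-spec.jitter, spec.jitter, size=coords.shape)
    jit[spec.n_core: spec.n_core + n_link, 1] = 0.0
    jit[spec.n_core + n_link, 1] = 0.0      # attachment
    jit[spec.n_core + n_link + 1, 1] = 0.0  # tip
    coords = coords + jit

    # designated core sites for measures (post-reorder indices)
    def core_find(target):
        return int(np.argmin(np.linalg.norm(core_sites - np.array(target),
                                            axis=1)))

    trp = core_find([core_center_x, a / 2, core_top_z])
    drms_core = (
        trp,
        core_find([core_center_x - a, a / 2, core_top_z]),
        core_find([core_center_x + a, -a / 2, core_top_z]),
    )
    return coords, trp, drms_core


def make_toy_dimer(spec: ToyDimerSpec | None = None) -> ToyDimer:
    """Generate the toy homodimer; deterministic for a given spec/seed."""
    spec = spec or ToyDimerSpec()
    rng = np.random.default_rng(spec.seed)
    chain_a, trp_idx, drms_core_idx = _chain_a_layout(spec, rng)
    chain_b = _c2_about_z(chain_a)

    coords = np.vstack([chain_a, chain_b])
    n = spec.n_per_chain
    # construction sanity: no overlapping sites
    from scipy.spatial import cKDTree
    tree = cKDTree(coords)
    close = tree.query_pairs(r=2.5)
    if close:
        raise ValueError("toy dimer construction produced overlapping sites")

    atoms = struc.AtomArray(2 * n)
    atoms.coord = coords.astype(np.float32)
    atoms.chain_id = np.array(["A"] * n + ["B"] * n)
    atoms.res_id = np.array(list(range(1, n + 1)) * 2)
    atoms.res_name = np.array(["ALA"] * (2 * n))
    atoms.atom_name = np.array(["CA"] * (2 * n))
    atoms.element = np.array(["C"] * (2 * n))
    atoms.hetero = np.zeros(2 * n, dtype=bool)
    structure = Structure(struc.stack([atoms]), source_id="toy-dimer")

    n_core, n_link = spec.n_core, spec.linker_length
    hinge_res = n_core + (n_link + 1) // 2   # centre of the linker
    return ToyDimer(
        structure=structure,
        spec=spec,
        core_range=(1, n_core),
        linker_range=(n_core + 1, n_core + n_link),
        mobile_range=(n_core + n_link + 1, n),
        trp_res=trp_idx + 1,
        tip_res=n_core + n_link + 2,
        attachment_res=n_core + n_link + 1,
        hinge_res=hinge_res,
        hinge_triple=(hinge_res - 1, hinge_res, hinge_res + 1),
        drms_mobile=(n_core + n_link + 2, n_core + n_link + 1),
        drms_core=tuple(i + 1 for i in drms_core_idx),
    )


def _rotate_about_y(points: np.ndarray, pivot: np.ndarray,
                    angle_deg: float) -> np.ndarray:
    """Rotate points about the y axis through ``pivot`` (closing sense)."""
    phi = np.deg2rad(angle_deg)
    c, s = np.cos(phi), np.sin(phi)
    rel = points - pivot
    out = rel.copy()
    out[:, 0] = c * rel[:, 0] + s * rel[:, 2]
    out[:, 2] = -s * rel[:, 0] + c * rel[:, 2]
    return out + pivot


def make_open_closed_pair(toy: ToyDimer, hinge_rotation: float
                          ) -> tuple[Structure, Structure]:
    """Open/closed reference pair related by a rigid hinge rotation.

    The closed form rotates everything distal of the hinge residue (the
    outer half of the linker plus the whole mobile domain) of *both* chains
    about the y axis through each chain's hinge C-alpha, by
    ``hinge_rotation`` degrees in the cleft-closing sense; C2 symmetry is
    preserved.  Raises if the rotation causes a steric clash (< 2.8 A).
    """
    n = toy.spec.n_per_chain
    coords = toy.structure.coords(0)
    chain_a = coords[:n].copy()

    s = toy.structure.stack
    hinge_idx_a = toy.structure.atom_index("A", toy.hinge_res)
    pivot = coords[hinge_idx_a]
    distal = np.array([rid > toy.hinge_res for rid in s.res_id[:n]])
    chain_a[distal] = _rotate_about_y(chain_a[distal], pivot, hinge_rotation)
    closed_coords = np.vstack([chain_a, _c2_about_z(chain_a)])

    from scipy.spatial import cKDTree
    moved = np.where(np.concatenate([distal, distal]))[0]
    fixed = np.where(~np.concatenate([distal, distal]))[0]
    if len(moved) and len(fixed):
        d, _ = cKDTree(closed_coords[fixed]).query(closed_coords[moved], k=1)
        if d.min() < 2.8:
            raise ValueError(
                f"hinge rotation of {hinge_rotation} deg causes a clash "
                f"(min distance {d.min():.2f} A)")

    open_structure = toy.structure.with_coords(coords, "toy-open")
    closed_structure = toy.structure.with_coords(closed_coords, "toy-closed")
    return open_structure, closed_structure


def make_mode_trajectory(structure: Structure, directions: np.ndarray,
                         amplitudes: np.ndarray, noise: float = 0.0,
                         seed: int = 0) -> Structure:
    """Frames = structure + sum_i a_i(t) * direction_i + isotropic noise.

    ``directions`` is (n_dir, 3*n_atoms) with orthonormal rows;
    ``amplitudes`` is (n_frames, n_dir) in Angstrom.
    """
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    amplitudes = np.atleast_2d(np.asarray(amplitudes, dtype=float))
    gram = directions @ directions.T
    if not np.allclose(gram, np.eye(len(directions)), atol=1e-8):
        raise ValueError("directions must be orthonormal")
    if directions.shape[1] != 3 * structure.n_atoms:
        raise ValueError("direction length does not match structure")
    rng = np.random.default_rng(seed)
    base = structure.coords(0).ravel()
    frames = base[None, :] + amplitudes @ directions
    if noise > 0:
        frames = frames + rng.normal(scale=noise, size=frames.shape)
    return structure.with_coords(frames.reshape(len(frames), -1, 3),
                                 "mode-trajectory")


def make_correlated_series(n: int, rho: float, seed: int = 0
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Bivariate standard-normal pairs with population correlation ``rho``."""
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    if abs(rho) == 1.0:
        y = np.sign(rho) * x
    else:
        y = rho * x + np.sqrt(1.0 - rho ** 2) * rng.standard_normal(n)
    return x, y
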