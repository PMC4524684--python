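"""Template-based geometric simulation of flexible motion.

The engine explores large-amplitude motion of a structure while
maintaining its local bonding geometry and steric exclusion, in the
FRODA tradition: the structure is covered by overlapping templates (one
rigid template per rigid cluster from the pebble-game decomposition, plus
a small local template spanning every variable bond's neighbourhood);
each iteration perturbs all atoms along a bias direction derived from a
normal-mode eigenvector plus a small random kick, then *relaxes* the
positions by repeatedly fitting each template to the current atoms,
moving atoms to the average of their templates' proposals, and resolving
steric overlaps by symmetric pair separation.

Because no energy function is involved the motion has a natural
amplitude limit: once the bias pushes the structure against its bonding
and steric constraints the relaxation stops converging -- the trajectory
*jams* -- and the last satisfiable frame ends the run.

The bias field is recomputed from the fixed input-structure eigenvector,
never from the moving structure; exploring a mode therefore means running
once parallel and once antiparallel to it (eigenvector sign is
arbitrary).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structures import Structure
from .rigidity import (ConstraintNetwork, RigidDecomposition, VDW_RADII)

__all__ = [
    "GeoSimConfig",
    "TemplateSet",
    "GeoSimTrajectory",
    "build_templates",
    "relax",
    "run_geosim",
]


@dataclass
class GeoSimConfig:
    """Knobs of the geometric simulation (lengths in Angstrom)."""

    bias_step: float = 0.01        # per-step RMS displacement along the bias
    random_step: float = 0.01      # per-atom random kick radius
    direction: str = "parallel"    # or "antiparallel"
    max_steps: int = 5000
    relax_tolerance: float = 0.125
    max_relax_iters: int = 200
    jam_patience: int = 20         # consecutive failed steps => jammed
    jam_progress_fraction: float = 0.15  # min net motion per step vs bias
    steric_scale: float = 0.85     # soft-sphere scaling of vdW radii
    save_interval: int = 100       # frames kept every this many steps
    seed: int = 0

    def __post_init__(self):
        if self.direction not in ("parallel", "antiparallel"):
            raise ValueError("direction must be parallel or antiparallel")
        for name in ("bias_step", "random_step", "relax_tolerance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TemplateSet:
    """Overlapping rigid templates covering every atom."""

    indices: list[np.ndarray]      # atom index list per template
    references: list[np.ndarray]   # (m, 3) reference geometry per template
    n_atoms: int

    def membership(self) -> list[list[int]]:
        member: list[list[int]] = [[] for _ in range(self.n_atoms)]
        for t, idx in enumerate(self.indices):
            for a in idx:
                member[a].append(t)
        return member


@dataclass
class GeoSimTrajectory:
    """Frames, per-frame violations and jam status of one biased run."""

    frames: Structure
    frame_steps: np.ndarray
    max_violations: np.ndarray
    jammed: bool
    jam_step: int | None
    bias_label: str
    config: GeoSimConfig

    def to_files(self, prefix: str | Path) -> None:
        """Write <prefix>.pdb (multi-model), <prefix>.csv and <prefix>.json."""
        from .structures import write_trajectory

        prefix = Path(prefix)
        write_trajectory(self.frames, prefix.with_suffix(".pdb"))
        pd.DataFrame({"frame": np.arange(len(self.frame_steps)),
                      "step": self.frame_steps,
                      "max_violation": self.max_violations}) \
          .to_csv(prefix.with_suffix(".csv"), index=False)
        header = {"bias": self.bias_label, "jammed": self.jammed,
                  "jam_step": self.jam_step, "config": self.config.to_dict()}
        prefix.with_suffix(".json").write_text(json.dumps(header, indent=2))


def build_templates(structure: Structure, rigid: RigidDecomposition,
                    network: ConstraintNetwork) -> TemplateSet:
    """One template per rigid cluster plus local templates per variable bond.

    Every atom belongs to at least one template; templates adjacent along
    the chain of variable bonds overlap on the bond's endpoints, which is
    what propagates geometry through flexible regions.  Template reference
    geometry is the input structure, so the initial violation is zero.

    The flexible-region templates must enforce exactly the freedoms the
    rigidity analysis assigns.  In atomistic (body-bar) mode a variable
    bond keeps bond lengths and bond angles but rotates its dihedral, so
    each endpoint gets an atom-centred template over its own covalent
    neighbourhood (two templates overlapping on the bond).  In coarse
    point mode only the distance itself is constrained, so the template is
    the bare atom pair.
    """
    coords = network.coords
    n = structure.n_atoms
    templates: list[np.ndarray] = []
    for cluster in range(rigid.n_clusters):
        idx = np.where(rigid.cluster_labels == cluster)[0]
        if len(idx) >= 2:
            templates.append(idx)

    neighbors: dict[int, set[int]] = {}
    for c in network.constraints:
        if c.kind in ("covalent", "peptide-locked"):
            neighbors.setdefault(c.i, set()).add(c.j)
            neighbors.setdefault(c.j, set()).add(c.i)
    covalent_pairs = {c.pair() for c in network.constraints
                      if c.kind in ("covalent", "peptide-locked")}
    coarse = network.mode == "coarse"
    seen: set[tuple[int, ...]] = set()
    for (a, b), label in rigid.bond_labels.items():
        if label != "variable":
            continue
        if (min(a, b), max(a, b)) not in covalent_pairs:
            continue  # noncovalent links are pair constraints, not templates
        if coarse:
            groups = [(a, b)]
        else:
            groups = [tuple(sorted({a, b} | neighbors.get(a, set()))),
                      tuple(sorted({a, b} | neighbors.get(b, set())))]
        for g in groups:
            key = tuple(sorted(g))
            if key not in seen:
                seen.add(key)
                templates.append(np.array(sorted(g), dtype=int))

    covered = np.zeros(n, dtype=bool)
    for idx in templates:
        covered[idx] = True
    for a in np.where(~covered)[0]:
        idx = sorted({int(a)} | neighbors.get(int(a), set()))
        templates.append(np.array(idx, dtype=int))
        covered[idx] = True
    if not covered.all():
        raise ValueError("template construction left atoms uncovered")
    refs = [coords[idx].copy() for idx in templates]
    return TemplateSet(indices=templates, references=refs, n_atoms=n)


def _kabsch_fit(ref: np.ndarray, cur: np.ndarray) -> np.ndarray:
    """Proposal positions: ``ref`` rigidly superposed onto ``cur``."""
    c_ref = ref.mean(axis=0)
    c_cur = cur.mean(axis=0)
    h = (ref - c_ref).T @ (cur - c_cur)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return (ref - c_ref) @ rot.T + c_cur


def _steric_exclusions(network: ConstraintNetwork,
                       rigid: RigidDecomposition | None = None
                       ) -> set[tuple[int, int]]:
    """Pairs exempt from steric checks: 1-2 and 1-3 bonded pairs plus any
    pair joined directly by a constraint (their geometry is template- or
    constraint-governed)."""
    excl: set[tuple[int, int]] = set()
    bonded: dict[int, set[int]] = {}
    for c in network.constraints:
        excl.add(c.pair())
        if c.kind in ("covalent", "peptide-locked"):
            bonded.setdefault(c.i, set()).add(c.j)
            bonded.setdefault(c.j, set()).add(c.i)
    for a, nb in bonded.items():
        for b in nb:
            for c in bonded.get(b, ()):  # 1-3
                if c != a:
                    excl.add((min(a, c), max(a, c)))
    return excl


class _RelaxContext:
    """Precomputed bookkeeping reused across relax calls."""

    def __init__(self, structure: Structure, templates: TemplateSet,
                 network: ConstraintNetwork, config: GeoSimConfig,
                 rigid: RigidDecomposition | None = None):
        self.templates = templates
        self.network = network
        self.config = config
        self.member_counts = np.zeros(templates.n_atoms)
        for idx in templates.indices:
            self.member_counts[idx] += 1
        self.uncovered = self.member_counts == 0
        elements = [str(e).upper() for e in structure.stack.element]
        self.radii = np.array([VDW_RADII.get(e, 1.7) for e in elements])
        n = templates.n_atoms
        self.excl_codes = np.array(sorted(a * n + b for a, b in
                                          _steric_exclusions(network, rigid)),
                                   dtype=np.int64)
        # distance-maintaining pair constraints that cross template
        # boundaries (noncovalent links between different clusters)
        atom_sets = [set(int(i) for i in idx) for idx in templates.indices]
        pi, pj, pd0, ptether = [], [], [], []
        coords = network.coords
        seen: set[tuple[int, int]] = set()
        for c in network.constraints:
            pair = c.pair()
            if pair in seen:
                continue
            seen.add(pair)
            if any(c.i in s and c.j in s for s in atom_sets):
                continue
            pi.append(pair[0])
            pj.append(pair[1])
            pd0.append(float(np.linalg.norm(coords[c.i] - coords[c.j])))
            ptether.append(c.kind == "hydrophobic")
        self.pair_i = np.array(pi, dtype=int)
        self.pair_j = np.array(pj, dtype=int)
        self.pair_d0 = np.array(pd0)
        self.pair_tether = np.array(ptether, dtype=bool)


def relax(positions: np.ndarray, ctx: _RelaxContext
          ) -> tuple[np.ndarray, bool, float]:
    """Relax atom positions onto the templates and steric constraints.

    Returns ``(new_positions, converged, max_violation)``.  Convergence
    means the worst template mismatch, pair-constraint violation and
    steric overlap are all at or below ``relax_tolerance``; failure to
    converge within ``max_relax_iters`` is reported via the flag, never an
    exception.
    """
    cfg = ctx.config
    pos = positions.copy()
    tset = ctx.templates
    n = tset.n_atoms
    counts = ctx.member_counts[:, None]
    viol = np.inf
    for _ in range(cfg.max_relax_iters):
        accum = np.zeros_like(pos)
        mismatch = 0.0
        for idx, ref in zip(tset.indices, tset.references):
            prop = _kabsch_fit(ref, pos[idx])
            accum[idx] += prop
            # factor 2: two atoms each `dev` off their proposals can hold
            # an internal distance wrong by up to 2*dev, and the tolerance
            # is a bound on distance errors, not atom displacements
            mismatch = max(mismatch,
                           2.0 * float(np.linalg.norm(prop - pos[idx],
                                                      axis=1).max()))
        new_pos = np.where(ctx.uncovered[:, None], pos, accum
                           / np.where(counts == 0, 1, counts))
        pos = new_pos

        # noncovalent cross-template distance constraints
        pair_viol = 0.0
        if len(ctx.pair_i):
            delta = pos[ctx.pair_i] - pos[ctx.pair_j]
            d = np.linalg.norm(delta, axis=1)
            err = d - ctx.pair_d0
            err[ctx.pair_tether & (err < 0)] = 0.0  # tethers may shorten
            active = (np.abs(err) > 1e-12) & (d > 1e-9)
            if active.any():
                pair_viol = float(np.abs(err[active]).max())
                shift = 0.5 * (err[active] / d[active])[:, None] \
                    * delta[active]
                np.subtract.at(pos, ctx.pair_i[active], shift)
                np.add.at(pos, ctx.pair_j[active], shift)

        # steric exclusion
        tree = cKDTree(pos)
        contact_max = 2 * ctx.radii.max() * cfg.steric_scale
        pairs = tree.query_pairs(r=contact_max, output_type="ndarray")
        overlap = 0.0
        if len(pairs):
            codes = pairs[:, 0] * n + pairs[:, 1]
            keep = ~np.isin(codes, ctx.excl_codes)
            pairs = pairs[keep]
        if len(pairs):
            a, b = pairs[:, 0], pairs[:, 1]
            contact = (ctx.radii[a] + ctx.radii[b]) * cfg.steric_scale
            delta = pos[a] - pos[b]
            d = np.linalg.norm(delta, axis=1)
            clash = (d < contact) & (d > 1e-9)
            if clash.any():
                gap = contact[clash] - d[clash]
                overlap = float(gap.max())
                shift = 0.5 * (gap / d[clash])[:, None] * delta[clash]
                np.add.at(pos, a[clash], shift)
                np.subtract.at(pos, b[clash], shift)

        viol = max(mismatch, pair_viol, overlap)
        if viol <= cfg.relax_tolerance:
            return pos, True, viol
    return pos, False, viol


def _random_in_sphere(rng: np.random.Generator, n: int,
                      radius: float) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.uniform(0, 1, size=n) ** (1 / 3)
    return v * r[:, None]


def run_geosim(structure: Structure, bias_field: np.ndarray,
               templates: TemplateSet, network: ConstraintNetwork,
               config: GeoSimConfig | None = None,
               rigid: RigidDecomposition | None = None,
               bias_label: str = "bias") -> GeoSimTrajectory:
    """Run a mode-biased geometric simulation.

    ``bias_field`` is the per-atom displacement per step (already scaled
    so its RMS is the bias step; see ``enm.atomize_bias``).  Each step
    applies the bias plus an isotropic random kick and relaxes; a step
    whose relaxation fails is rolled back.  The trajectory ends as
    *jammed* either after ``jam_patience`` consecutive relaxation failures
    or when the net motion over the last ``jam_patience`` accepted steps
    falls below ``jam_progress_fraction`` of the driven displacement (the
    relaxation then merely undoes the bias each step: the motion has hit
    its constraint wall).  All emitted frames satisfy the relaxation
    tolerance.
    """
    config = config or GeoSimConfig()
    bias_field = np.asarray(bias_field, dtype=float)
    if bias_field.shape != (structure.n_atoms, 3):
        raise ValueError("bias field shape does not match structure")
    sign = 1.0 if config.direction == "parallel" else -1.0
    rng = np.random.default_rng(config.seed)
    ctx = _RelaxContext(structure, templates, network, config, rigid)

    bias_rms = float(np.sqrt((bias_field ** 2).sum(axis=1).mean()))
    pos = structure.coords(0).copy()
    frames = [pos.copy()]
    frame_steps = [0]
    violations = [0.0]
    fails = 0
    jammed = False
    jam_step = None
    last_viol = 0.0
    checkpoint = pos.copy()          # progress reference, jam detection
    accepted_since_checkpoint = 0
    step = 0
    for step in range(1, config.max_steps + 1):
        trial = pos + sign * bias_field \
            + _random_in_sphere(rng, len(pos), config.random_step)
        relaxed, ok, viol = relax(trial, ctx)
        if ok:
            pos = relaxed
            last_viol = viol
            fails = 0
            accepted_since_checkpoint += 1
            if accepted_since_checkpoint >= config.jam_patience:
                moved = float(np.sqrt(((pos - checkpoint) ** 2)
                                      .sum(axis=1).mean()))
                driven = bias_rms * accepted_since_checkpoint
                if moved < config.jam_progress_fraction * driven:
                    jammed = True
                    jam_step = step
                    break
                checkpoint = pos.copy()
                accepted_since_checkpoint = 0
        else:
            fails += 1
            if fails >= config.jam_patience:
                jammed = True
                jam_step = step
                break
            continue
        if step % config.save_interval == 0:
            frames.append(pos.copy())
            frame_steps.append(step)
            violations.append(viol)
    if frame_steps[-1] != step or jammed:
        frames.append(pos.copy())
        frame_steps.append(step)
        violations.append(last_viol)

    traj = structure.with_coords(np.stack(frames),
                                 source_id=f"geosim-{bias_label}")
    return GeoSimTrajectory(frames=traj,
                            frame_steps=np.array(frame_steps),
                            max_violations=np.array(violations),
                            jammed=jammed, jam_step=jam_step,
                            bias_label=bias_label, config=config)
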