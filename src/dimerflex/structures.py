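"""Protein structures, selections and multi-model PDB input/output.

The rest of the package manipulates a thin :class:`Structure` wrapper around a
:class:`biotite.structure.AtomArrayStack`.  A stack keeps one atom-identity
list shared by every model, which is exactly the contract a trajectory needs:
frame ``i`` is model ``i`` over the same atoms.

Conventions
-----------
* Coordinates are Angstrom everywhere; no unit conversion is performed.
* Author residue numbering (including insertion codes) is authoritative.
* Alternate locations are reduced to the highest-occupancy conformer at parse
  time (ties resolved alphabetically by altloc identifier).
* Waters and other non-protein HETATM records are dropped by default; pass
  ``include_ligands=True`` to keep non-water heteroatoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "AtomRecord",
    "Structure",
    "SelectionSpec",
    "read_structure",
    "write_trajectory",
    "swap_chains",
]

_WATER_NAMES = {"HOH", "WAT", "H2O", "DOD", "TIP", "TIP3"}


@dataclass(frozen=True)
class AtomRecord:
    """One atom of one model, in PDB author conventions."""

    serial: int
    name: str
    element: str
    alt_loc: str
    res_name: str
    chain_id: str
    res_seq: int
    insertion_code: str
    position: np.ndarray  # (3,) Angstrom
    occupancy: float

    @property
    def key(self) -> tuple:
        """Identity of the atom within a model."""
        return (self.chain_id, self.res_seq, self.insertion_code,
                self.name, self.alt_loc)


class Structure:
    """A (possibly multi-model) protein structure.

    Parameters
    ----------
    stack:
        Atom array stack; every model shares the atom identity list.
    source_id:
        Free text provenance, e.g. a PDB accession or generator tag.
    """

    def __init__(self, stack: struc.AtomArrayStack, source_id: str = ""):
        if isinstance(stack, struc.AtomArray):
            stack = struc.stack([stack])
        if stack.stack_depth() < 1:
            raise ValueError("a Structure needs at least one model")
        if stack.array_length() < 1:
            raise ValueError("a Structure needs at least one atom")
        self.stack = stack
        self.source_id = source_id

    # -- basic introspection -------------------------------------------------

    @property
    def n_models(self) -> int:
        return self.stack.stack_depth()

    @property
    def n_atoms(self) -> int:
        return self.stack.array_length()

    @property
    def chain_ids(self) -> list[str]:
        """Distinct chain identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for cid in self.stack.chain_id:
            seen.setdefault(str(cid), None)
        return list(seen)

    def coords(self, model: int = 0) -> np.ndarray:
        """(n_atoms, 3) coordinates of one model."""
        return np.asarray(self.stack.coord[model], dtype=float)

    def model(self, index: int) -> "Structure":
        """Single-model view (copy) of model ``index``."""
        return Structure(self.stack[index : index + 1].copy(), self.source_id)

    def with_coords(self, coords: np.ndarray, source_id: str | None = None) -> "Structure":
        """New Structure with identical atom identities and given coordinates.

        ``coords`` may be (n_atoms, 3) for one model or (n_models, n_atoms, 3).
        """
        coords = np.asarray(coords, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
        if coords.shape[1:] != (self.n_atoms, 3):
            raise ValueError(f"coordinate shape {coords.shape} does not match "
                             f"{self.n_atoms} atoms")
        template = self.stack[0]
        arrays = []
        for frame in coords:
            arr = template.copy()
            arr.coord = np.asarray(frame, dtype=np.float32)
            arrays.append(arr)
        return Structure(struc.stack(arrays),
                         self.source_id if source_id is None else source_id)

    # -- residue-level helpers ----------------------------------------------

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Ordered (chain_id, res_id, ins_code) for every residue."""
        keys: list[tuple[str, int, str]] = []
        last = None
        ins = self.stack.ins_code if "ins_code" in self.stack.get_annotation_categories() \
            else np.full(self.n_atoms, "", dtype="U1")
        for cid, rid, ic in zip(self.stack.chain_id, self.stack.res_id, ins):
            key = (str(cid), int(rid), str(ic))
            if key != last:
                keys.append(key)
                last = key
        return keys

    def ca_indices(self) -> np.ndarray:
        return np.where(self.stack.atom_name == "CA")[0]

    def atom_index(self, chain_id: str, res_seq: int, atom_name: str = "CA",
                   insertion_code: str = "") -> int:
        """Index of one named atom; raises ``KeyError`` if unresolvable."""
        s = self.stack
        mask = ((s.chain_id == chain_id) & (s.res_id == res_seq)
                & (s.atom_name == atom_name))
        if "ins_code" in s.get_annotation_categories():
            mask &= s.ins_code == insertion_code
        idx = np.where(mask)[0]
        if len(idx) == 0:
            raise KeyError(f"no atom {atom_name} in {chain_id}:{res_seq}"
                           f"{insertion_code!r}")
        return int(idx[0])

    def atom_records(self, model: int = 0) -> list[AtomRecord]:
        s = self.stack
        coords = self.coords(model)
        occ = getattr(s, "occupancy", None)
        ins = s.ins_code if "ins_code" in s.get_annotation_categories() else None
        records = []
        for i in range(self.n_atoms):
            records.append(AtomRecord(
                serial=i + 1,
                name=str(s.atom_name[i]),
                element=str(s.element[i]),
                alt_loc="",
                res_name=str(s.res_name[i]),
                chain_id=str(s.chain_id[i]),
                res_seq=int(s.res_id[i]),
                insertion_code=str(ins[i]) if ins is not None else "",
                position=coords[i],
                occupancy=float(occ[i]) if occ is not None else 1.0,
            ))
        return records


@dataclass(frozen=True)
class SelectionSpec:
    """Deterministic atom selection: chain / residue range / atom names.

    ``resolve`` always returns indices in ascending atom order, so the same
    spec on the same structure yields the same ordered list.
    """

    chains: tuple[str, ...] | None = None
    res_range: tuple[int, int] | None = None  # inclusive author numbering
    atom_names: tuple[str, ...] | None = None

    def resolve(self, structure: Structure) -> np.ndarray:
        s = structure.stack
        mask = np.ones(structure.n_atoms, dtype=bool)
        if self.chains is not None:
            mask &= np.isin(s.chain_id, list(self.chains))
        if self.res_range is not None:
            lo, hi = self.res_range
            mask &= (s.res_id >= lo) & (s.res_id <= hi)
        if self.atom_names is not None:
            mask &= np.isin(s.atom_name, list(self.atom_names))
        return np.where(mask)[0]

    @staticmethod
    def parse(text: str) -> "SelectionSpec":
        """Parse the CLI mini-language, e.g. ``"chain A,B res 10-50 name CA"``.

        Tokens: ``chain <ids>``, ``res <lo>-<hi>``, ``name <names>``; each
        optional, comma-separated lists allowed.
        """
        tokens = text.split()
        chains = res_range = atom_names = None
        i = 0
        while i < len(tokens):
            tok = tokens[i].lower()
            if tok == "chain":
                chains = tuple(tokens[i + 1].split(","))
            elif tok == "res":
                lo, hi = tokens[i + 1].split("-")
                res_range = (int(lo), int(hi))
            elif tok == "name":
                atom_names = tuple(tokens[i + 1].split(","))
            else:
                raise ValueError(f"unknown selection token {tokens[i]!r}")
            i += 2
        return SelectionSpec(chains, res_range, atom_names)


CA_SELECTION = SelectionSpec(atom_names=("CA",))


def _infer_elements(stack: struc.AtomArrayStack) -> None:
    """Fill empty element symbols from the atom name (in place)."""
    elements = stack.element.astype("U2")
    for i, (el, name) in enumerate(zip(elements, stack.atom_name)):
        if el.strip() == "":
            name = str(name).strip()
            stripped = name.lstrip("0123456789")
            elements[i] = stripped[:1].upper() if stripped else "C"
    stack.element = elements


def read_structure(path: str | Path, include_ligands: bool = False) -> Structure:
    """Read a (multi-model) PDB file.

    Alternate locations are reduced to the highest-occupancy conformer; water
    is always removed; other HETATM records are removed unless
    ``include_ligands``.

    Raises
    ------
    ValueError
        If the file contains no atoms or the models have mismatching atom
        identity lists (biotite refuses to stack them).
    """
    path = Path(path)
    pdb = PDBFile.read(str(path))
    try:
        stack = pdb.get_structure(model=None, altloc="occupancy",
                                  extra_fields=["occupancy"])
    except Exception as exc:  # mismatched models, empty file, ...
        raise ValueError(f"cannot read {path}: {exc}") from exc
    if stack.array_length() == 0:
        raise ValueError(f"{path} contains no ATOM records")
    keep = ~np.isin(stack.res_name, list(_WATER_NAMES))
    if not include_ligands:
        keep &= ~stack.hetero
    stack = stack[:, keep]
    if stack.array_length() == 0:
        raise ValueError(f"{path} contains no non-water atoms")
    _infer_elements(stack)
    return Structure(stack, source_id=path.stem)


def write_trajectory(frames: Structure, path: str | Path) -> None:
    """Write a Structure (>=1 model) as a multi-model PDB file.

    Round-tripping through :func:`read_structure` reproduces coordinates to
    PDB fixed-width precision (3 decimals).
    """
    if frames.n_models < 1:
        raise ValueError("no frames to write")
    pdb = PDBFile()
    stack = frames.stack
    if "occupancy" not in stack.get_annotation_categories():
        stack = stack.copy()
        stack.set_annotation("occupancy",
                             np.ones(stack.array_length(), dtype=float))
    pdb.set_structure(stack)
    pdb.write(str(path))


def write_structure(structure: Structure, path: str | Path, model: int = 0) -> None:
    """Write a single model as a PDB file."""
    write_trajectory(structure.model(model), path)


def swap_chains(structure: Structure, id1: str, id2: str) -> Structure:
    """Exchange two chain labels, leaving all coordinates untouched.

    Applying the swap twice restores the original labelling.  This is how the
    "swapped" closed reference of a homodimer is built: the same coordinates
    with the A/B identities reversed.
    """
    for cid in (id1, id2):
        if cid not in structure.chain_ids:
            raise KeyError(f"chain {cid!r} not present")
    stack = structure.stack.copy()
    c = stack.chain_id.astype("U4")
    m1 = c == id1
    m2 = c == id2
    c[m1] = id2
    c[m2] = id1
    stack.chain_id = c
    # keep atom order grouped per chain/residue so identity lists stay tidy
    return Structure(stack, source_id=structure.source_id + "-swapped")


def concat_frames(frames: Iterable[Structure]) -> Structure:
    """Concatenate single/multi-model structures that share one atom list."""
    arrays = []
    first: Structure | None = None
    for f in frames:
        if first is None:
            first = f
        for m in range(f.n_models):
            arrays.append(f.stack[m])
    if first is None:
        raise ValueError("no frames given")
    return Structure(struc.stack(arrays), first.source_id)
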