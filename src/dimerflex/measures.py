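"""Structural descriptors of cleft opening/closure and domain motion.

All measures are defined over named atom sites (chain, author residue
number, atom name) so the same machinery serves the real enzymes and the
synthetic toy dimer.  The stock site definitions for the two enzymes the
package targets:

* Scavenger-decapping-enzyme style intersite distances: the "A-B" active
  site is built from Trp175 of chain A and Asp111 of chain B, so
  ``d(AB) = |Ca Trp175:A - Ca Asp111:B|`` and d(BA) is the mirror.  The
  hinge angle of each chain is the Ca angle Tyr143-Arg145-Arg149.
* Citrate-synthase style cleft geometry: a tip-hinge-hinge-tip quartet
  (Gly312/Gly386 of both chains) defining the two cleft-closing angles ABC
  and BCD and the inter-domain dihedral ABCD.
* dRMS: root-mean-square of six cross-cleft distances, a multi-distance
  closure descriptor.

Angles are reported in degrees in [0, 180]; dihedrals are signed (IUPAC
convention, (-180, 180]); distances in Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

import biotite.structure as struc

from .structures import Structure, SelectionSpec

__all__ = [
    "Site",
    "DistanceMeasure",
    "AngleMeasure",
    "DihedralMeasure",
    "DrmsMeasure",
    "MeasureSet",
    "distance",
    "angle",
    "dihedral",
    "superpose",
    "dcps_intersite_measures",
    "dcps_hinge_measures",
    "dcps_drms_measure",
    "cs_cleft_measures",
    "toy_measures",
]


@dataclass(frozen=True)
class Site:
    """A named atom reference: chain, author residue number, atom name."""

    chain: str
    res: int
    atom: str = "CA"

    def resolve(self, structure: Structure) -> int:
        return structure.atom_index(self.chain, self.res, self.atom)


# -- geometry primitives ----------------------------------------------------

def distance(p: np.ndarray, q: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(p) - np.asarray(q)))


def angle(p: np.ndarray, q: np.ndarray, r: np.ndarray) -> float:
    """Interior angle at q, degrees in [0, 180]."""
    u = np.asarray(p) - np.asarray(q)
    v = np.asarray(r) - np.asarray(q)
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def dihedral(p: np.ndarray, q: np.ndarray, r: np.ndarray,
             s: np.ndarray) -> float:
    """Signed dihedral p-q-r-s, degrees in (-180, 180], IUPAC sign."""
    b1 = np.asarray(q) - np.asarray(p)
    b2 = np.asarray(r) - np.asarray(q)
    b3 = np.asarray(s) - np.asarray(r)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


# -- measure objects --------------------------------------------------------

@dataclass(frozen=True)
class DistanceMeasure:
    name: str
    sites: tuple[Site, Site]

    def evaluate(self, coords: np.ndarray, index: dict) -> float:
        i, j = (index[s] for s in self.sites)
        return distance(coords[i], coords[j])


@dataclass(frozen=True)
class AngleMeasure:
    name: str
    sites: tuple[Site, Site, Site]

    def evaluate(self, coords: np.ndarray, index: dict) -> float:
        i, j, k = (index[s] for s in self.sites)
        return angle(coords[i], coords[j], coords[k])


@dataclass(frozen=True)
class DihedralMeasure:
    name: str
    sites: tuple[Site, Site, Site, Site]

    def evaluate(self, coords: np.ndarray, index: dict) -> float:
        i, j, k, l = (index[s] for s in self.sites)
        return dihedral(coords[i], coords[j], coords[k], coords[l])


@dataclass(frozen=True)
class DrmsMeasure:
    """Raw root-mean-square of a set of intersite distances."""

    name: str
    pairs: tuple[tuple[Site, Site], ...]

    def evaluate(self, coords: np.ndarray, index: dict) -> float:
        d2 = [distance(coords[index[a]], coords[index[b]]) ** 2
              for a, b in self.pairs]
        return float(np.sqrt(np.mean(d2)))


Measure = DistanceMeasure | AngleMeasure | DihedralMeasure | DrmsMeasure


class MeasureSet:
    """An ordered collection of named measures evaluated per frame."""

    def __init__(self, measures: Sequence[Measure]):
        self.measures = list(measures)
        names = [m.name for m in self.measures]
        if len(set(names)) != len(names):
            raise ValueError("duplicate measure names")

    def _site_index(self, structure: Structure) -> dict:
        index: dict[Site, int] = {}
        for m in self.measures:
            if isinstance(m, DrmsMeasure):
                flat = [s for pair in m.pairs for s in pair]
            else:
                flat = list(m.sites)
            for s in flat:
                if s not in index:
                    index[s] = s.resolve(structure)
        return index

    def evaluate(self, structure: Structure, model: int = 0) -> dict:
        index = self._site_index(structure)
        coords = structure.coords(model)
        return {m.name: m.evaluate(coords, index) for m in self.measures}

    def series(self, frames: Structure) -> pd.DataFrame:
        """Per-frame evaluation; one row per frame, one column per measure."""
        index = self._site_index(frames)
        rows = []
        for f in range(frames.n_models):
            coords = frames.coords(f)
            rows.append({m.name: m.evaluate(coords, index)
                         for m in self.measures})
        df = pd.DataFrame(rows)
        df.insert(0, "frame", np.arange(frames.n_models))
        return df

    def tidy_series(self, frames: Structure) -> pd.DataFrame:
        """Long-format (frame, measure, value) table."""
        wide = self.series(frames)
        return wide.melt(id_vars="frame", var_name="measure",
                         value_name="value")

    # -- YAML round trip ----------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        kinds = {DistanceMeasure: "distance", AngleMeasure: "angle",
                 DihedralMeasure: "dihedral", DrmsMeasure: "drms"}
        entries = []
        for m in self.measures:
            e: dict = {"name": m.name, "kind": kinds[type(m)]}
            if isinstance(m, DrmsMeasure):
                e["pairs"] = [[[a.chain, a.res, a.atom],
                               [b.chain, b.res, b.atom]] for a, b in m.pairs]
            else:
                e["sites"] = [[s.chain, s.res, s.atom] for s in m.sites]
            entries.append(e)
        Path(path).write_text(yaml.safe_dump({"measures": entries},
                                             sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MeasureSet":
        data = yaml.safe_load(Path(path).read_text())
        measures: list[Measure] = []
        for e in data["measures"]:
            if e["kind"] == "drms":
                pairs = tuple((Site(a[0], int(a[1]), a[2]),
                               Site(b[0], int(b[1]), b[2]))
                              for a, b in e["pairs"])
                measures.append(DrmsMeasure(e["name"], pairs))
                continue
            sites = tuple(Site(s[0], int(s[1]), s[2]) for s in e["sites"])
            kind = {"distance": DistanceMeasure, "angle": AngleMeasure,
                    "dihedral": DihedralMeasure}[e["kind"]]
            measures.append(kind(e["name"], sites))
        return cls(measures)


# -- superposition ----------------------------------------------------------

def superpose(mobile: Structure, reference: Structure,
              selection: SelectionSpec | None = None,
              report_selection: SelectionSpec | None = None,
              model_mobile: int = 0, model_reference: int = 0
              ) -> tuple[Structure, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the fitted copy of ``mobile`` (all atoms moved) and the RMSD
    over ``report_selection`` (defaulting to the fit selection).  The fit
    selection must resolve to equal atom counts in both structures, in
    corresponding order.
    """
    sel = selection or SelectionSpec(atom_names=("CA",))
    idx_m = sel.resolve(mobile)
    idx_r = sel.resolve(reference)
    if len(idx_m) != len(idx_r):
        raise ValueError("fit selections resolve to different atom counts")
    if len(idx_m) < 3:
        raise ValueError("need at least 3 atoms to superpose")
    fixed = reference.stack[model_reference][idx_r]
    mob = mobile.stack[model_mobile][idx_m]
    _, transform = struc.superimpose(fixed, mob)
    moved_all = transform.apply(mobile.stack[model_mobile])
    fitted = mobile.with_coords(np.asarray(moved_all.coord, dtype=float))

    rep = report_selection or sel
    ridx_m = rep.resolve(mobile)
    ridx_r = rep.resolve(reference)
    if len(ridx_m) != len(ridx_r):
        raise ValueError("report selections resolve to different counts")
    diff = fitted.coords(0)[ridx_m] - reference.coords(model_reference)[ridx_r]
    rmsd = float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))
    return fitted, rmsd


# -- stock measure sets -----------------------------------------------------

def dcps_intersite_measures(trp: int = 175, asp: int = 111,
                            chains: tuple[str, str] = ("A", "B")
                            ) -> MeasureSet:
    a, b = chains
    return MeasureSet([
        DistanceMeasure("d_AB", (Site(a, trp), Site(b, asp))),
        DistanceMeasure("d_BA", (Site(b, trp), Site(a, asp))),
    ])


def dcps_hinge_measures(triple: tuple[int, int, int] = (143, 145, 149),
                        chains: tuple[str, str] = ("A", "B")) -> MeasureSet:
    r1, r2, r3 = triple
    return MeasureSet([
        AngleMeasure(f"hinge_{c}", (Site(c, r1), Site(c, r2), Site(c, r3)))
        for c in chains
    ])


def dcps_drms_measure(n_sites: tuple[int, int] = (110, 130),
                      c_sites: tuple[int, int, int] = (175, 279, 205),
                      chains: tuple[str, str] = ("A", "B")) -> MeasureSet:
    """Six cross-cleft distances per active site, RMS-combined."""
    a, b = chains

    def pairs(mob_chain, core_chain):
        return tuple((Site(mob_chain, m), Site(core_chain, c))
                     for m in n_sites for c in c_sites)

    return MeasureSet([
        DrmsMeasure("drms_AB", pairs(b, a)),
        DrmsMeasure("drms_BA", pairs(a, b)),
    ])


def cs_cleft_measures(tip: int = 312, hinge: int = 386,
                      chains: tuple[str, str] = ("A", "B")) -> MeasureSet:
    """Tip-hinge-hinge-tip quartet: angles ABC, BCD and dihedral ABCD."""
    a, b = chains
    A, B, C, D = Site(a, tip), Site(a, hinge), Site(b, hinge), Site(b, tip)
    return MeasureSet([
        AngleMeasure("ABC", (A, B, C)),
        AngleMeasure("BCD", (B, C, D)),
        DihedralMeasure("ABCD", (A, B, C, D)),
    ])


def toy_measures(toy) -> MeasureSet:
    """All stock measures mapped onto a toy dimer's designated sites."""
    t = toy
    a, b = "A", "B"
    h1, h2, h3 = t.hinge_triple
    m1, m2 = t.drms_mobile
    c1, c2, c3 = t.drms_core
    measures = [
        DistanceMeasure("d_AB", (Site(a, t.trp_res), Site(b, t.tip_res))),
        DistanceMeasure("d_BA", (Site(b, t.trp_res), Site(a, t.tip_res))),
        AngleMeasure("hinge_A", (Site(a, h1), Site(a, h2), Site(a, h3))),
        AngleMeasure("hinge_B", (Site(b, h1), Site(b, h2), Site(b, h3))),
        AngleMeasure("ABC", (Site(a, t.tip_res), Site(a, t.hinge_res),
                             Site(b, t.hinge_res))),
        AngleMeasure("BCD", (Site(a, t.hinge_res), Site(b, t.hinge_res),
                             Site(b, t.tip_res))),
        DihedralMeasure("ABCD", (Site(a, t.tip_res), Site(a, t.hinge_res),
                                 Site(b, t.hinge_res), Site(b, t.tip_res))),
        DrmsMeasure("drms_AB", tuple((Site(b, m), Site(a, c))
                                     for m in (m1, m2)
                                     for c in (c1, c2, c3))),
        DrmsMeasure("drms_BA", tuple((Site(a, m), Site(b, c))
                                     for m in (m1, m2)
                                     for c in (c1, c2, c3))),
    ]
    return MeasureSet(measures)
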