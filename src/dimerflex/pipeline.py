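"""End-to-end orchestration: structure -> modes -> rigidity -> biased
geometric simulation over a mode list -> measures -> summary.

Every run directory is reproducible from the resolved configuration and
seed written into it; output tables carry the run id and a configuration
hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .structures import Structure, read_structure, SelectionSpec
from . import enm as enm_mod
from .enm import build_enm, compute_modes, combine_modes, atomize_bias, ModeSet
from .rigidity import (build_constraint_network, pebble_game, RigidityConfig)
from .geosim import GeoSimConfig, build_templates, run_geosim
from .measures import (MeasureSet, DistanceMeasure, toy_measures,
                       dcps_intersite_measures, superpose)
from .synth import make_toy_dimer, ToyDimerSpec

__all__ = [
    "RunConfig",
    "run_pipeline",
    "compare_to_reference",
    "parse_mode_spec",
    "classify_cleft_modes",
]


def parse_mode_spec(text: str) -> list[tuple[int, float]]:
    """Parse "7", "8+7" or "9-7" into (mode, weight) pairs."""
    text = str(text).strip()
    out: list[tuple[int, float]] = []
    num = ""
    sign = 1.0
    for ch in text + "+":
        if ch in "+-":
            if num:
                out.append((int(num), sign))
            sign = 1.0 if ch == "+" else -1.0
            num = ""
        elif ch.isdigit():
            num += ch
        else:
            raise ValueError(f"bad mode spec {text!r}")
    if not out:
        raise ValueError(f"bad mode spec {text!r}")
    return out


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    input_path: str | None = None     # PDB file; None => toy dimer
    toy_seed: int = 0
    enm_cutoff: float = 12.0
    energy_cutoff: float = -2.0
    mode_specs: list = field(default_factory=lambda: ["7", "8", "9"])
    bias_step: float = 0.01
    random_step: float = 0.01
    max_steps: int = 5000
    save_interval: int = 100
    measure_spec: str | None = None   # YAML path; None => stock/toy set
    output_dir: str = "dimerflex-run"
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        """Hash of the scientific configuration (where the outputs land
        does not change what was computed)."""
        payload = {k: v for k, v in asdict(self).items()
                   if k != "output_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def classify_cleft_modes(modes: ModeSet, structure: Structure,
                         measure_set: MeasureSet,
                         pair_names: tuple[str, str] = ("d_AB", "d_BA"),
                         candidates: range | None = None) -> dict:
    """Classify low-frequency modes by their cleft-coupling signature.

    For each candidate mode the analytic derivative of both intersite
    distances along the eigenvector is computed; opposite signs mean an
    anti-symmetric (cooperative, one-closes-one-opens) motion, like signs
    a symmetric one.  Returns the strongest mode of each character --
    robust against the mode-order swaps that small changes of cutoff or
    spring constant can cause.
    """
    by_name = {m.name: m for m in measure_set.measures}
    pairs = []
    for name in pair_names:
        m = by_name[name]
        if not isinstance(m, DistanceMeasure):
            raise TypeError(f"{name} is not a distance measure")
        pairs.append(tuple(s.resolve(structure) for s in m.sites))
    coords = structure.coords(0)
    stack = structure.stack
    key_index = {key: i for i, key in enumerate(modes.residue_keys)}

    def residue_of(atom: int) -> int:
        ins = ""
        if "ins_code" in stack.get_annotation_categories():
            ins = str(stack.ins_code[atom])
        return key_index[(str(stack.chain_id[atom]),
                          int(stack.res_id[atom]), ins)]

    candidates = candidates or range(modes.n_trivial + 1,
                                     min(modes.n_trivial + 3,
                                         modes.n_modes) + 1)
    best = {"antisymmetric": (None, 0.0), "symmetric": (None, 0.0)}
    table = {}
    for m in candidates:
        v = modes.per_residue(modes.mode(m))
        derivs = []
        for i, j in pairs:
            u = coords[i] - coords[j]
            u = u / np.linalg.norm(u)
            derivs.append(float(u @ (v[residue_of(i)] - v[residue_of(j)])))
        d1, d2 = derivs
        character = "antisymmetric" if d1 * d2 < 0 else "symmetric"
        strength = min(abs(d1), abs(d2))
        table[m] = (character, d1, d2)
        if strength > best[character][1]:
            best[character] = (m, strength)
    return {"antisymmetric": best["antisymmetric"][0],
            "symmetric": best["symmetric"][0],
            "derivatives": table}


def compare_to_reference(frames: Structure, reference: Structure,
                         selection: SelectionSpec | None = None
                         ) -> pd.DataFrame:
    """Per-frame C-alpha RMSD trace against a reference structure.

    Returns a frame-indexed table with the RMSD column; the minimizing
    frame is ``df['rmsd'].idxmin()``.
    """
    sel = selection or SelectionSpec(atom_names=("CA",))
    rows = []
    for f in range(frames.n_models):
        _, rmsd = superpose(frames.model(f), reference, sel)
        rows.append(rmsd)
    return pd.DataFrame({"frame": np.arange(frames.n_models),
                         "rmsd": rows})


def run_pipeline(config: RunConfig) -> Path:
    """Run the full workflow; returns the output directory.

    For each mode spec, both parallel and antiparallel biased geometric
    simulations are run; each produces a trajectory (multi-model PDB), its
    measure series (CSV) and a jam report, plus a JSON summary of the
    minimum/maximum of every measure per run.  Any stage failure aborts
    with the stage name; partial outputs are retained.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    run_id = config.config_hash()

    stage = "input"
    try:
        if config.input_path is None:
            toy = make_toy_dimer(ToyDimerSpec(seed=config.toy_seed))
            structure = toy.structure
            measure_set = (MeasureSet.from_yaml(config.measure_spec)
                           if config.measure_spec else toy_measures(toy))
        else:
            structure = read_structure(config.input_path)
            measure_set = (MeasureSet.from_yaml(config.measure_spec)
                           if config.measure_spec
                           else dcps_intersite_measures())

        stage = "enm_modes"
        network = build_enm(structure, cutoff=config.enm_cutoff)
        max_needed = max(max(m for m, _ in parse_mode_spec(s))
                         for s in config.mode_specs)
        modes = compute_modes(network, n_modes=max(max_needed + 3, 12))
        modes.to_csv(out / "modes.csv")

        stage = "rigidity"
        rig_config = RigidityConfig(energy_cutoff=config.energy_cutoff)
        constraint_net = build_constraint_network(
            structure, energy_cutoff=config.energy_cutoff, config=rig_config)
        constraint_net.to_csv(out / "constraints.csv")
        decomposition = pebble_game(constraint_net)
        decomposition.to_csv(out / "clusters.csv")

        stage = "geosim"
        templates = build_templates(structure, decomposition, constraint_net)
        summary: dict = {"run_id": run_id, "floppy_modes":
                         decomposition.floppy_modes, "runs": {}}
        for spec in config.mode_specs:
            vec = combine_modes(modes, parse_mode_spec(spec))
            for direction in ("parallel", "antiparallel"):
                label = f"mode{spec}_{direction}"
                bias = atomize_bias(vec, structure, modes,
                                    step=config.bias_step)
                gs_config = GeoSimConfig(
                    bias_step=config.bias_step,
                    random_step=config.random_step,
                    direction=direction, max_steps=config.max_steps,
                    save_interval=config.save_interval, seed=config.seed)
                traj = run_geosim(structure, bias, templates, constraint_net,
                                  gs_config, rigid=decomposition,
                                  bias_label=label)
                traj.to_files(out / label)
                series = measure_set.series(traj.frames)
                series.insert(0, "run_id", run_id)
                series.insert(1, "stage", "measures")
                series.to_csv(out / f"{label}_measures.csv", index=False)
                summary["runs"][label] = {
                    "jammed": traj.jammed,
                    "jam_step": traj.jam_step,
                    "n_frames": traj.frames.n_models,
                    "measures": {
                        name: {"min": float(series[name].min()),
                               "max": float(series[name].max()),
                               "final": float(series[name].iloc[-1])}
                        for name in series.columns
                        if name not in ("run_id", "stage", "frame")},
                }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") \
            from exc
    return out
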