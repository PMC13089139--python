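"""End-to-end experiment orchestration.

Six named experiments reproduce the structure of the docking study:

* ``a723t_depro_scan`` — cation A docked into the A723T variant with one
  constraint set per (alpha proton, pyrophosphate anchor) pair: 5 x 2 = 10
  sets, pooled.
* ``a723t_depro_scan_with_water_6a`` / ``..._6b`` — the same ten sets rerun
  with the reactant water added under loosened face constraints (the water
  does not react with A).
* ``wt_water_dock_6a`` / ``wt_water_dock_6b`` — the rearranged cation B plus
  water docked into wild-type receptor with anchor-only sets (one per
  pyrophosphate end) and reactive water constraints; reports the epimer and
  the water's nearest labeled pyrophosphate oxygen.
* ``wt_mechanism_check`` — wild-type docking of A or B with the water and an
  added C7-to-residue-723 proximity restraint, probing whether the native
  reaction tolerates the reactant sitting against the 723 position.

Every run is deterministic given the config seed; per-set RNG streams are
derived from (seed, set_id) so adding sets never perturbs existing ones.
Artifacts (pose table, outcome report, manifest, filter trace) are written
under the configured output directory.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .classification import (
    classify_epimer,
    classify_pose,
    classify_water_location,
    tally,
    OutcomeReport,
)
from .conformers import ConformerLibrary, filter_library, generate_conformers
from .constraints import (
    ConstraintSet,
    build_deprotonation_sets,
    build_water_constraints,
    build_wt_mechanism_constraints,
)
from .docking import (
    DockingConfig,
    FilterTrace,
    Pose,
    Receptor,
    filter_stages,
    sample_poses,
    score_pose,
    write_poses_pdb,
)
from .intermediates import (
    CationGraph,
    enumerate_deprotonation_sites,
    enumerate_olefin_products,
    load_species,
)

__all__ = ["ExperimentConfig", "ExperimentResult", "EXPERIMENTS",
           "build_experiment_sets", "run_experiment", "StageError"]

EXPERIMENTS = (
    "a723t_depro_scan",
    "a723t_depro_scan_with_water_6a",
    "a723t_depro_scan_with_water_6b",
    "wt_water_dock_6a",
    "wt_water_dock_6b",
    "wt_mechanism_check",
)

BASE_SELECTOR = {"O": ("receptor", "BASE.O"), "H": ("receptor", "BASE.H")}


class StageError(RuntimeError):
    """An experiment stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class ExperimentConfig:
    experiment: str
    receptor: Receptor | str | Path
    species: CationGraph | str = "A"
    variant: str | None = None  # default: T for the A723T scans, A for WT
    docking: DockingConfig = field(default_factory=DockingConfig)
    outdir: str | Path | None = None
    pocket: tuple | None = None        # (center, radius) when loading a PDB
    conformer_library: ConformerLibrary | None = None
    write_pose_pdb: bool = False

    def resolved_variant(self) -> str:
        if self.variant is not None:
            return self.variant
        return "T" if self.experiment.startswith("a723t") else "A"


@dataclass
class ExperimentResult:
    report: OutcomeReport
    trace: FilterTrace
    passing: list[Pose]
    stage2: list[Pose]
    labels: list[str]
    sets: list[ConstraintSet]
    manifest: dict


def build_experiment_sets(
    experiment: str, g: CationGraph, rec: Receptor
) -> list[ConstraintSet]:
    """The constraint-set recipe for one named experiment."""
    if experiment not in EXPERIMENTS:
        raise StageError("config", f"unknown experiment {experiment!r}")
    anchors = rec.anchor_selectors()
    if experiment.startswith("a723t_depro_scan"):
        sites = enumerate_deprotonation_sites(g)
        sets = build_deprotonation_sets(g, sites, BASE_SELECTOR, anchors)
        if experiment.endswith("_6a") or experiment.endswith("_6b"):
            epimer = experiment[-2:]
            water = build_water_constraints(epimer, reactive=False)
            sets = [cs.with_restraints(water, water_mode=f"loose_{epimer}")
                    for cs in sets]
        return sets
    from .constraints import ANCHOR_DIST, FlatBottomRestraint

    anchor_sets = [
        ConstraintSet(
            set_id=f"anchor_{label}",
            restraints=[FlatBottomRestraint(
                "distance", (("carbocation", "C16"), sel), *ANCHOR_DIST)],
            anchor=label,
        )
        for label, sel in anchors
    ]
    if experiment in ("wt_water_dock_6a", "wt_water_dock_6b"):
        epimer = experiment[-2:]
        water = build_water_constraints(epimer, reactive=True)
        return [cs.with_restraints(water, water_mode=f"reactive_{epimer}")
                for cs in anchor_sets]
    # wt_mechanism_check: anchors x epimers, each with the C7-723 restraint
    mech = build_wt_mechanism_constraints(g.label if g.label in ("A", "B")
                                          else "A")
    reactive = g.label == "B"
    sets = []
    for cs in anchor_sets:
        for epimer in ("6a", "6b"):
            water = build_water_constraints(epimer, reactive=reactive)
            mode = ("reactive_" if reactive else "loose_") + epimer
            sets.append(ConstraintSet(
                set_id=f"{cs.set_id}_{epimer}_mech",
                restraints=list(cs.restraints) + list(water) + list(mech),
                anchor=cs.anchor,
                water_mode=mode,
            ))
    return sets


def _load_inputs(cfg: ExperimentConfig) -> tuple[Receptor, CationGraph]:
    from .docking import load_receptor

    if isinstance(cfg.receptor, Receptor):
        rec = cfg.receptor
    else:
        if cfg.pocket is None:
            raise StageError("config", "pocket spec required with a PDB path")
        rec = load_receptor(cfg.receptor, cfg.pocket, cfg.resolved_variant())
    if rec.pp_coords is None:
        from .docking import place_cofactors

        rec = place_cofactors(rec, cfg.docking.grid_spacing)
    g = (cfg.species if isinstance(cfg.species, CationGraph)
         else load_species(cfg.species))
    return rec, g


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Enumerate -> constrain -> dock -> filter -> classify -> tally."""
    t_start = time.time()
    try:
        rec, g = _load_inputs(cfg)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage context wrapper
        raise StageError("load", str(exc)) from exc

    try:
        sets = build_experiment_sets(cfg.experiment, g, rec)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("constraints", str(exc)) from exc

    try:
        lib = cfg.conformer_library
        if lib is None:
            lib = generate_conformers(
                g, cfg.docking.n_conformers, seed=cfg.docking.seed)
            lib = filter_library(lib)
    except Exception as exc:
        raise StageError("conformers", str(exc)) from exc

    ligand_index = {a.name: a.atom_id for a in g.atoms}
    pool: list[Pose] = []
    set_by_id = {cs.set_id: cs for cs in sets}
    try:
        for cs in sets:
            poses = sample_poses(rec, lib, cs, cfg.docking)
            for p in poses:
                score_pose(rec, p, cs, cfg.docking, ligand_index)
            pool.extend(poses)
    except Exception as exc:
        raise StageError("docking", str(exc)) from exc

    stage1, stage2, passing, trace = filter_stages(pool, cfg.docking)

    try:
        labels, water_labels, hypotheses = [], [], []
        depro = cfg.experiment.startswith(("a723t", "wt_mechanism"))
        sites = enumerate_deprotonation_sites(g) if rec.has_base_hydroxyl \
            and depro else []
        products = enumerate_olefin_products(g, sites) if sites else {}
        for p in passing:
            cs = set_by_id[p.set_id]
            hypotheses.append(cs.product_hypothesis.product_id
                              if cs.product_hypothesis else None)
            if sites:
                labels.append(classify_pose(p, rec, g, sites, products))
            elif p.water_coords is not None:
                labels.append(classify_epimer(p, g))
            else:
                labels.append("unassigned")
            if p.water_coords is not None:
                water_labels.append(classify_water_location(p, rec))
        report = tally(passing, labels,
                       water_labels if water_labels else None, hypotheses)
    except Exception as exc:
        raise StageError("classification", str(exc)) from exc

    manifest = {
        "experiment": cfg.experiment,
        "variant": cfg.resolved_variant(),
        "species": g.label,
        "n_sets": len(sets),
        "set_ids": [cs.set_id for cs in sets],
        "docking": asdict(cfg.docking),
        "n_conformers_used": len(lib),
        "trace": asdict(trace),
        "version": __version__,
        "config_hash": _config_hash(cfg, sets),
        "runtime_s": round(time.time() - t_start, 3),
    }
    result = ExperimentResult(report, trace, passing, stage2, labels, sets,
                              manifest)
    if cfg.outdir is not None:
        _write_artifacts(cfg, rec, g, result)
    return result


def _config_hash(cfg: ExperimentConfig, sets: list[ConstraintSet]) -> str:
    from .constraints import sets_to_json

    payload = json.dumps({
        "experiment": cfg.experiment,
        "variant": cfg.resolved_variant(),
        "docking": asdict(cfg.docking),
        "sets": sets_to_json(sets),
    }, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_artifacts(cfg: ExperimentConfig, rec: Receptor, g: CationGraph,
                     result: ExperimentResult) -> None:
    import pandas as pd

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # manifest omits runtime so reruns are byte-identical
    manifest = {k: v for k, v in result.manifest.items() if k != "runtime_s"}
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    result.report.to_json(outdir / "report.json")
    rows = [{
        "pose_id": p.pose_id, "set_id": p.set_id,
        "conformer_id": p.conformer_id,
        "total_score": round(p.total_score, 6),
        "interface_energy": round(p.interface_energy, 6),
        "label": lab,
        **{f"cst_{k}": round(v, 6) for k, v in p.cst_scores.items()},
    } for p, lab in zip(result.passing, result.labels)]
    pd.DataFrame(rows).to_csv(outdir / "passing_poses.tsv", sep="\t",
                              index=False)
    if cfg.write_pose_pdb and result.passing:
        write_poses_pdb(rec, result.passing, g, outdir / "passing_poses.pdb")
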