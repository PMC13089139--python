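"""Seeded rigid-body docking into a pocket with a simplified scorer.

Poses place one conformer of the carbocation (plus, depending on the
constraint set, a water) into the receptor pocket: rotations are drawn
uniformly on SO(3) (Shoemake quaternion method), translations uniformly in
the pocket sphere, and the water is positioned by an exhaustive local grid
search around its constraint target.  The pyrophosphate-magnesium co-product
is held at a fixed, grid-optimized position.

Scoring is a documented soft-sphere/contact surrogate, not a physical force
field:

    total = w_rep * sum (d_clash - d)^2_+        (all ligand bodies vs receptor)
          + w_att * (-min(contacts, cap))        (heavy pairs in 3.2-4.5 A)
          + w_cst * sum restraint penalties

    interface = repulsive + attractive terms of the carbocation body only.

The three-stage filter cascade keeps (1) poses whose per-ligand constraint
scores are all strictly below one, (2) the lowest 10% by total score, and
(3) the lowest 10% of those by carbocation interface energy, with floor
arithmetic and a minimum of one survivor per non-empty stage.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .conformers import ConformerLibrary
from .constraints import (
    ConstraintSet,
    Geometry,
    SelectorError,
    ligand_constraint_score,
)
from .intermediates import load_species

__all__ = [
    "Receptor",
    "Pose",
    "DockingConfig",
    "FilterTrace",
    "PlacementError",
    "load_receptor",
    "place_cofactors",
    "sample_poses",
    "score_pose",
    "filter_cascade",
    "stream_seed",
    "write_poses_pdb",
]

CLASH_DISTANCE = 3.0     # A, heavy-heavy soft-sphere onset
CONTACT_SHELL = (3.2, 4.5)
CONTACT_CAP = 100
WATER_CONTACT_CAP = 12   # coordination limit for a single water oxygen

# ideal side-chain hydroxyl grafting geometry (angstrom along CA->CB axis)
_CB_O_BOND = 1.43
_O_H_BOND = 0.96

_VARIANT_RESNAME = {"A": "ALA", "S": "SER", "T": "THR"}
_VARIANT_HYDROXYL = {"S": ("OG", "HG"), "T": ("OG1", "HG1")}


class PlacementError(RuntimeError):
    pass


@dataclass
class DockingConfig:
    n_poses_per_set: int = 4000
    seed: int = 0
    w_rep: float = 1.0
    w_att: float = 0.4
    w_cst: float = 1.0
    grid_spacing: float = 1.0       # A, cofactor and water grids
    percentile: float = 0.10
    water_grid_radius: float = 5.5  # A, local search box around the water target
    n_conformers: int = 8

    def __post_init__(self) -> None:
        if not (0.0 < self.percentile < 1.0):
            raise ValueError("percentile must lie in (0, 1)")
        if self.n_poses_per_set < 1:
            raise ValueError("n_poses_per_set must be >= 1")


@dataclass
class Receptor:
    """Pocket atoms plus labeled functional sites.

    Atom keys in geometry dictionaries are ``<resnum>.<atomname>``; the
    aliases ``BASE.O`` / ``BASE.H`` point at the residue-723 hydroxyl (when
    the variant has one) and ``723.TIP`` at the side-chain tip.  The
    pyrophosphate-Mg cluster is a separate rigid body ``pp_mg`` with atoms
    named as in the species registry (bridging oxygen ``O_BR``, terminals
    ``OT1``..``OT3``).
    """

    serials: np.ndarray
    atomnames: np.ndarray
    resnames: np.ndarray
    resnums: np.ndarray
    elements: np.ndarray
    coords: np.ndarray
    pocket_center: np.ndarray
    pocket_radius: float
    variant: str = "A"
    base_resnum: int = 723
    pp_coords: np.ndarray | None = None
    _cache: dict = field(default_factory=dict, repr=False)

    # -- selectors ---------------------------------------------------------
    def atom_index(self) -> dict[str, int]:
        if "index" not in self._cache:
            index = {
                f"{rn}.{an}": i
                for i, (rn, an) in enumerate(zip(self.resnums, self.atomnames))
            }
            mask = self.resnums == self.base_resnum
            names = set(self.atomnames[mask])
            hydroxyl = _VARIANT_HYDROXYL.get(self.variant)
            if hydroxyl and hydroxyl[0] in names:
                index["BASE.O"] = index[f"{self.base_resnum}.{hydroxyl[0]}"]
                index["BASE.H"] = index[f"{self.base_resnum}.{hydroxyl[1]}"]
            tip = None
            for cand in ("OG1", "OG", "CB"):
                if cand in names:
                    tip = cand
                    break
            if tip is not None:
                index["723.TIP"] = index[f"{self.base_resnum}.{tip}"]
            self._cache["index"] = index
        return self._cache["index"]

    @property
    def has_base_hydroxyl(self) -> bool:
        return "BASE.O" in self.atom_index()

    def base_o(self) -> np.ndarray:
        try:
            return self.coords[self.atom_index()["BASE.O"]]
        except KeyError:
            raise SelectorError(
                f"variant {self.variant!r} receptor has no base hydroxyl"
            ) from None

    def heavy_coords(self) -> np.ndarray:
        if "heavy" not in self._cache:
            self._cache["heavy"] = self.coords[self.elements != "H"]
        return self._cache["heavy"]

    def pp_index(self) -> dict[str, int]:
        pp = load_species("pp_mg")
        return {a.name: a.atom_id for a in pp.atoms}

    def pp_oxygen_labels(self) -> dict[str, str]:
        """Labeled pyrophosphate oxygens: atom name -> bridging|terminal."""
        return {"O_BR": "bridging", "OT1": "terminal", "OT2": "terminal",
                "OT3": "terminal"}

    def anchor_selectors(self) -> list[tuple[str, tuple[str, str]]]:
        """The two pyrophosphate 'ends': maximally separated terminal oxygens."""
        if self.pp_coords is None:
            raise PlacementError("pyrophosphate cluster has not been placed")
        idx = self.pp_index()
        terminals = [n for n, lab in self.pp_oxygen_labels().items()
                     if lab == "terminal"]
        best, best_d = None, -1.0
        for a in terminals:
            for b in terminals:
                if a >= b:
                    continue
                d = float(np.linalg.norm(
                    self.pp_coords[idx[a]] - self.pp_coords[idx[b]]))
                if d > best_d:
                    best, best_d = (a, b), d
        return [(name, ("pp_mg", name)) for name in best]

    def base_geometry(self) -> Geometry:
        geom: Geometry = {"receptor": (self.coords, self.atom_index())}
        if self.pp_coords is not None:
            geom["pp_mg"] = (self.pp_coords, self.pp_index())
        return geom

    # -- I/O ---------------------------------------------------------------
    def to_pdb(self, path: str | Path) -> None:
        import biotite.structure as struc
        import biotite.structure.io.pdb as pdb

        arr = struc.AtomArray(len(self.serials))
        arr.coord = np.asarray(self.coords, dtype=np.float32)
        arr.atom_name = self.atomnames
        arr.res_name = self.resnames
        arr.res_id = self.resnums
        arr.element = self.elements
        arr.chain_id = np.full(len(self.serials), "A")
        arr.hetero = np.array([rn not in _VARIANT_RESNAME.values()
                               for rn in self.resnames])
        f = pdb.PDBFile()
        pdb.set_structure(f, arr)
        f.write(str(path))


def load_receptor(
    path: str | Path,
    pocket: tuple[np.ndarray, float],
    variant: str = "A",
    base_resnum: int = 723,
) -> Receptor:
    """Read a receptor PDB and install the residue-723 variant side chain.

    When the requested variant differs from the crystal identity, the
    hydroxyl is grafted with ideal geometry along the CA->CB axis (Thr:
    OG1/HG1, Ser: OG/HG); variant A strips any hydroxyl atoms.  When the
    variant matches the file, coordinates are left untouched (a missing
    hydroxyl hydrogen is added).
    """
    import biotite.structure.io.pdb as pdb

    arr = pdb.PDBFile.read(str(path)).get_structure(model=1)
    if variant not in _VARIANT_RESNAME:
        raise ValueError(f"unknown variant {variant!r}; expected A, S or T")
    resnums = np.asarray(arr.res_id)
    if base_resnum not in resnums:
        raise PlacementError(f"receptor lacks residue {base_resnum}")

    serials = np.arange(1, arr.array_length() + 1)
    rec = Receptor(
        serials=serials,
        atomnames=np.asarray(arr.atom_name, dtype="U6"),
        resnames=np.asarray(arr.res_name, dtype="U4"),
        resnums=resnums.copy(),
        elements=np.asarray(arr.element, dtype="U2"),
        coords=np.asarray(arr.coord, dtype=float),
        pocket_center=np.asarray(pocket[0], dtype=float),
        pocket_radius=float(pocket[1]),
        variant=variant,
        base_resnum=base_resnum,
    )
    return _apply_variant(rec, variant)


def _apply_variant(rec: Receptor, variant: str) -> Receptor:
    mask = rec.resnums == rec.base_resnum
    names = list(rec.atomnames[mask])
    missing = [n for n in ("CA", "CB") if n not in names]
    if missing:
        raise PlacementError(
            f"residue {rec.base_resnum} lacks atoms {missing}; cannot graft"
        )
    keep = np.ones(len(rec.serials), dtype=bool)
    hydroxyl_names = {"OG", "HG", "OG1", "HG1"}
    target = _VARIANT_HYDROXYL.get(variant, ())
    # drop hydroxyl atoms that do not belong to the requested variant
    for i in np.flatnonzero(mask):
        if rec.atomnames[i] in hydroxyl_names and rec.atomnames[i] not in target:
            keep[i] = False
    rec = _subset(rec, keep)
    mask = rec.resnums == rec.base_resnum
    names = set(rec.atomnames[mask])
    if target:
        idx = {n: i for n, i in zip(rec.atomnames[mask], np.flatnonzero(mask))}
        ca = rec.coords[idx["CA"]]
        cb = rec.coords[idx["CB"]]
        u = (cb - ca) / np.linalg.norm(cb - ca)
        additions = []
        if target[0] not in names:
            additions.append((target[0], "O", cb + _CB_O_BOND * u))
        o_pos = (rec.coords[idx[target[0]]] if target[0] in names
                 else cb + _CB_O_BOND * u)
        if target[1] not in names:
            additions.append((target[1], "H", o_pos + _O_H_BOND * u))
        if additions:
            rec = _append_atoms(rec, additions)
    rec.resnames[rec.resnums == rec.base_resnum] = _VARIANT_RESNAME[variant]
    rec.variant = variant
    rec._cache.clear()
    return rec


def _subset(rec: Receptor, keep: np.ndarray) -> Receptor:
    return replace(
        rec,
        serials=rec.serials[keep], atomnames=rec.atomnames[keep],
        resnames=rec.resnames[keep], resnums=rec.resnums[keep],
        elements=rec.elements[keep], coords=rec.coords[keep],
        _cache={},
    )


def _append_atoms(rec: Receptor, additions: list[tuple[str, str, np.ndarray]]
                  ) -> Receptor:
    n = len(additions)
    return replace(
        rec,
        serials=np.concatenate([rec.serials,
                                rec.serials.max() + 1 + np.arange(n)]),
        atomnames=np.concatenate([rec.atomnames,
                                  np.array([a[0] for a in additions], "U6")]),
        resnames=np.concatenate([rec.resnames,
                                 np.full(n, _VARIANT_RESNAME[rec.variant], "U4")]),
        resnums=np.concatenate([rec.resnums, np.full(n, rec.base_resnum)]),
        elements=np.concatenate([rec.elements,
                                 np.array([a[1] for a in additions], "U2")]),
        coords=np.vstack([rec.coords, [a[2] for a in additions]]),
        _cache={},
    )


# ---------------------------------------------------------------------------
# cofactor placement
# ---------------------------------------------------------------------------

def _pocket_grid(center: np.ndarray, radius: float, spacing: float) -> np.ndarray:
    ticks = np.arange(-radius, radius + 1e-9, spacing)
    pts = np.stack(np.meshgrid(ticks, ticks, ticks, indexing="ij"),
                   axis=-1).reshape(-1, 3)
    pts = pts[np.linalg.norm(pts, axis=1) <= radius]
    return pts + center


def place_cofactors(
    rec: Receptor,
    grid_spacing: float | None = None,
    restraints=None,
) -> Receptor:
    """Position the pyrophosphate-Mg cluster by exhaustive pocket grid scan.

    The cluster is translated (template orientation fixed) over a cubic grid
    inside the pocket sphere; the chosen point minimizes soft-sphere clash
    with the receptor plus any supplied restraint penalties.  Ties break on
    the lexicographically smallest grid index, and the scan fails loudly if
    no clash-free point exists.
    """
    spacing = grid_spacing if grid_spacing is not None else 1.0
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    from .intermediates import RIGID_TEMPLATES

    template = load_species("pp_mg")
    tcoords = RIGID_TEMPLATES["pp_mg"] - RIGID_TEMPLATES["pp_mg"].mean(axis=0)
    grid = _pocket_grid(rec.pocket_center, rec.pocket_radius, spacing)
    heavy = rec.heavy_coords()
    clash = np.zeros(len(grid))
    for atom_offset in tcoords:
        d = cdist(grid + atom_offset, heavy)
        clash += np.sum(np.maximum(0.0, CLASH_DISTANCE - d) ** 2, axis=1)
    penalty = clash.copy()
    if restraints:
        pp_index = {a.name: a.atom_id for a in template.atoms}
        for k, point in enumerate(grid):
            geom: Geometry = dict(rec.base_geometry())
            geom["pp_mg"] = (tcoords + point, pp_index)
            penalty[k] += sum(r.penalty(geom) for r in restraints)
    if clash.min() > 0.0:
        raise PlacementError(
            "no clash-free grid point for the pyrophosphate-Mg cluster"
        )
    best = int(np.argmin(penalty))  # np.argmin returns the first minimum
    out = replace(rec, pp_coords=tcoords + grid[best], _cache={})
    return out


# ---------------------------------------------------------------------------
# pose sampling
# ---------------------------------------------------------------------------

@dataclass
class Pose:
    pose_id: str
    set_id: str
    conformer_id: int
    quat: np.ndarray         # unit quaternion, scalar-last (x, y, z, w)
    translation: np.ndarray  # centroid position, A
    ligand_coords: np.ndarray
    water_coords: np.ndarray | None = None
    cst_scores: dict[str, float] = field(default_factory=dict)
    total_score: float = math.nan
    interface_energy: float = math.nan

    def geometry(self, rec: Receptor, ligand_index: dict[str, int]) -> Geometry:
        geom = dict(rec.base_geometry())
        geom["carbocation"] = (self.ligand_coords, ligand_index)
        if self.water_coords is not None:
            geom["water"] = (self.water_coords, {"O": 0, "H1": 1, "H2": 2})
        return geom

    def serialize(self) -> str:
        parts = [self.pose_id, str(self.conformer_id)]
        parts += [f"{v:.9f}" for v in self.quat]
        parts += [f"{v:.9f}" for v in self.translation]
        if self.water_coords is not None:
            parts += [f"{v:.9f}" for v in self.water_coords.ravel()]
        return " ".join(parts)


def stream_seed(base_seed: int, set_id: str) -> int:
    """Per-set RNG stream: adding sets never perturbs existing streams."""
    digest = hashlib.sha256(f"{base_seed}|{set_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _shoemake_quats(rng: np.random.Generator, n: int) -> np.ndarray:
    u1, u2, u3 = rng.random((3, n))
    return np.stack([
        np.sqrt(1 - u1) * np.sin(2 * np.pi * u2),
        np.sqrt(1 - u1) * np.cos(2 * np.pi * u2),
        np.sqrt(u1) * np.sin(2 * np.pi * u3),
        np.sqrt(u1) * np.cos(2 * np.pi * u3),
    ], axis=1)


def _flat_bottom_vec(x: np.ndarray, lower: float, upper: float,
                     sd: float, weight: float) -> np.ndarray:
    excess = np.where(x < lower, lower - x, np.where(x > upper, x - upper, 0.0))
    return weight * (excess / sd) ** 2


def _place_water(
    rng_point_tiebreak: None,
    rec: Receptor,
    ligand_coords: np.ndarray,
    ligand_index: dict[str, int],
    cset: ConstraintSet,
    cfg: DockingConfig,
) -> np.ndarray:
    """Exhaustive local grid search for the water oxygen around its target.

    Candidates around the 13-yl carbon are scored by the water restraints of
    the set plus soft clash against receptor and ligand heavy atoms; the
    first minimal grid point wins (deterministic).
    """
    from .intermediates import RIGID_TEMPLATES

    water_restraints = [r for r in cset.restraints if "water" in r.bodies]
    # target: the carbocation-side member of the water distance restraint
    target_name = "C13"
    for r in water_restraints:
        if r.kind == "distance":
            for body, name in r.members:
                if body == "carbocation":
                    target_name = name
    target = ligand_coords[ligand_index[target_name]]
    ticks = np.arange(-cfg.water_grid_radius, cfg.water_grid_radius + 1e-9,
                      cfg.grid_spacing)
    pts = np.stack(np.meshgrid(ticks, ticks, ticks, indexing="ij"),
                   axis=-1).reshape(-1, 3) + target
    score = np.zeros(len(pts))
    for r in water_restraints:
        if r.kind == "distance":
            other = [m for m in r.members if m[0] == "carbocation"][0]
            d = np.linalg.norm(pts - ligand_coords[ligand_index[other[1]]],
                               axis=1)
            score += _flat_bottom_vec(d, r.lower, r.upper, r.sd, r.weight)
        elif r.kind == "face_angle":
            center, s1, s2, s3, _probe = r.members
            c = ligand_coords[ligand_index[center[1]]]
            a1 = ligand_coords[ligand_index[s1[1]]]
            a2 = ligand_coords[ligand_index[s2[1]]]
            a3 = ligand_coords[ligand_index[s3[1]]]
            normal = r.face_sign * np.cross(a2 - a1, a3 - a1)
            v = pts - c
            denom = np.linalg.norm(normal) * np.linalg.norm(v, axis=1)
            cos = np.clip(np.einsum("j,ij->i", normal, v)
                          / np.maximum(denom, 1e-12), -1, 1)
            ang = np.degrees(np.arccos(cos))
            score += _flat_bottom_vec(ang, r.lower, r.upper, r.sd, r.weight)
    # full local objective — restraints + soft clash - capped attractive
    # contacts against the fixed environment (receptor + PP cluster) and the
    # ligand — evaluated only for candidates whose restraint penalty is
    # within the largest bonus the attractive term could confer; no point
    # outside that margin can beat the best candidate
    heavy_lig = ligand_coords[[i for n, i in ligand_index.items()
                               if not n.startswith("H")]]
    if "kdtree" not in rec._cache:
        from scipy.spatial import cKDTree

        rec._cache["kdtree"] = cKDTree(rec.heavy_coords())
    near_idx = rec._cache["kdtree"].query_ball_point(
        target, cfg.water_grid_radius * math.sqrt(3) + CONTACT_SHELL[1])
    near_rec = rec.heavy_coords()[near_idx]
    env = [near_rec] if len(near_rec) else []
    if rec.pp_coords is not None:
        env.append(rec.pp_coords)
    env = np.vstack(env) if env else np.zeros((0, 3))
    margin = cfg.w_att * WATER_CONTACT_CAP
    cand = np.flatnonzero(score <= score.min() + margin)
    clash = np.zeros(len(cand))
    contacts = np.zeros(len(cand))
    lo, hi = CONTACT_SHELL
    if len(env):
        d = cdist(pts[cand], env)
        clash += np.sum(np.maximum(0.0, CLASH_DISTANCE - d) ** 2, axis=1)
        contacts = np.minimum(np.sum((d >= lo) & (d <= hi), axis=1),
                              WATER_CONTACT_CAP)
    # the ligand contributes clash only, mirroring the pose scorer, which
    # counts attractive contacts against the fixed environment alone
    d_lig = cdist(pts[cand], heavy_lig)
    clash += np.sum(np.maximum(0.0, CLASH_DISTANCE - d_lig) ** 2, axis=1)
    total = score[cand] + cfg.w_rep * clash - cfg.w_att * contacts
    best_point = pts[cand[int(np.argmin(total))]]
    template = RIGID_TEMPLATES["water"]
    return template - template[0] + best_point


def sample_poses(
    rec: Receptor,
    lib: ConformerLibrary,
    cset: ConstraintSet,
    cfg: DockingConfig,
) -> list[Pose]:
    """Draw ``cfg.n_poses_per_set`` rigid placements for one constraint set.

    Fully reproducible: the RNG stream is derived from (cfg.seed, set_id),
    so per-set pose lists are independent of which other sets run.
    """
    if len(lib) == 0:
        raise ValueError("conformer library is empty")
    rng = np.random.default_rng(stream_seed(cfg.seed, cset.set_id))
    n = cfg.n_poses_per_set
    conf_ids = rng.integers(0, len(lib), size=n)
    quats = _shoemake_quats(rng, n)
    directions = rng.normal(size=(n, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    radii = rec.pocket_radius * rng.random(n) ** (1.0 / 3.0)
    centers = rec.pocket_center + directions * radii[:, None]
    species = lib[0].species
    ligand_index = {a.name: a.atom_id for a in species.atoms}
    poses = []
    for i in range(n):
        conf = lib[int(conf_ids[i])]
        local = conf.coords - conf.coords.mean(axis=0)
        rot = Rotation.from_quat(quats[i])
        ligand = rot.apply(local) + centers[i]
        water = None
        if cset.water_mode != "none":
            water = _place_water(None, rec, ligand, ligand_index, cset, cfg)
        poses.append(Pose(
            pose_id=f"{cset.set_id}:{i:05d}",
            set_id=cset.set_id,
            conformer_id=int(conf_ids[i]),
            quat=quats[i],
            translation=centers[i],
            ligand_coords=ligand,
            water_coords=water,
        ))
    return poses


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _body_terms(body_heavy: np.ndarray, receptor_heavy: np.ndarray
                ) -> tuple[float, int]:
    d = cdist(body_heavy, receptor_heavy)
    rep = float(np.sum(np.maximum(0.0, CLASH_DISTANCE - d) ** 2))
    lo, hi = CONTACT_SHELL
    contacts = int(np.sum((d >= lo) & (d <= hi)))
    return rep, contacts


def score_pose(
    rec: Receptor,
    pose: Pose,
    cset: ConstraintSet,
    cfg: DockingConfig,
    ligand_index: dict[str, int],
) -> Pose:
    """Fill in per-ligand constraint scores, total score and interface energy."""
    geom = pose.geometry(rec, ligand_index)
    bodies = [b for b in ("carbocation", "water", "pp_mg") if b in geom]
    pose.cst_scores = {
        b: ligand_constraint_score(geom, cset, b) for b in bodies
    }
    # the mobile bodies are scored against the fixed environment: receptor
    # atoms plus the stationary pyrophosphate-Mg co-product
    receptor_heavy = rec.heavy_coords()
    env = (np.vstack([receptor_heavy, rec.pp_coords])
           if rec.pp_coords is not None else receptor_heavy)
    heavy_rows = [i for n, i in ligand_index.items() if not n.startswith("H")]
    rep_c, con_c = _body_terms(pose.ligand_coords[heavy_rows], env)
    rep, contacts = rep_c, con_c
    if pose.water_coords is not None:
        r, c = _body_terms(pose.water_coords[:1], env)
        rep += r
        contacts += min(c, WATER_CONTACT_CAP)
    if rec.pp_coords is not None:
        r, c = _body_terms(rec.pp_coords, receptor_heavy)
        rep += r
        contacts += c
    cst_total = sum(r.penalty(geom) for r in cset.restraints)
    pose.total_score = (cfg.w_rep * rep
                        - cfg.w_att * min(contacts, CONTACT_CAP)
                        + cfg.w_cst * cst_total)
    pose.interface_energy = (cfg.w_rep * rep_c
                             - cfg.w_att * min(con_c, CONTACT_CAP))
    return pose


# ---------------------------------------------------------------------------
# filter cascade
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterTrace:
    n0: int  # input poses
    n1: int  # after the per-ligand constraint-score stage
    k1: int  # after the total-score percentile stage
    k2: int  # after the interface-energy percentile stage


def filter_stages(
    poses: list[Pose], cfg: DockingConfig
) -> tuple[list[Pose], list[Pose], list[Pose], FilterTrace]:
    """All three cascade stages: constraint-satisfying poses, the lowest
    10% of those by total score, and the lowest 10% of those by carbocation
    interface energy.

    Percentile counts use floor with a minimum of one survivor whenever the
    previous stage is non-empty; sorting is stable with pose_id as the tie
    break, so the output is invariant to input shuffling.
    """
    n0 = len(poses)
    stage1 = [p for p in poses
              if all(v < 1.0 for v in p.cst_scores.values())]
    n1 = len(stage1)
    if n1 == 0:
        return stage1, [], [], FilterTrace(n0, 0, 0, 0)
    k1 = max(1, int(math.floor(cfg.percentile * n1)))
    stage2 = sorted(stage1, key=lambda p: (p.total_score, p.pose_id))[:k1]
    k2 = max(1, int(math.floor(cfg.percentile * k1)))
    stage3 = sorted(stage2, key=lambda p: (p.interface_energy, p.pose_id))[:k2]
    return stage1, stage2, stage3, FilterTrace(n0, n1, k1, k2)


def filter_cascade(
    poses: list[Pose], cfg: DockingConfig
) -> tuple[list[Pose], FilterTrace]:
    """Poses surviving the full three-stage cascade, with the stage trace."""
    _, _, stage3, trace = filter_stages(poses, cfg)
    return stage3, trace


# ---------------------------------------------------------------------------
# pose output
# ---------------------------------------------------------------------------

def write_poses_pdb(
    rec: Receptor,
    poses: list[Pose],
    species,
    path: str | Path,
    max_models: int = 25,
) -> None:
    """Multi-model PDB: receptor plus ligand bodies, one pose per MODEL."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    poses = poses[:max_models]
    if not poses:
        Path(path).write_text("")
        return
    lig_names = np.array([a.name for a in species.atoms], "U6")
    lig_elements = np.array([a.element for a in species.atoms], "U2")
    has_water = poses[0].water_coords is not None
    has_pp = rec.pp_coords is not None
    pp = load_species("pp_mg")

    def model_array(pose: Pose) -> struc.AtomArray:
        blocks = [(rec.atomnames, rec.resnames, rec.resnums, rec.elements,
                   rec.coords)]
        blocks.append((lig_names, np.full(len(lig_names), "LIG", "U4"),
                       np.full(len(lig_names), 901),
                       lig_elements, pose.ligand_coords))
        if has_water and pose.water_coords is not None:
            blocks.append((np.array(["O", "H1", "H2"], "U6"),
                           np.full(3, "HOH", "U4"), np.full(3, 902),
                           np.array(["O", "H", "H"], "U2"),
                           pose.water_coords))
        if has_pp:
            blocks.append((np.array([a.name for a in pp.atoms], "U6"),
                           np.full(pp.n_atoms, "PPM", "U4"),
                           np.full(pp.n_atoms, 903),
                           np.array([a.element for a in pp.atoms], "U2"),
                           rec.pp_coords))
        total = sum(len(b[0]) for b in blocks)
        arr = struc.AtomArray(total)
        arr.atom_name = np.concatenate([b[0] for b in blocks])
        arr.res_name = np.concatenate([b[1] for b in blocks])
        arr.res_id = np.concatenate([b[2] for b in blocks])
        arr.element = np.concatenate([b[3] for b in blocks])
        arr.coord = np.vstack([b[4] for b in blocks]).astype(np.float32)
        arr.chain_id = np.full(total, "A")
        arr.hetero = arr.res_id >= 900
        return arr

    stack = struc.stack([model_array(p) for p in poses])
    f = pdb.PDBFile()
    pdb.set_structure(f, stack)
    f.write(str(path))
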