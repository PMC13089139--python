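"""Programmatic fixtures: toy receptors, toy cations and planted pose sets.

Nothing here downloads or ships data.  The toy receptor is a spherical shell
of pseudo-atoms with (i) one protein-like residue numbered 723 whose side
chain protrudes into the cavity and carries the variant hydroxyl (emulating
the helix-break base site) and (ii) a rigid pyrophosphate-Mg cluster with a
labeled bridging oxygen near the wall.  The toy cation is a star-shaped
carbocation whose alpha-proton census is freely configurable — ``[2, 2, 1]``
mirrors the C7/C14/C9 census of the isopimarenyl cation — plus a small
anchor/face scaffold (C12, C13, C15, C16) so the same constraint builders
and classifiers run unchanged on it.

``plant_poses`` manufactures pose sets with known truth: each pose is
oriented so its planted product's proton (or, for epimer planting, a water
on the requested face of C13) satisfies the classification gate exactly,
with controllable geometric jitter and synthetic score distributions, so
cascade and classifier behavior can be tested against planted ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .conformers import Conformer

from .docking import Pose, Receptor, _apply_variant
from .intermediates import (
    Atom,
    CationGraph,
    DeprotonationSite,
    ProductSpec,
    RIGID_TEMPLATES,
    SpeciesError,
    enumerate_deprotonation_sites,
    enumerate_olefin_products,
)

__all__ = [
    "FixtureSpec",
    "Workspace",
    "make_toy_receptor",
    "make_toy_cation",
    "plant_poses",
    "make_aligned_workspace",
    "write_demo_workspace",
]

SHELL_MARGIN = 4.5  # A between the atom shell and the pose-sampling sphere


@dataclass
class FixtureSpec:
    """Parameters of one synthetic fixture; all lengths in angstrom."""

    seed: int = 0
    pocket_radius: float = 10.0         # radius of the atom shell
    shell_atoms: int = 420              # ~2 A wall spacing: waters cannot slip through
    base_polar_angle: float = 55.0      # degrees from +z, base-site direction
    pp_direction: tuple[float, float, float] = (0.0, 1.0, 0.3)
    pp_fraction: float = 0.62           # radial position of the PP centroid
    outcome_fractions: dict[str, float] = field(default_factory=lambda: {"7": 1.0})
    score_noise_sd: float = 0.3         # sd of synthetic constraint scores
    geom_noise_sd: float = 0.0          # positional jitter of planted poses
    constraint_fail_fraction: float = 0.0

    def validate(self) -> "FixtureSpec":
        if abs(sum(self.outcome_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("outcome fractions must sum to 1")
        for name in ("pocket_radius", "shell_atoms", "pp_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.score_noise_sd < 0 or self.geom_noise_sd < 0:
            raise ValueError("noise levels must be non-negative")
        return self


# ---------------------------------------------------------------------------
# toy receptor
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5**0.5) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def make_toy_receptor(
    spec: FixtureSpec,
    variant: str = "T",
    base_direction: np.ndarray | None = None,
    base_o_position: np.ndarray | None = None,
    pp_centroid: np.ndarray | None = None,
) -> Receptor:
    """Spherical pseudo-atom shell with a 723 base site and a PP-Mg cluster.

    The base residue sits where `base_direction` (default: the spec's polar
    angle at azimuth zero) meets the shell, side chain pointing inward; if
    `base_o_position` is given, the grafted hydroxyl oxygen lands exactly
    there instead.  Deterministic per seed; seeds vary the shell jitter but
    never the site topology.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    radius = spec.pocket_radius
    shell = _fibonacci_sphere(spec.shell_atoms) * radius
    shell += rng.normal(0.0, 0.15, shell.shape)

    if base_o_position is not None:
        u = (np.asarray(base_direction, float)
             if base_direction is not None else base_o_position)
        u = u / np.linalg.norm(u)
        cb = base_o_position + 1.43 * u
        ca = cb + 1.5 * u
    else:
        if base_direction is None:
            theta = math.radians(spec.base_polar_angle)
            base_direction = np.array(
                [math.sin(theta), 0.0, math.cos(theta)])
        u = np.asarray(base_direction, float)
        u = u / np.linalg.norm(u)
        ca = u * radius
        cb = ca - 1.5 * u
    # clear shell atoms that would collide with the residue
    shell = shell[np.linalg.norm(shell - ca, axis=1) > 2.5]

    n_shell = len(shell)
    atomnames = [f"C{i + 1}" for i in range(n_shell)] + ["CA", "CB"]
    resnames = ["SHL"] * n_shell + ["ALA", "ALA"]
    resnums = list(range(1, n_shell + 1)) + [723, 723]
    elements = ["C"] * n_shell + ["C", "C"]
    coords = np.vstack([shell, ca, cb])

    rec = Receptor(
        serials=np.arange(1, len(coords) + 1),
        atomnames=np.array(atomnames, "U6"),
        resnames=np.array(resnames, "U4"),
        resnums=np.array(resnums),
        elements=np.array(elements, "U2"),
        coords=coords,
        pocket_center=np.zeros(3),
        pocket_radius=radius - SHELL_MARGIN,
        variant="A",
        base_resnum=723,
    )
    rec = _apply_variant(rec, variant)

    if pp_centroid is None:
        v = np.asarray(spec.pp_direction, float)
        v = v / np.linalg.norm(v)
        pp_centroid = v * (spec.pp_fraction * radius)
    template = RIGID_TEMPLATES["pp_mg"]
    rec.pp_coords = template - template.mean(axis=0) + pp_centroid
    rec._cache.clear()
    return rec


# ---------------------------------------------------------------------------
# toy cation
# ---------------------------------------------------------------------------

_ALPHA_NAMES = ["C7", "C14", "C9"]


def make_toy_cation(census: list[int]) -> tuple[CationGraph, Conformer]:
    """Star-shaped cation with the requested alpha-proton census.

    The cation center ``C8`` always has three carbon neighbors (blank,
    hydrogen-free ones pad a short census); entry i of `census` is the number
    of protons on alpha carbon i.  A rigid scaffold ``C13-C12/C15-C16``
    hangs off the second alpha carbon so anchor restraints (C16) and face
    classification at C13 work on the toy.  Returns the graph and one
    hand-built conformer.
    """
    if not census:
        raise ValueError("census must be non-empty")
    if len(census) > 3:
        raise SpeciesError("a trivalent cation center allows at most 3 "
                           "alpha carbons")
    if any(c < 0 or c > 3 for c in census):
        raise SpeciesError("each alpha carbon carries 0..3 hydrogens")

    padded = list(census) + [None] * (3 - len(census))  # None = blank carbon
    alpha_dirs = [np.array([1.0, 0.0, 0.0]),
                  np.array([-0.5, math.sqrt(3) / 2, 0.0]),
                  np.array([-0.5, -math.sqrt(3) / 2, 0.0])]

    atoms: list[Atom] = [Atom(0, "C", "C8")]
    bonds: list[tuple[int, int, int]] = []
    coords: list[np.ndarray] = [np.zeros(3)]

    def add(element: str, name: str, pos: np.ndarray, bond_to: int) -> int:
        idx = len(atoms)
        atoms.append(Atom(idx, element, name))
        coords.append(pos)
        bonds.append((min(bond_to, idx), max(bond_to, idx), 1))
        return idx

    z = np.array([0.0, 0.0, 1.0])
    alpha_ids = []
    for i, (count, e) in enumerate(zip(padded, alpha_dirs)):
        name = _ALPHA_NAMES[i] if i < len(census) else f"CB{i}"
        cname = name if count is not None else f"CX{i}"
        cid = add("C", cname, 1.5 * e, 0)
        alpha_ids.append(cid)
        if count:
            tilts = [e + 1.2 * z, e - 1.2 * z, 1.8 * e + 0.01 * z][:count]
            for k in range(count):
                u = tilts[k] / np.linalg.norm(tilts[k])
                suffix = "ABC"[k] if count > 1 else ""
                add("H", f"H{cname[1:]}{suffix}", 1.5 * e + 1.09 * u, cid)

    # anchor / face scaffold off the second alpha carbon (or the first):
    # C13 is trigonal planar in the xy-plane, so its two prochiral faces
    # point along +z and -z; the reference order (C12, C14, C15) is chosen
    # so the +z face is alpha (epimer 6a)
    host = alpha_ids[1] if len(alpha_ids) > 1 else alpha_ids[0]
    e_host = coords[host] / np.linalg.norm(coords[host])
    c13 = add("C", "C13", coords[host] + 1.5 * e_host, host)
    d14 = -e_host

    def rot_z(v: np.ndarray, deg: float) -> np.ndarray:
        a = math.radians(deg)
        return np.array([v[0] * math.cos(a) - v[1] * math.sin(a),
                         v[0] * math.sin(a) + v[1] * math.cos(a), v[2]])

    d12 = rot_z(d14, -120.0)
    d15 = rot_z(d14, 120.0)
    add("C", "C12", coords[c13] + 1.5 * d12, c13)
    c15 = add("C", "C15", coords[c13] + 1.5 * d15, c13)
    add("C", "C16", coords[c15] + 1.4 * d15, c15)

    g = CationGraph(atoms, bonds, 0, "toy").validate()
    return g, Conformer(g, np.array(coords), 0.0)


# ---------------------------------------------------------------------------
# planted poses
# ---------------------------------------------------------------------------

def _exact_allocation(fractions: dict[str, float], n: int) -> list[str]:
    """Largest-remainder partition of n poses over the planted outcomes."""
    items = sorted(fractions.items())
    raw = [(pid, frac * n) for pid, frac in items]
    counts = {pid: int(math.floor(x)) for pid, x in raw}
    remainder = n - sum(counts.values())
    by_frac = sorted(raw, key=lambda kv: (-(kv[1] - math.floor(kv[1])), kv[0]))
    for pid, _ in by_frac[:remainder]:
        counts[pid] += 1
    labels = [pid for pid, c in counts.items() for _ in range(c)]
    return labels


def _rotation_to(a: np.ndarray, b: np.ndarray, spin: float) -> Rotation:
    """Rotation taking direction a to direction b, then spinning about b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    align, _ = Rotation.align_vectors(b[None, :], a[None, :])
    return Rotation.from_rotvec(spin * b) * align


def plant_poses(
    rec: Receptor,
    g: CationGraph,
    conformer: Conformer,
    spec: FixtureSpec,
    n: int,
) -> tuple[list[Pose], list[str]]:
    """Pose set with planted truth labels and synthetic score distributions.

    Deprotonation outcomes (keys of ``spec.outcome_fractions`` matching the
    species' olefin products) orient the ligand so the planted proton sits
    2.0 A from the base hydroxyl oxygen at an ideal 180-degree abstraction
    angle; epimer outcomes ("6a"/"6b") instead place a water 2.2 A off the
    requested face of C13.  ``geom_noise_sd`` jitters the placement;
    ``score_noise_sd`` draws the synthetic constraint scores, and
    ``constraint_fail_fraction`` of poses get a failing score of 1.5.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 7)
    labels = _exact_allocation(spec.outcome_fractions, n)
    rng.shuffle(labels)

    sites = enumerate_deprotonation_sites(g)
    products = enumerate_olefin_products(g, sites)
    by_product: dict[str, DeprotonationSite] = {}
    for site, prod in products.items():
        by_product.setdefault(prod.product_id, site)

    local = conformer.coords
    center = rec.pocket_center
    epimer_mode = any(lab in ("6a", "6b") for lab in labels)
    if not epimer_mode:
        base_o = rec.base_o()
        u_in = center - base_o
        u_in = u_in / np.linalg.norm(u_in)

    c13 = g.atom_id("C13")
    refs = tuple(g.atom_id(nm) for nm in ("C12", "C14", "C15"))

    poses: list[Pose] = []
    n_fail = int(round(spec.constraint_fail_fraction * n))
    for i, label in enumerate(labels):
        spin = float(rng.uniform(0.0, 2 * np.pi))
        jitter = rng.normal(0.0, spec.geom_noise_sd, 3) \
            if spec.geom_noise_sd > 0 else np.zeros(3)
        water = None
        if label in ("6a", "6b"):
            rot = Rotation.from_quat(
                _shoemake_one(rng))
            ligand = rot.apply(local - local.mean(axis=0)) + center + jitter
            s1, s2, s3 = (ligand[r] for r in refs)
            normal = np.cross(s2 - s1, s3 - s1)
            normal = normal / np.linalg.norm(normal)
            sign = 1.0 if label == "6a" else -1.0
            o_pos = ligand[c13] + 2.2 * sign * normal
            template = RIGID_TEMPLATES["water"]
            water = template - template[0] + o_pos
        else:
            site = by_product[label]
            ch_local = local[site.hydrogen] - local[site.carbon]
            rot = _rotation_to(ch_local, -u_in, spin)
            p_h = base_o + 2.0 * u_in
            shift = p_h - rot.apply(local[site.hydrogen]) + jitter
            ligand = rot.apply(local) + shift

        score = min(0.95, abs(rng.normal(0.0, spec.score_noise_sd)))
        if i < n_fail:
            score = 1.5
        pose = Pose(
            pose_id=f"planted:{i:05d}",
            set_id="planted",
            conformer_id=0,
            quat=rot.as_quat(),
            translation=ligand.mean(axis=0),
            ligand_coords=ligand,
            water_coords=water,
            cst_scores={"carbocation": score},
            total_score=float(rng.normal(0.0, 1.0)),
            interface_energy=float(rng.normal(0.0, 1.0)),
        )
        poses.append(pose)
    return poses, labels


def _shoemake_one(rng: np.random.Generator) -> np.ndarray:
    u1, u2, u3 = rng.random(3)
    return np.array([
        math.sqrt(1 - u1) * math.sin(2 * math.pi * u2),
        math.sqrt(1 - u1) * math.cos(2 * math.pi * u2),
        math.sqrt(u1) * math.sin(2 * math.pi * u3),
        math.sqrt(u1) * math.cos(2 * math.pi * u3),
    ])


# ---------------------------------------------------------------------------
# aligned workspace for end-to-end runs
# ---------------------------------------------------------------------------

@dataclass
class Workspace:
    receptor: Receptor
    graph: CationGraph
    conformer: Conformer
    sites: list[DeprotonationSite]
    products: dict[DeprotonationSite, ProductSpec]


def make_aligned_workspace(
    spec: FixtureSpec, variant: str = "T", census: list[int] | None = None
) -> Workspace:
    """Toy receptor whose base probe sits on the planted C7-proton approach
    vector and whose PP cluster is within anchor range of C16.

    A reference placement of the toy cation (identity rotation, cation
    center on the pocket center) defines where the first C7 proton points;
    the 723 hydroxyl is grafted so its oxygen lies 2.0 A beyond that proton,
    and the PP cluster is translated so a terminal oxygen is 3.5 A from C16.
    This is the geometrically consistent stage used by the end-to-end
    experiments on synthetic data.
    """
    g, conformer = make_toy_cation(census or [2, 2, 1])
    # reference pose: identity rotation, shifted down the z-axis so the
    # reactant sits against the lower pocket wall (the catalytic machinery
    # of a terpene synthase lines the cavity wall, it does not float in the
    # middle); the alpha face of C13 then opens toward the pocket interior
    wall_clearance = 5.5
    offset = np.array([0.0, 0.0, -(spec.pocket_radius - wall_clearance)])
    local = conformer.coords + offset

    h7a = local[g.atom_id("H7A")]
    c7 = local[g.atom_id("C7")]
    u_out = h7a - c7
    u_out = u_out / np.linalg.norm(u_out)
    base_o = h7a + 2.0 * u_out

    c16 = local[g.atom_id("C16")]
    c13_pos = local[g.atom_id("C13")]
    template = RIGID_TEMPLATES["pp_mg"]
    toffsets = template - template.mean(axis=0)
    terminal_rows = [3, 5]  # OT1, OT3 in the rigid template
    water_spot = c13_pos + np.array([0.0, 0.0, 3.3])  # on the alpha face

    # deterministic construction-time grid search for the PP centroid:
    # a terminal oxygen in anchor range of C16, cluster atoms in contact
    # (not clash) range of the alpha-face water spot, no ligand clash
    ticks = np.arange(-6.0, 6.0 + 1e-9, 0.5)
    zticks = np.arange(1.0, 7.0 + 1e-9, 0.5)
    cand = np.stack(np.meshgrid(ticks, ticks, zticks, indexing="ij"),
                    axis=-1).reshape(-1, 3) + c13_pos
    best, best_obj = None, math.inf
    for point in cand:
        atoms = toffsets + point
        anchor = min(abs(np.linalg.norm(atoms[r] - c16) - 3.5)
                     for r in terminal_rows)
        d_w = np.linalg.norm(atoms - water_spot, axis=1)
        contacts = int(np.sum((d_w >= 3.2) & (d_w <= 4.5)))
        d_lig = np.linalg.norm(atoms[:, None, :] - local[None, :, :], axis=2)
        clash = float(np.sum(np.maximum(0.0, 3.0 - d_lig) ** 2))
        clash += float(np.sum(np.maximum(0.0, 3.0 - d_w) ** 2))
        obj = 4.0 * anchor - contacts + 10.0 * clash
        if obj < best_obj - 1e-12:
            best, best_obj = point, obj
    pp_centroid = best

    rec = make_toy_receptor(
        spec, variant=variant,
        base_direction=u_out, base_o_position=base_o, pp_centroid=pp_centroid,
    )
    sites = enumerate_deprotonation_sites(g)
    products = enumerate_olefin_products(g, sites)
    return Workspace(rec, g, conformer, sites, products)


# ---------------------------------------------------------------------------
# demo workspace on disk
# ---------------------------------------------------------------------------

def write_demo_workspace(outdir: str | Path, spec: FixtureSpec | None = None
                         ) -> dict[str, str]:
    """Write a complete runnable demo: receptor PDB, toy-cation SDF,
    config YAML and planted-truth JSON.  Returns the file map."""
    from . import intermediates as im

    spec = (spec or FixtureSpec()).validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ws = make_aligned_workspace(spec)
    files = {}

    receptor_path = outdir / "toy_receptor.pdb"
    ws.receptor.to_pdb(receptor_path)
    files["receptor"] = str(receptor_path)

    sdf_path = outdir / "toy_cation.sdf"
    im.write_sdf(ws.graph, ws.conformer.coords, sdf_path)
    files["species"] = str(sdf_path)

    poses, labels = plant_poses(ws.receptor, ws.graph, ws.conformer, spec, 50)
    truth_path = outdir / "planted_truth.json"
    truth_path.write_text(json.dumps(
        {"labels": labels, "n": len(labels)}, indent=2))
    files["truth"] = str(truth_path)

    config_path = outdir / "config.yaml"
    config_path.write_text(
        "experiment: a723t_depro_scan\n"
        f"receptor: {receptor_path.name}\n"
        "variant: T\n"
        "species: toy\n"
        "docking:\n"
        f"  seed: {spec.seed}\n"
        "  n_poses_per_set: 400\n"
    )
    files["config"] = str(config_path)
    return files
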