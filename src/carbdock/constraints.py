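"""Flat-bottom geometric restraints encoding the mechanistic hypotheses.

Each catalytic hypothesis (deprotonation of a particular alpha proton by the
base hydroxyl; water addition to one prochiral face of the 13-yl cation;
proximity of C7 to the wild-type residue 723) is encoded as a named
``ConstraintSet`` of flat-bottom restraints.  A flat-bottom penalty is zero
inside ``[lower, upper]`` and grows as ``((x - nearest_edge)/sd)^2 * weight``
outside, so a restraint violated by exactly one softness unit scores 1.0 —
which is why the pose filter requires every per-ligand constraint score to be
*strictly below one*.

Geometries are passed around as ``{body: (coords, {atom_name: row})}``
dictionaries with bodies named ``receptor``, ``carbocation``, ``water`` and
``pp_mg``; restraint members are ``(body, atom_name)`` selectors.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .intermediates import (
    CationGraph,
    DeprotonationSite,
    ProductSpec,
    enumerate_olefin_products,
)

__all__ = [
    "Selector",
    "Geometry",
    "FlatBottomRestraint",
    "ConstraintSet",
    "SelectorError",
    "build_deprotonation_sets",
    "build_water_constraints",
    "build_wt_mechanism_constraints",
    "ligand_constraint_score",
    "write_constraint_text",
    "read_constraint_text",
    "sets_to_json",
    "sets_from_json",
]

Selector = tuple[str, str]  # (body, atom name)
Geometry = dict[str, tuple[np.ndarray, dict[str, int]]]

# default restraint geometry (angstrom / degrees); proton-transfer and
# hydrogen-bond norms, overridable by callers
DEPRO_DIST = (1.6, 2.6, 0.3)        # base O ... alpha H
DEPRO_ANGLE = (120.0, 180.0, 20.0)  # C-H...O
ANCHOR_DIST = (2.5, 4.5, 0.5)       # vinyl methylene ... pyrophosphate end
WATER_DIST_REACTIVE = (2.6, 3.4, 0.3)   # water O ... C13, attack distance
WATER_DIST_LOOSE_UPPER = 5.0            # loosened upper bound (non-reactive)
WATER_FACE_ANGLE = (0.0, 35.0, 10.0)    # approach vs face normal
MECH_DIST = (3.5, 5.5, 0.5)         # C7 ... residue-723 side-chain tip


class SelectorError(KeyError):
    pass


def resolve(geom: Geometry, sel: Selector) -> np.ndarray:
    body, name = sel
    if body not in geom:
        raise SelectorError(f"geometry has no body {body!r} (needed for {name!r})")
    coords, index = geom[body]
    if name not in index:
        raise SelectorError(f"body {body!r} has no atom named {name!r}")
    return coords[index[name]]


@dataclass(frozen=True)
class FlatBottomRestraint:
    """Zero inside [lower, upper]; quadratic in units of `sd` outside.

    Kinds: ``distance`` (2 members, angstrom), ``angle`` (3 members, degrees,
    vertex is the middle member) and ``face_angle`` (5 members: trigonal
    center, three reference substituents, probe; the measured value is the
    angle in degrees between the face normal — signed by ``face_sign`` —
    and the center-to-probe vector).
    """

    kind: str
    members: tuple[Selector, ...]
    lower: float
    upper: float
    sd: float
    weight: float = 1.0
    face_sign: int = 1

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower must be <= upper")
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        n_expected = {"distance": 2, "angle": 3, "face_angle": 5}[self.kind]
        if len(self.members) != n_expected:
            raise ValueError(
                f"{self.kind} restraint needs {n_expected} members, "
                f"got {len(self.members)}"
            )

    def measure(self, geom: Geometry) -> float:
        pts = [resolve(geom, sel) for sel in self.members]
        if self.kind == "distance":
            return float(np.linalg.norm(pts[0] - pts[1]))
        if self.kind == "angle":
            v1 = pts[0] - pts[1]
            v2 = pts[2] - pts[1]
            cosine = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            return math.degrees(math.acos(np.clip(cosine, -1.0, 1.0)))
        # face_angle
        center, s1, s2, s3, probe = pts
        normal = self.face_sign * np.cross(s2 - s1, s3 - s1)
        v = probe - center
        cosine = np.dot(normal, v) / (np.linalg.norm(normal) * np.linalg.norm(v))
        return math.degrees(math.acos(np.clip(cosine, -1.0, 1.0)))

    def penalty_of(self, value: float) -> float:
        if value < self.lower:
            excess = self.lower - value
        elif value > self.upper:
            excess = value - self.upper
        else:
            return 0.0
        return self.weight * (excess / self.sd) ** 2

    def penalty(self, geom: Geometry) -> float:
        return self.penalty_of(self.measure(geom))

    @property
    def bodies(self) -> frozenset[str]:
        return frozenset(body for body, _ in self.members)


@dataclass
class ConstraintSet:
    """A named restraint collection tied to one product hypothesis."""

    set_id: str
    restraints: list[FlatBottomRestraint]
    product_hypothesis: ProductSpec | None = None
    anchor: str | None = None
    water_mode: str = "none"  # none | reactive_6a | reactive_6b | loose_6a | loose_6b

    def with_restraints(self, extra: Iterable[FlatBottomRestraint],
                        water_mode: str | None = None) -> "ConstraintSet":
        out = ConstraintSet(
            self.set_id, list(self.restraints) + list(extra),
            self.product_hypothesis, self.anchor,
            water_mode if water_mode is not None else self.water_mode,
        )
        return out


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_deprotonation_sets(
    g: CationGraph,
    sites: list[DeprotonationSite],
    base: dict[str, Selector],
    anchors: list[tuple[str, Selector]],
    anchor_atom: str = "C16",
) -> list[ConstraintSet]:
    """One constraint set per (alpha proton, pyrophosphate anchor) pair.

    Each set carries three restraints: base-O-to-proton distance, C-H...O
    abstraction angle, and the vinyl-methylene-to-pyrophosphate-end anchor
    distance that keeps the reactant registered against the ionized ester
    bond.  Five alpha protons and two pyrophosphate ends give the ten sets
    of the deprotonation scan.
    """
    if not sites:
        raise ValueError("no deprotonation sites supplied")
    for key in ("O", "H"):
        if key not in base:
            raise SelectorError(f"base hydroxyl selector lacks {key!r} atom")
    products = enumerate_olefin_products(g, sites)
    out: list[ConstraintSet] = []
    for site in sites:
        c_name = g.name(site.carbon)
        h_name = g.name(site.hydrogen)
        for anchor_label, anchor_sel in anchors:
            restraints = [
                FlatBottomRestraint(
                    "distance", (base["O"], ("carbocation", h_name)),
                    *DEPRO_DIST),
                FlatBottomRestraint(
                    "angle",
                    (("carbocation", c_name), ("carbocation", h_name), base["O"]),
                    *DEPRO_ANGLE),
                FlatBottomRestraint(
                    "distance", (("carbocation", anchor_atom), anchor_sel),
                    *ANCHOR_DIST),
            ]
            out.append(ConstraintSet(
                set_id=f"depro_{c_name}_{h_name}_anchor_{anchor_label}",
                restraints=restraints,
                product_hypothesis=products[site],
                anchor=anchor_label,
            ))
    return out


def build_water_constraints(
    epimer: str,
    reactive: bool,
    center: str = "C13",
    refs: tuple[str, str, str] = ("C12", "C14", "C15"),
) -> list[FlatBottomRestraint]:
    """Water-placement restraints for one prochiral face of the 13-yl carbon.

    Reactive mode (rearranged cation B, water is the nucleophile): O(water)
    within attack distance [2.6, 3.4] A of C13 and approaching within 35
    degrees of the face normal of the requested epimer's face.  Loose mode
    (initial cation A, water is a spectator): same face constraint but the
    upper distance bound relaxed to 5.0 A.
    """
    if epimer not in ("6a", "6b"):
        raise ValueError(f"unknown epimer {epimer!r}")
    lower, upper, sd = WATER_DIST_REACTIVE
    if not reactive:
        upper = WATER_DIST_LOOSE_UPPER
    face_sign = 1 if epimer == "6a" else -1
    c = ("carbocation", center)
    return [
        FlatBottomRestraint("distance", (("water", "O"), c), lower, upper, sd),
        FlatBottomRestraint(
            "face_angle",
            (c, ("carbocation", refs[0]), ("carbocation", refs[1]),
             ("carbocation", refs[2]), ("water", "O")),
            *WATER_FACE_ANGLE, face_sign=face_sign),
    ]


def build_wt_mechanism_constraints(
    species: str,
    tip: Selector = ("receptor", "723.TIP"),
) -> list[FlatBottomRestraint]:
    """C7-to-residue-723 proximity restraint for the wild-type plausibility
    check; the same ligand atom and bounds apply to both cations A and B."""
    if species not in ("A", "B"):
        raise ValueError(f"unknown species {species!r}")
    return [
        FlatBottomRestraint("distance", (("carbocation", "C7"), tip), *MECH_DIST),
    ]


def ligand_constraint_score(
    geom: Geometry, cset: ConstraintSet, body: str
) -> float:
    """Summed penalty of all restraints that involve `body`.

    A pose satisfies a constraint set when this score is strictly below 1.0
    for every ligand body independently.
    """
    return sum(
        r.penalty(geom) for r in cset.restraints if body in r.bodies
    )


# ---------------------------------------------------------------------------
# text / JSON serialization
# ---------------------------------------------------------------------------

def _restraint_line(r: FlatBottomRestraint) -> str:
    members = " ".join(f"{b}:{n}" for b, n in r.members)
    line = f"{r.kind} {members} {r.lower:g} {r.upper:g} {r.sd:g} {r.weight:g}"
    if r.kind == "face_angle":
        line += f" {r.face_sign:+d}"
    return line


def _parse_restraint(line: str) -> FlatBottomRestraint:
    parts = line.split()
    kind = parts[0]
    n_members = {"distance": 2, "angle": 3, "face_angle": 5}[kind]
    members = tuple(tuple(tok.split(":", 1)) for tok in parts[1:1 + n_members])
    nums = parts[1 + n_members:]
    lower, upper, sd, weight = map(float, nums[:4])
    face_sign = int(nums[4]) if kind == "face_angle" else 1
    return FlatBottomRestraint(kind, members, lower, upper, sd, weight, face_sign)


def write_constraint_text(sets: list[ConstraintSet], path: str | Path) -> None:
    lines = []
    for cs in sets:
        pid = cs.product_hypothesis.product_id if cs.product_hypothesis else "-"
        lines.append(f"# set {cs.set_id} product={pid} "
                     f"anchor={cs.anchor or '-'} water_mode={cs.water_mode}")
        lines.extend(_restraint_line(r) for r in cs.restraints)
    Path(path).write_text("\n".join(lines) + "\n")


def read_constraint_text(path: str | Path) -> list[ConstraintSet]:
    sets: list[ConstraintSet] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("# set "):
            tokens = line[6:].split()
            meta = dict(tok.split("=", 1) for tok in tokens[1:])
            sets.append(ConstraintSet(
                set_id=tokens[0], restraints=[],
                anchor=None if meta.get("anchor") == "-" else meta.get("anchor"),
                water_mode=meta.get("water_mode", "none"),
            ))
        else:
            sets[-1].restraints.append(_parse_restraint(line))
    return sets


def sets_to_json(sets: list[ConstraintSet], path: str | Path | None = None) -> str:
    payload = []
    for cs in sets:
        payload.append({
            "set_id": cs.set_id,
            "anchor": cs.anchor,
            "water_mode": cs.water_mode,
            "product": cs.product_hypothesis.product_id
            if cs.product_hypothesis else None,
            "restraints": [
                {"kind": r.kind, "members": [list(m) for m in r.members],
                 "lower": r.lower, "upper": r.upper, "sd": r.sd,
                 "weight": r.weight, "face_sign": r.face_sign}
                for r in cs.restraints
            ],
        })
    text = json.dumps(payload, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def sets_from_json(path: str | Path) -> list[ConstraintSet]:
    payload = json.loads(Path(path).read_text())
    sets = []
    for entry in payload:
        restraints = [
            FlatBottomRestraint(
                d["kind"], tuple(tuple(m) for m in d["members"]),
                d["lower"], d["upper"], d["sd"], d["weight"], d["face_sign"])
            for d in entry["restraints"]
        ]
        sets.append(ConstraintSet(
            entry["set_id"], restraints, None,
            entry["anchor"], entry["water_mode"]))
    return sets
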