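"""Assign surviving poses a predicted product and tally the outcomes.

Classification is by *realized geometry*, not by the hypothesis of the
constraint set that generated a pose: the predicted olefin is the one formed
by abstracting the alpha proton that actually sits nearest the base hydroxyl
oxygen, gated at O...H <= 2.8 A and C-H...O >= 100 degrees (deliberately
looser than the docking restraint flat bottom, so near-miss poses are still
attributed).  Poses failing the gate are "unassigned".  The generating
hypothesis is kept alongside so the agreement rate between the two views can
be reported.

For water-carrying poses two further taxonomies apply: the nearest labeled
pyrophosphate oxygen (bridging / terminal / none within a cutoff) and, for
the trigonal 13-yl cation, the prochiral face occupied by the water, which
maps to the abietaenol epimer (alpha -> 6a, beta -> 6b).
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constraints import SelectorError
from .docking import Pose, Receptor
from .intermediates import (
    CationGraph,
    DeprotonationSite,
    ProductSpec,
    assign_addition_face,
)

__all__ = [
    "OutcomeReport",
    "classify_pose",
    "classify_water_location",
    "classify_epimer",
    "tally",
    "GATE_DISTANCE",
    "GATE_ANGLE",
]

GATE_DISTANCE = 2.8   # A, max O...H for attribution
GATE_ANGLE = 100.0    # degrees, min C-H...O
WATER_CUTOFF = 3.5    # A, max water-O to labeled PP oxygen


def classify_pose(
    pose: Pose,
    rec: Receptor,
    g: CationGraph,
    sites: list[DeprotonationSite],
    products: dict[DeprotonationSite, ProductSpec],
    gate_distance: float = GATE_DISTANCE,
    gate_angle: float = GATE_ANGLE,
) -> str:
    """Product formed by abstracting the proton nearest the base hydroxyl."""
    base_o = rec.base_o()
    coords = pose.ligand_coords
    best_site, best_d = None, math.inf
    for site in sites:
        d = float(np.linalg.norm(coords[site.hydrogen] - base_o))
        if d < best_d:
            best_site, best_d = site, d
    if best_site is None or best_d > gate_distance:
        return "unassigned"
    # angle at the hydrogen between its bonds to C and to the base O
    ch = coords[best_site.carbon] - coords[best_site.hydrogen]
    ho = base_o - coords[best_site.hydrogen]
    cosine = np.dot(ch, ho) / (np.linalg.norm(ch) * np.linalg.norm(ho))
    angle = math.degrees(math.acos(np.clip(cosine, -1.0, 1.0)))
    if angle < gate_angle:
        return "unassigned"
    return products[best_site].product_id


def classify_water_location(
    pose: Pose, rec: Receptor, cutoff: float = WATER_CUTOFF
) -> str:
    """Label of the nearest labeled pyrophosphate oxygen, or "none"."""
    if pose.water_coords is None:
        raise SelectorError(f"pose {pose.pose_id} carries no water")
    if rec.pp_coords is None:
        raise SelectorError("receptor has no placed pyrophosphate cluster")
    water_o = pose.water_coords[0]
    idx = rec.pp_index()
    labels = rec.pp_oxygen_labels()
    best_label, best_d = "none", math.inf
    for name, label in labels.items():
        d = float(np.linalg.norm(rec.pp_coords[idx[name]] - water_o))
        if d < best_d:
            best_label, best_d = label, d
    return best_label if best_d <= cutoff else "none"


def classify_epimer(
    pose: Pose,
    g: CationGraph,
    center: str = "C13",
    refs: tuple[str, str, str] = ("C12", "C14", "C15"),
) -> str:
    """Abietaenol epimer from the face of C13 occupied by the water oxygen."""
    if pose.water_coords is None:
        raise SelectorError(f"pose {pose.pose_id} carries no water")
    ref_ids = tuple(g.atom_id(n) for n in refs)
    label = assign_addition_face(
        pose.ligand_coords, g.atom_id(center), ref_ids, pose.water_coords[0]
    )
    return label.epimer


@dataclass
class OutcomeReport:
    """Per-product pose tallies, rendered in the ``k/n`` style."""

    counts: dict[str, int]
    denominator: int
    per_set: dict[str, dict[str, int]] = field(default_factory=dict)
    water_locations: dict[str, int] = field(default_factory=dict)
    agreement_rate: float | None = None  # geometry vs generating hypothesis

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.denominator:
            raise ValueError("tally counts do not sum to the denominator")

    @property
    def majority(self) -> str | None:
        if not self.counts:
            return None
        top, top_n = max(self.counts.items(), key=lambda kv: (kv[1], kv[0]))
        return top if top_n * 2 > self.denominator else None

    def fraction(self, product_id: str) -> str:
        return f"{self.counts.get(product_id, 0)}/{self.denominator}"

    def summary(self) -> str:
        lines = [f"passing poses: {self.denominator}"]
        for pid in sorted(self.counts, key=lambda k: (-self.counts[k], k)):
            mark = "  <- majority" if pid == self.majority else ""
            lines.append(f"  {pid}: {self.fraction(pid)}{mark}")
        if self.water_locations:
            lines.append("water nearest PP oxygen: " + ", ".join(
                f"{k}={v}" for k, v in sorted(self.water_locations.items())))
        if self.agreement_rate is not None:
            lines.append(
                f"geometry vs constraint-set hypothesis agreement: "
                f"{self.agreement_rate:.2f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "counts": dict(sorted(self.counts.items())),
            "denominator": self.denominator,
            "fractions": {k: self.fraction(k) for k in sorted(self.counts)},
            "majority": self.majority,
            "per_set": {k: dict(sorted(v.items()))
                        for k, v in sorted(self.per_set.items())},
            "water_locations": dict(sorted(self.water_locations.items())),
            "agreement_rate": self.agreement_rate,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def tally(
    poses: list[Pose],
    labels: list[str],
    water_labels: list[str] | None = None,
    hypotheses: list[str | None] | None = None,
) -> OutcomeReport:
    """Histogram the per-pose labels into an OutcomeReport.

    Counts are grouped per originating constraint set; when the generating
    hypotheses are supplied the geometry-vs-hypothesis agreement rate is
    computed over assigned poses.
    """
    if len(poses) != len(labels):
        raise ValueError("one label per pose required")
    counts = Counter(labels)
    per_set: dict[str, Counter] = {}
    for pose, label in zip(poses, labels):
        per_set.setdefault(pose.set_id, Counter())[label] += 1
    agreement = None
    if hypotheses is not None:
        pairs = [(lab, hyp) for lab, hyp in zip(labels, hypotheses)
                 if lab != "unassigned" and hyp is not None]
        if pairs:
            agreement = sum(lab == hyp for lab, hyp in pairs) / len(pairs)
    water_hist = Counter(water_labels) if water_labels is not None else Counter()
    return OutcomeReport(
        counts=dict(counts),
        denominator=len(poses),
        per_set={k: dict(v) for k, v in per_set.items()},
        water_locations=dict(water_hist),
        agreement_rate=agreement,
    )
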