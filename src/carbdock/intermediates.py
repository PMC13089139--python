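"""Molecular-graph models of the reaction species and their possible outcomes.

The central objects are the two tricyclic diterpene carbocation intermediates
of the abietane/(iso)pimarane branch point:

* species ``A`` — the isopimara-15-en-8-yl cation (cation at C8, vinyl at
  C13), the first cyclic cation formed after ionization of copalyl
  pyrophosphate.  Deprotonation of A at C7, C14 or C9 yields the olefins
  isopimara-7,15-diene (``7``), isopimara-8(14),15-diene (``8``) and
  isopimara-8,15-diene (``10``) respectively.
* species ``B`` — the rearranged abieta-8(14)-en-13-yl cation (cation at C13,
  8(14) olefin, isopropyl at C13), which is quenched by water addition to
  give the abietaenol C13 epimers ``6a`` (alpha face) and ``6b`` (beta face).

Both skeletons are shipped as built-in bond tables using standard diterpene
numbering: rings A (C1-C2-C3-C4-C5-C10), B (C5-C6-C7-C8-C9-C10) and
C (C8-C9-C11-C12-C13-C14); gem-dimethyl C18/C19 on C4, angular methyl C20 on
C10; in A the C13 substituents are the methyl C17 and vinyl C15=C16, in B the
isopropyl C15(H)(C16)(C17).  Hydrogens are explicit everywhere — the
deprotonation enumeration needs them.

Two rigid auxiliary species are registered as well: ``water`` and ``pp_mg``,
a seven-point pyrophosphate-magnesium cluster with a labeled bridging oxygen
(the former ester oxygen) and three terminal oxygens.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Atom",
    "CationGraph",
    "DeprotonationSite",
    "ProductSpec",
    "FaceLabel",
    "DegenerateGeometryError",
    "SpeciesError",
    "PRODUCTS",
    "COPLANARITY_TOL",
    "load_species",
    "enumerate_deprotonation_sites",
    "enumerate_olefin_products",
    "assign_addition_face",
    "registry_to_json",
    "to_rdkit",
    "write_sdf",
    "write_xyz",
]

#: coplanarity tolerance for face assignment, in cubic angstroms.  A probe
#: whose signed parallelepiped volume with the substituent plane falls below
#: this is rejected as degenerate; real poses never get close.
COPLANARITY_TOL = 1e-6

#: product registry: identifier -> human-readable name.
PRODUCTS = {
    "7": "isopimara-7,15-diene",
    "8": "isopimara-8(14),15-diene (sandaracopimaradiene)",
    "10": "isopimara-8,15-diene",
    "6a": "abieta-8(14)-en-13alpha-ol",
    "6b": "abieta-8(14)-en-13beta-ol",
}


class SpeciesError(ValueError):
    """Raised for unknown species keys or chemically invalid graphs."""


class DegenerateGeometryError(ValueError):
    """Raised when a face assignment is attempted on (near-)coplanar geometry."""


@dataclass(frozen=True)
class Atom:
    atom_id: int
    element: str
    name: str


@dataclass(frozen=True)
class DeprotonationSite:
    """An alpha C-H pair: abstraction of `hydrogen` quenches the cation."""

    carbon: int
    hydrogen: int


@dataclass(frozen=True)
class ProductSpec:
    """A reaction outcome: the new bond formed when the cation is quenched."""

    product_id: str
    new_bond: tuple[int, int]
    origin: str  # "deprotonation" | "water_addition"

    @property
    def name(self) -> str:
        return PRODUCTS.get(self.product_id, self.product_id)


@dataclass(frozen=True)
class FaceLabel:
    """One prochiral face of a trigonal carbon, mapped to its epimer."""

    face: str  # "alpha" | "beta"
    epimer: str  # "6a" | "6b"
    reference_substituents: tuple[int, int, int]


@dataclass
class CationGraph:
    """Explicit-hydrogen molecular graph with an optional cationic carbon.

    ``atoms`` are 0-based and names are unique; ``bonds`` are (i, j, order)
    with i < j.  ``cation_center`` is None for neutral rigid species.
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int, int]]
    cation_center: int | None
    label: str
    _adj: dict[int, list[tuple[int, int]]] = field(default_factory=dict, repr=False)
    _by_name: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._adj = {a.atom_id: [] for a in self.atoms}
        for i, j, order in self.bonds:
            self._adj[i].append((j, order))
            self._adj[j].append((i, order))
        self._by_name = {a.name: a.atom_id for a in self.atoms}
        if len(self._by_name) != len(self.atoms):
            raise SpeciesError(f"{self.label}: atom names are not unique")

    # -- accessors ---------------------------------------------------------
    def neighbors(self, atom_id: int) -> list[tuple[int, int]]:
        return self._adj[atom_id]

    def element(self, atom_id: int) -> str:
        return self.atoms[atom_id].element

    def name(self, atom_id: int) -> str:
        return self.atoms[atom_id].name

    def atom_id(self, name: str) -> int:
        try:
            return self._by_name[name]
        except KeyError:
            raise SpeciesError(f"{self.label}: no atom named {name!r}") from None

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def heavy_ids(self) -> list[int]:
        return [a.atom_id for a in self.atoms if a.element != "H"]

    # -- validation --------------------------------------------------------
    def validate(self) -> "CationGraph":
        if not self.atoms:
            raise SpeciesError(f"{self.label}: empty graph")
        # connectivity
        seen = {self.atoms[0].atom_id}
        queue = deque(seen)
        while queue:
            i = queue.popleft()
            for j, _ in self._adj[i]:
                if j not in seen:
                    seen.add(j)
                    queue.append(j)
        if len(seen) != len(self.atoms):
            raise SpeciesError(f"{self.label}: graph is disconnected")
        # every hydrogen has exactly one bond
        for a in self.atoms:
            if a.element == "H" and len(self._adj[a.atom_id]) != 1:
                raise SpeciesError(
                    f"{self.label}: hydrogen {a.name} has "
                    f"{len(self._adj[a.atom_id])} bonds (expected 1)"
                )
        # the cation center is a trivalent carbon (bond orders sum to 3)
        if self.cation_center is not None:
            c = self.cation_center
            if self.element(c) != "C":
                raise SpeciesError(f"{self.label}: cation center is not carbon")
            valence = sum(order for _, order in self._adj[c])
            if valence != 3:
                raise SpeciesError(
                    f"{self.label}: cation center {self.name(c)} has bond-order "
                    f"sum {valence}, expected 3"
                )
        return self


# ---------------------------------------------------------------------------
# built-in species registry
# ---------------------------------------------------------------------------

_CORE_BONDS = [
    ("C1", "C2"), ("C2", "C3"), ("C3", "C4"), ("C4", "C5"), ("C5", "C10"),
    ("C10", "C1"), ("C5", "C6"), ("C6", "C7"), ("C7", "C8"), ("C8", "C9"),
    ("C9", "C10"), ("C9", "C11"), ("C11", "C12"), ("C12", "C13"),
    ("C13", "C14"), ("C4", "C18"), ("C4", "C19"), ("C10", "C20"),
]

# species A: isopimara-15-en-8-yl cation — cation at C8, vinyl C15=C16 and
# methyl C17 on C13
_A_BONDS = _CORE_BONDS + [
    ("C14", "C8", 1), ("C13", "C15", 1), ("C15", "C16", 2), ("C13", "C17", 1),
]
_A_H = {
    "C1": 2, "C2": 2, "C3": 2, "C5": 1, "C6": 2, "C7": 2, "C9": 1,
    "C11": 2, "C12": 2, "C14": 2, "C15": 1, "C16": 2,
    "C17": 3, "C18": 3, "C19": 3, "C20": 3,
}

# species B: abieta-8(14)-en-13-yl cation — cation at C13, C8=C14 olefin,
# isopropyl C15(C16)(C17) on C13
_B_BONDS = _CORE_BONDS + [
    ("C14", "C8", 2), ("C13", "C15", 1), ("C15", "C16", 1), ("C15", "C17", 1),
]
_B_H = {
    "C1": 2, "C2": 2, "C3": 2, "C5": 1, "C6": 2, "C7": 2, "C9": 1,
    "C11": 2, "C12": 2, "C14": 1, "C15": 1, "C16": 3,
    "C17": 3, "C18": 3, "C19": 3, "C20": 3,
}


def _element_of(name: str) -> str:
    if name.startswith("MG"):
        return "Mg"
    return name[0]


def build_graph(
    label: str,
    heavy_names: list[str],
    bonds: list[tuple],
    h_counts: dict[str, int],
    cation_name: str | None,
) -> CationGraph:
    """Assemble an explicit-hydrogen CationGraph from a heavy-atom bond table.

    Hydrogens are appended after the heavy atoms, named ``H<carbon#><A/B/C>``
    (e.g. the two protons on C7 are H7A and H7B).
    """
    atoms = [Atom(i, _element_of(n), n) for i, n in enumerate(heavy_names)]
    index = {n: i for i, n in enumerate(heavy_names)}
    edge_list: list[tuple[int, int, int]] = []
    for bond in bonds:
        a, b = bond[0], bond[1]
        order = bond[2] if len(bond) > 2 else 1
        i, j = index[a], index[b]
        edge_list.append((min(i, j), max(i, j), order))
    next_id = len(atoms)
    for cname, count in h_counts.items():
        if count > 3:
            raise SpeciesError(f"{label}: {cname} cannot carry {count} hydrogens")
        for k in range(count):
            suffix = "ABC"[k] if count > 1 else ""
            atoms.append(Atom(next_id, "H", f"H{cname[1:]}{suffix}"))
            edge_list.append((index[cname], next_id, 1))
            next_id += 1
    center = index[cation_name] if cation_name is not None else None
    return CationGraph(atoms, edge_list, center, label).validate()


def _species_A() -> CationGraph:
    names = [f"C{i}" for i in range(1, 21)]
    return build_graph("A", names, _A_BONDS, _A_H, "C8")


def _species_B() -> CationGraph:
    names = [f"C{i}" for i in range(1, 21)]
    return build_graph("B", names, _B_BONDS, _B_H, "C13")


def _water() -> CationGraph:
    atoms = [Atom(0, "O", "O"), Atom(1, "H", "H1"), Atom(2, "H", "H2")]
    return CationGraph(atoms, [(0, 1, 1), (0, 2, 1)], None, "water").validate()


def _pp_mg() -> CationGraph:
    """Rigid 7-point pyrophosphate-magnesium cluster.

    O_BR is the bridging oxygen (the former ester oxygen of the prenyl
    diphosphate); OT1..OT3 are terminal phosphate oxygens; MG coordinates one
    terminal oxygen.  Geometry is idealized, not a real Mg coordination shell.
    """
    names = ["P1", "P2", "O_BR", "OT1", "OT2", "OT3", "MG1"]
    atoms = [Atom(i, _element_of(n) if not n.startswith("O") else "O", n)
             for i, n in enumerate(names)]
    atoms[6] = Atom(6, "Mg", "MG1")
    bonds = [(0, 2, 1), (1, 2, 1), (0, 3, 1), (0, 4, 1), (1, 5, 1), (4, 6, 1)]
    return CationGraph(atoms, bonds, None, "pp_mg").validate()


#: fixed template coordinates (angstrom) for the rigid species.
RIGID_TEMPLATES: dict[str, np.ndarray] = {
    "water": np.array([
        [0.000, 0.000, 0.000],     # O
        [0.9572, 0.000, 0.000],    # H1
        [-0.2400, 0.9266, 0.000],  # H2
    ]),
    "pp_mg": np.array([
        [0.00, 0.00, 0.00],    # P1
        [2.90, 0.00, 0.00],    # P2
        [1.45, 0.95, 0.00],    # O_BR (bridging)
        [-1.20, -0.90, 0.00],  # OT1 (terminal, ester-oxygen end)
        [-0.40, 0.80, 1.20],   # OT2 (terminal)
        [4.10, -0.90, 0.00],   # OT3 (terminal, distal end)
        [0.10, 2.40, 1.40],    # MG1
    ]),
}

_REGISTRY = {"A": _species_A, "B": _species_B, "water": _water, "pp_mg": _pp_mg}

#: deprotonation product map: alpha carbon -> product.  The toy cation
#: reuses the isopimarenyl map so its alpha carbons C7/C14/C9 land on the
#: same product registry.
OLEFIN_MAP = {
    "A": {"C7": "7", "C14": "8", "C9": "10"},
    "toy": {"C7": "7", "C14": "8", "C9": "10"},
}


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def load_species(
    name_or_file: str | Path,
    *,
    charge: int = 1,
    add_hydrogens: bool = False,
) -> CationGraph:
    """Return a validated species graph from the registry or an SDF/XYZ file.

    Registry keys: ``A``, ``B``, ``water``, ``pp_mg``.  Files are parsed with
    RDKit; the cation center is the (unique) positively charged carbon, or,
    failing a formal charge, the unique carbon whose bond orders sum to 3.
    ``add_hydrogens`` adds explicit hydrogens only when the input has none.
    """
    key = str(name_or_file)
    if key in _REGISTRY:
        return _REGISTRY[key]()
    path = Path(name_or_file)
    if not path.exists():
        raise SpeciesError(f"unknown species key or missing file: {name_or_file!r}")
    from rdkit import Chem

    suffix = path.suffix.lower()
    if suffix in (".sdf", ".mol"):
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        mol = next(iter(supplier), None)
        if mol is None:
            raise SpeciesError(f"could not parse {path}")
    elif suffix == ".xyz":
        from rdkit.Chem import rdDetermineBonds

        mol = Chem.MolFromXYZFile(str(path))
        if mol is None:
            raise SpeciesError(f"could not parse {path}")
        rdDetermineBonds.DetermineConnectivity(mol, charge=charge)
    else:
        raise SpeciesError(f"unsupported species file type: {suffix}")
    if add_hydrogens and not any(a.GetAtomicNum() == 1 for a in mol.GetAtoms()):
        mol = Chem.AddHs(mol)
    return from_rdkit(mol, label=path.stem)


def from_rdkit(mol, label: str = "species") -> CationGraph:
    """Convert an RDKit Mol (explicit H) to a validated CationGraph."""
    atoms = []
    counts: dict[str, int] = {}
    for a in mol.GetAtoms():
        sym = a.GetSymbol()
        counts[sym] = counts.get(sym, 0) + 1
        atoms.append(Atom(a.GetIdx(), sym, f"{sym}{counts[sym]}"))
    bonds = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        bonds.append((min(i, j), max(i, j), int(b.GetBondTypeAsDouble())))
    center = None
    charged = [a.GetIdx() for a in mol.GetAtoms()
               if a.GetFormalCharge() > 0 and a.GetSymbol() == "C"]
    if charged:
        center = charged[0]
    else:
        adj: dict[int, int] = {a.atom_id: 0 for a in atoms}
        for i, j, order in bonds:
            adj[i] += order
            adj[j] += order
        trivalent = [a.atom_id for a in atoms
                     if a.element == "C" and adj[a.atom_id] == 3]
        if len(trivalent) == 1:
            center = trivalent[0]
    return CationGraph(atoms, bonds, center, label).validate()


def to_rdkit(g: CationGraph, coords: np.ndarray | None = None):
    """Build an RDKit RWMol (with conformer if coords given) from a graph."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    mol = Chem.RWMol()
    for a in g.atoms:
        atom = Chem.Atom(a.element)
        if a.atom_id == g.cation_center:
            atom.SetFormalCharge(1)
        atom.SetNoImplicit(True)
        mol.AddAtom(atom)
    order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                 3: Chem.BondType.TRIPLE}
    for i, j, order in g.bonds:
        mol.AddBond(i, j, order_map[order])
    Chem.SanitizeMol(mol)
    if coords is not None:
        conf = Chem.Conformer(g.n_atoms)
        for a in g.atoms:
            x, y, z = map(float, coords[a.atom_id])
            conf.SetAtomPosition(a.atom_id, Point3D(x, y, z))
        mol.AddConformer(conf, assignId=True)
    return mol


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def enumerate_deprotonation_sites(g: CationGraph) -> list[DeprotonationSite]:
    """All alpha C-H pairs flanking the cation center.

    Deterministic order: sorted by alpha-carbon name, then hydrogen name
    (atom id as the final tie break), so the ordering is invariant to atom
    input order.
    For species A this yields five sites: two protons each on C7 and C14 and
    one on C9.
    """
    if g.cation_center is None:
        raise SpeciesError(f"{g.label}: species has no cation center")
    sites = []
    for c, _ in g.neighbors(g.cation_center):
        if g.element(c) != "C":
            continue
        for h, _ in g.neighbors(c):
            if g.element(h) == "H":
                sites.append(DeprotonationSite(c, h))
    return sorted(sites, key=lambda s: (g.name(s.carbon), g.name(s.hydrogen),
                                        s.hydrogen))


def enumerate_olefin_products(
    g: CationGraph, sites: list[DeprotonationSite] | None = None
) -> dict[DeprotonationSite, ProductSpec]:
    """Map each deprotonation site to the olefin it would form.

    Sites on the same alpha carbon collapse onto one product (the same
    C=C bond forms regardless of which geminal proton leaves).  Built-in
    species use the product registry (A: C7 -> 7, C14 -> 8, C9 -> 10);
    anonymous species get synthesized ids ``olefin_<carbon name>``.
    """
    if sites is None:
        sites = enumerate_deprotonation_sites(g)
    name_map = OLEFIN_MAP.get(g.label, {})
    out: dict[DeprotonationSite, ProductSpec] = {}
    cache: dict[int, ProductSpec] = {}
    for site in sites:
        if site.carbon not in cache:
            cname = g.name(site.carbon)
            pid = name_map.get(cname, f"olefin_{cname}")
            cache[site.carbon] = ProductSpec(
                pid, (g.cation_center, site.carbon), "deprotonation"
            )
        out[site] = cache[site.carbon]
    return out


# ---------------------------------------------------------------------------
# prochiral face assignment
# ---------------------------------------------------------------------------

#: face -> epimer map for the trigonal C13 of the abietenyl cation.
FACE_EPIMERS = {"alpha": "6a", "beta": "6b"}


def assign_addition_face(
    coords: np.ndarray,
    center: int,
    reference_substituents: tuple[int, int, int],
    probe: np.ndarray,
    tol: float = COPLANARITY_TOL,
) -> FaceLabel:
    """Which prochiral face of a trigonal carbon does `probe` approach?

    The face is the sign of the scalar triple product
    ``det(s2 - s1, s3 - s1, probe - center)`` with the substituents taken in
    the fixed reference order; positive -> alpha -> epimer 6a, negative ->
    beta -> 6b.  Mirror reflection of all coordinates flips the label; rigid
    motions leave it unchanged.
    """
    s1, s2, s3 = (np.asarray(coords[i], dtype=float)
                  for i in reference_substituents)
    c = np.asarray(coords[center], dtype=float)
    probe = np.asarray(probe, dtype=float)
    volume = float(np.linalg.det(np.stack([s2 - s1, s3 - s1, probe - c])))
    if abs(volume) < tol:
        raise DegenerateGeometryError(
            f"probe is coplanar with the substituent plane "
            f"(|triple product| = {abs(volume):.3g} A^3 < {tol:g})"
        )
    face = "alpha" if volume > 0 else "beta"
    return FaceLabel(face, FACE_EPIMERS[face], tuple(reference_substituents))


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def registry_to_json(path: str | Path | None = None) -> str:
    """Dump the built-in species registry (atoms, bonds, cation center)."""
    payload = {}
    for key in _REGISTRY:
        g = _REGISTRY[key]()
        payload[key] = {
            "atoms": [[a.atom_id, a.element, a.name] for a in g.atoms],
            "bonds": [list(b) for b in g.bonds],
            "cation_center": g.cation_center,
        }
    text = json.dumps(payload, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def write_sdf(g: CationGraph, coords: np.ndarray, path: str | Path) -> None:
    from rdkit import Chem

    mol = to_rdkit(g, coords)
    with Chem.SDWriter(str(path)) as writer:
        writer.write(mol)


def write_xyz(g: CationGraph, coords: np.ndarray, path: str | Path) -> None:
    lines = [str(g.n_atoms), g.label]
    for a in g.atoms:
        x, y, z = coords[a.atom_id]
        lines.append(f"{a.element} {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")
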