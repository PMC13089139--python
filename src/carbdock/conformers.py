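"""Conformer library generation, energy filtering and RMSD deduplication.

Libraries are produced by seeded distance-geometry embedding (RDKit ETKDG)
and ranked with a pluggable energy function.  The default energy is a
deliberately simple molecular-mechanics surrogate — a threefold torsional
term plus a soft Lennard-Jones-like self-clash — on a relative kcal/mol
scale; callers with externally computed (e.g. quantum-chemical) energies can
inject them via ``table_energy_fn``.

Filtering keeps conformers within a 5 kcal/mol window of the library minimum
and removes duplicates closer than 0.25 A heavy-atom RMSD after optimal
superposition, always retaining the lowest-energy member of each duplicate
cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .intermediates import CationGraph, RIGID_TEMPLATES, SpeciesError, to_rdkit

__all__ = [
    "Conformer",
    "ConformerLibrary",
    "EmbeddingError",
    "generate_conformers",
    "filter_library",
    "default_energy_fn",
    "table_energy_fn",
    "superposed_rmsd",
    "write_library_sdf",
    "read_library_sdf",
]

# default-energy constants (documented, relative kcal/mol scale)
TORSION_BARRIER = 0.3     # kcal/mol, threefold term per proper torsion
CLASH_DISTANCE = 2.7      # A, heavy-heavy soft-sphere onset
CLASH_K = 10.0            # kcal/mol/A^2
ATTRACT_EPS = 0.05        # kcal/mol, capped dispersion-like attraction
ATTRACT_SIGMA = 3.5       # A

BOND_MIN, BOND_MAX = 0.7, 1.9  # A, sanity gate on bonded distances


class EmbeddingError(RuntimeError):
    pass


@dataclass
class Conformer:
    species: CationGraph
    coords: np.ndarray  # (n_atoms, 3), angstrom
    energy: float       # kcal/mol, relative scale

    def bonded_distances(self) -> np.ndarray:
        return np.array([
            np.linalg.norm(self.coords[i] - self.coords[j])
            for i, j, _ in self.species.bonds
        ])


@dataclass
class ConformerLibrary:
    conformers: list[Conformer]
    provenance: str = ""
    energy_min: float = field(init=False)

    def __post_init__(self) -> None:
        self.energy_min = min((c.energy for c in self.conformers), default=np.nan)

    def __len__(self) -> int:
        return len(self.conformers)

    def __getitem__(self, i: int) -> Conformer:
        return self.conformers[i]


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------

def _torsion_quads(g: CationGraph) -> list[tuple[int, int, int, int]]:
    """Proper torsions i-j-k-l over heavy-atom central bonds."""
    quads = []
    heavy = set(g.heavy_ids())
    for j, k, _ in g.bonds:
        if j not in heavy or k not in heavy:
            continue
        for i, _ in g.neighbors(j):
            if i == k:
                continue
            for l, _ in g.neighbors(k):
                if l == j or l == i:
                    continue
                quads.append((i, j, k, l))
    return quads


def _graph_distances_ge3(g: CationGraph) -> list[tuple[int, int]]:
    """Atom pairs at topological distance >= 3 (the nonbonded set)."""
    n = g.n_atoms
    near: list[set[int]] = []
    for start in range(n):  # BFS to depth 2: pairs closer than 3 bonds
        frontier = {start}
        reached = {start}
        for _ in range(2):
            frontier = {j for i in frontier for j, _ in g.neighbors(i)} - reached
            reached |= frontier
        near.append(reached)
    return [(i, j) for i in range(n) for j in range(i + 1, n) if j not in near[i]]


def default_energy_fn(g: CationGraph) -> Callable[[np.ndarray], float]:
    """Torsional rule term plus soft Lennard-Jones-like self-clash.

    E = sum_torsions V3/2 (1 + cos 3phi)
      + sum_{pairs >= 3 bonds apart, heavy-heavy}
            [ k (d_clash - d)^2_+  -  eps min(1, (sigma/d)^6) ]
    """
    quads = _torsion_quads(g)
    heavy = set(g.heavy_ids())
    pairs = [(i, j) for i, j in _graph_distances_ge3(g)
             if i in heavy and j in heavy]

    def energy(coords: np.ndarray) -> float:
        coords = np.asarray(coords, dtype=float)
        e = 0.0
        for i, j, k, l in quads:
            b1 = coords[j] - coords[i]
            b2 = coords[k] - coords[j]
            b3 = coords[l] - coords[k]
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            denom = np.linalg.norm(n1) * np.linalg.norm(n2)
            if denom < 1e-12:
                continue
            cos_phi = np.clip(np.dot(n1, n2) / denom, -1.0, 1.0)
            # cos(3phi) via Chebyshev: 4c^3 - 3c
            e += 0.5 * TORSION_BARRIER * (1.0 + 4 * cos_phi**3 - 3 * cos_phi)
        if pairs:
            idx = np.array(pairs)
            d = np.linalg.norm(coords[idx[:, 0]] - coords[idx[:, 1]], axis=1)
            e += CLASH_K * np.sum(np.maximum(0.0, CLASH_DISTANCE - d) ** 2)
            e -= ATTRACT_EPS * np.sum(np.minimum(1.0, (ATTRACT_SIGMA / d) ** 6))
        return float(e)

    return energy


def table_energy_fn(table: Sequence[float]) -> Callable[[np.ndarray], float]:
    """Adapter: assign externally computed energies by conformer index."""
    table = list(table)
    state = {"i": 0}

    def energy(_coords: np.ndarray) -> float:
        value = table[state["i"] % len(table)]
        state["i"] += 1
        return float(value)

    return energy


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_conformers(
    g: CationGraph,
    n: int,
    seed: int,
    energy_fn: Callable[[np.ndarray], float] | None = None,
    max_attempts: int = 10,
) -> ConformerLibrary:
    """Embed `n` conformers of a species, deterministically per seed.

    Rigid registry species (water, the pyrophosphate-Mg cluster) return their
    fixed template geometry.  Flexible species are embedded with seeded
    ETKDG; embedding failures are retried with perturbed seeds up to
    `max_attempts` times before raising.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if g.label in RIGID_TEMPLATES:
        coords = RIGID_TEMPLATES[g.label].copy()
        fn = energy_fn or (lambda c: 0.0)
        members = [Conformer(g, coords.copy(), fn(coords)) for _ in range(n)]
        return ConformerLibrary(members, provenance=f"rigid-template seed={seed}")

    from rdkit.Chem import AllChem

    mol = to_rdkit(g)
    fn = energy_fn or default_energy_fn(g)
    conf_ids: list[int] = []
    for attempt in range(max_attempts):
        params = AllChem.ETKDGv3()
        params.randomSeed = int(seed) + 1000003 * attempt
        params.useRandomCoords = attempt > 0
        conf_ids = list(AllChem.EmbedMultipleConfs(mol, numConfs=n, params=params))
        if len(conf_ids) == n:
            break
        mol.RemoveAllConformers()
    if len(conf_ids) != n:
        raise EmbeddingError(
            f"embedding failed for species {g.label!r} after "
            f"{max_attempts} attempts"
        )
    members = []
    for cid in conf_ids:
        coords = np.array(mol.GetConformer(cid).GetPositions(), dtype=float)
        members.append(Conformer(g, coords, fn(coords)))
    return ConformerLibrary(members, provenance=f"etkdg seed={seed}")


# ---------------------------------------------------------------------------
# superposition and filtering
# ---------------------------------------------------------------------------

def superposed_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Minimum RMSD between two coordinate sets over rigid superposition."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    if len(p) == 1:
        return 0.0
    rot, _ = Rotation.align_vectors(pc, qc)
    diff = pc - rot.apply(qc)
    return float(np.sqrt((diff**2).sum() / len(p)))


def filter_library(
    lib: ConformerLibrary,
    window: float = 5.0,
    dup_rmsd: float = 0.25,
) -> ConformerLibrary:
    """Drop high-energy and duplicate conformers.

    Survivors have energy <= min + `window` (kcal/mol); among conformers
    within `dup_rmsd` (A, heavy-atom, optimal superposition) only the
    lowest-energy one is kept.  The global minimum always survives, and the
    operation is idempotent.
    """
    if not lib.conformers:
        raise SpeciesError("cannot filter an empty conformer library")
    emin = min(c.energy for c in lib.conformers)
    candidates = [c for c in lib.conformers if c.energy <= emin + window]
    candidates.sort(key=lambda c: c.energy)
    heavy = candidates[0].species.heavy_ids()
    kept: list[Conformer] = []
    for cand in candidates:
        duplicate = any(
            superposed_rmsd(cand.coords[heavy], k.coords[heavy]) <= dup_rmsd
            for k in kept
        )
        if not duplicate:
            kept.append(cand)
    return ConformerLibrary(kept, provenance=lib.provenance + " | filtered")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

ENERGY_TAG = "ENERGY_KCAL"


def write_library_sdf(lib: ConformerLibrary, path: str | Path) -> None:
    from rdkit import Chem

    with Chem.SDWriter(str(path)) as writer:
        for c in lib.conformers:
            mol = to_rdkit(c.species, c.coords)
            mol.SetProp(ENERGY_TAG, f"{c.energy:.6f}")
            writer.write(mol)


def read_library_sdf(path: str | Path, g: CationGraph) -> ConformerLibrary:
    from rdkit import Chem

    members = []
    for mol in Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True):
        if mol is None:
            continue
        coords = np.array(mol.GetConformer().GetPositions(), dtype=float)
        energy = float(mol.GetProp(ENERGY_TAG)) if mol.HasProp(ENERGY_TAG) else 0.0
        members.append(Conformer(g, coords, energy))
    return ConformerLibrary(members, provenance=f"sdf:{path}")
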