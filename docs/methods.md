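# Methods

## Species models

The two carbocation intermediates are shipped as explicit-hydrogen bond
tables under standard diterpene numbering (rings A/B/C = C1–C10, C5–C10,
C8–C14; gem-dimethyl C18/C19 on C4; angular methyl C20 on C10):

* **A**, isopimara-15-en-8-yl cation: trivalent C8, vinyl C15=C16 and
  methyl C17 on C13.  C20H33⁺, 53 atoms.  Alpha protons: H7A/H7B, H14A/H14B,
  H9 — five sites on three carbons, hence three possible olefins
  (C7 → **7**, C14 → **8**, C9 → **10**).
* **B**, abieta-8(14)-en-13-yl cation: trivalent C13, C8=C14 olefin,
  isopropyl C15(C16)(C17) on C13.  The two prochiral faces of C13 map to the
  abietaenol epimers **6a** (alpha) and **6b** (beta).

Two rigid species complete the cast: water (template geometry 0.957 Å /
104.5°) and a seven-point pyrophosphate–magnesium cluster with one labeled
bridging oxygen (`O_BR`, the former ester oxygen) and three terminal oxygens
(`OT1–OT3`).  The cluster is an idealized placeholder, not a real Mg
coordination shell; the two docking "anchor ends" are the two terminal
oxygens that are maximally separated in the template.

Face assignment uses the sign of the scalar triple product
`det(s2−s1, s3−s1, probe−center)` over the fixed substituent order
(C12, C14, C15); positive = alpha = **6a**.  A probe within 1e-6 Å³ of
coplanarity raises a degenerate-geometry error — numerically safe and never
triggered by real poses.

## Conformers

Libraries are embedded with seeded ETKDG (bounded retry, 10 attempts with
perturbed seeds) and ranked by a pluggable energy function.  The default is
a deliberately simple surrogate on a relative kcal/mol scale: a threefold
torsional term (V₃ = 0.3 kcal/mol per proper torsion) plus a soft
Lennard-Jones-like self-term over heavy-atom pairs ≥ 3 bonds apart
(quadratic clash below 2.7 Å with k = 10 kcal/mol/Ų; capped attraction
ε = 0.05, σ = 3.5 Å).  An adapter accepts an external energy table so
quantum-chemical energies can be injected without touching the pipeline.
Filtering keeps conformers within **5 kcal/mol** of the library minimum and
removes duplicates below **0.25 Å** heavy-atom RMSD after optimal
superposition (below thermal-vibration scale, standard for conformer
dedup); the lowest-energy member of each duplicate cluster survives, so the
global minimum always does, and the filter is idempotent.

## Restraints

All restraints are flat-bottomed: zero on `[lower, upper]`, then
`((x − nearest_edge)/sd)² · weight`.  The normalization makes "one sd past
the edge" score exactly 1.0, which is why the filter requires per-ligand
scores *strictly below one*.  Defaults (Å / degrees, all configurable):

| restraint | bounds | sd |
|---|---|---|
| base O···alpha-H (proton transfer) | 1.6 – 2.6 | 0.3 |
| C–H···O abstraction angle | 120 – 180 | 20 |
| C16···pyrophosphate end | 2.5 – 4.5 | 0.5 |
| water O···C13, reactive (species B) | 2.6 – 3.4 | 0.3 |
| water O···C13, loosened (species A) | 2.6 – 5.0 | 0.3 |
| water face-approach angle vs. face normal | 0 – 35 | 10 |
| C7···residue-723 side-chain tip | 3.5 – 5.5 | 0.5 |

These magnitudes are hydrogen-bond/proton-transfer geometry norms; no
published values exist for them in this protocol, so they are declared
here rather than inferred.  The `face_angle` restraint kind extends the
distance/angle vocabulary because a prochiral-face constraint needs a
signed plane normal (center, three reference substituents, probe).

A deprotonation scan builds |sites| × |anchors| sets — 5 × 2 = 10 for
species A — each holding the three restraints in rows 1–3 above and tagged
with its olefin hypothesis.

## Docking and scoring

Pose sampling is uniform and rigid: conformer drawn uniformly, rotation
uniform on SO(3) by the Shoemake quaternion construction, translation
uniform in the pocket sphere.  Per-set RNG streams are
`SHA-256(seed ‖ set_id)` truncated below 2³¹, so adding sets never perturbs
existing streams and reruns are byte-identical.

The scorer is a documented soft-sphere/contact surrogate, not a physical
force field: repulsion `Σ (3.0 − d)²₊` and attraction `−min(contacts, 100)`
over heavy-atom pairs in the 3.2–4.5 Å shell, with weights w_rep = 1.0,
w_att = 0.4, w_cst = 1.0.  Mobile bodies (carbocation, water) are scored
against the fixed environment — receptor atoms *plus* the stationary
pyrophosphate cluster.  Including the co-product in the environment is a
deliberate choice: the water's interaction with the pyrophosphate (it ends
up nearest the bridging oxygen in the wild-type runs) is part of the
mechanism under study and would be invisible to a receptor-only scorer.
Interface energy is the repulsion+attraction of the carbocation body alone,
restraints excluded.  Absolute pose counts from any published force field
are *not* reproduced by this scorer — only the procedure and its
combinatorics are.

The water, when a set carries a water mode, is placed per pose by an
exhaustive local grid (default 1.0 Å spacing, 5.5 Å half-width) around its
constraint target (C13), minimizing the water's own restraint penalty plus
soft clash minus capped attractive contacts (cap 12 — a coordination limit
for one oxygen) against the environment; ligand atoms contribute clash
only, mirroring the pose scorer.  Candidates are pruned by a restraint
margin equal to the largest attainable contact bonus, which cannot change
the argmin.  The pyrophosphate cluster itself, when not supplied with the
receptor, is placed once by a translation-only grid scan over the pocket
(ties broken by the first grid index; the scan fails loudly if no
clash-free point exists).

The filter cascade keeps (1) poses with every per-ligand constraint score
< 1, then (2) the `max(1, floor(0.10·n))` lowest total scores, then (3) the
`max(1, floor(0.10·k))` lowest interface energies.  Floor-with-minimum-one
and pose-id tie-breaks make the output invariant to input order.  Whether
the published percentiles were taken over constraint-passing poses or all
poses is ambiguous in the protocol as described; they are applied
sequentially here, as quoted.

## Classification

Outcome classification is by realized geometry, not by the generating
constraint set: the predicted olefin is the one formed by abstracting the
alpha proton nearest the base hydroxyl oxygen, gated at O···H ≤ 2.8 Å and
C–H···O ≥ 100° (looser than the docking flat bottom so near-miss poses are
still attributed; below-gate poses are "unassigned").  The generating
hypothesis is recorded alongside and the agreement rate reported — on
poses whose proton restraints score exactly zero the two always agree.
Water taxonomy: nearest labeled pyrophosphate oxygen within 3.5 Å
(bridging/terminal), else "none".  Epimer: the face of C13 occupied by the
water oxygen.

## Synthetic fixtures

The toy receptor is a jittered Fibonacci-sphere shell of carbon
pseudo-atoms (default radius 10 Å, 420 atoms ≈ 2 Å spacing — dense enough
that a water cannot slip between wall atoms) with one protein-like residue
numbered 723 whose side chain points into the cavity, carrying the variant
hydroxyl by ideal-geometry grafting (Thr OG1/HG1 or Ser OG/HG at 1.43 /
0.96 Å along the CA→CB axis; Ala strips the probe), plus the rigid
pyrophosphate cluster.  Pose translations sample a sphere 4.5 Å inside the
wall.  Seeds change the shell jitter, never the site topology.

The toy cation is a star: trivalent center `C8` with up to three alpha
carbons carrying a configurable proton census (`[2,2,1]` mirrors species
A's C7/C14/C9 census and reuses the 7/8/10 product map), padded with blank
carbons so the center is always trivalent, plus a scaffold — trigonal-planar
C13 (faces along ±z; +z = alpha) with C12/C15 substituents and the C16
anchor tip.

The *aligned workspace* used by the end-to-end experiments places this
reactant against the lower pocket wall (terpene-synthase chemistry happens
at the cavity wall, not in mid-pocket), grafts the 723 hydroxyl so its
oxygen lies exactly 2.0 Å beyond the planted C7 proton on its approach
vector, and positions the pyrophosphate cluster over the alpha face of C13
by a deterministic construction-time grid search (a terminal oxygen in
anchor range of C16; cluster atoms in contact range of the alpha-face water
spot; no ligand clash).  This is the geometrically consistent stage on
which the water-constraint comparison is meaningful: with a sparse shell or
a mid-pocket reactant the loosened water constraint is vacuously
satisfiable everywhere and exerts no selection at all.

Planted pose sets orient the ligand so the designated proton sits 2.0 Å
from the base oxygen at a 180° abstraction angle (or, for epimer planting,
put a water 2.2 Å off the requested face of C13), with exact
largest-remainder allocation of the outcome fractions — a 70/30 mixture of
200 poses is exactly 140/60 — plus configurable geometric jitter, synthetic
score distributions and a constraint-failure fraction.  Recovery is exact
at zero noise and degrades monotonically with jitter.

What the fixtures do *not* emulate: real protein folds, pocket anisotropy
beyond the wall/base/cluster arrangement, Mg²⁺ electrostatics, receptor
flexibility, or physical score magnitudes.  Passing tests therefore
validate the combinatorics, determinism and geometric logic of the
pipeline, not its energetic realism on real structures.

## Problem sizes

The test suite runs the full-budget pooling check (10 × 4000 and 2 × 4000
sampled poses) and the directional water comparison at 1000 poses per set
over five seeds; the acceptance script uses 2000 poses per set over five
seeds for the directional comparison and the full 4000-pose budget for the
pooling counts.  The analysis drivers use 1500–2500 poses per set.  These
sizes give stable pooled fractions at desk scale; all are plain config
values.

## Known limitations

* Uniform rigid sampling makes constraint satisfaction rare (~0.2–0.5 % per
  set on the toy stage), so cascade denominators are tens, not thousands;
  fractions are pooled over seeds where statistics matter.
* The published experiment used docking that optimizes poses against
  constraints and a physical score function; survivor counts here are not
  comparable in absolute terms.
* The 1,4-proton transfer / 1,2-methyl shift connecting A and B is not
  modeled; the two cations are docked as separate rigid species.
* Receptor side chains are fixed; the only mutable position is 723.
* Per one description of the wild-type runs the per-set budget is 2500
  poses (5000 total per epimer), per another it is 4000 (8000 total); both
  are supported via `n_poses_per_set`, the analysis driver uses 2500 and
  the pooling count in the acceptance script uses 4000.
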