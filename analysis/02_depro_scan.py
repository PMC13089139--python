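"""Deprotonation scan of the toy reactant in the T-variant pocket.

Runs the ten-set constrained docking (no water), applies the three-stage
filter cascade and tallies which olefin each surviving pose would form.
Without the reactant water the outcome mixture is broad — the point of
departure for the water-constrained reruns in 03.
"""

from pathlib import Path

from carbdock import docking as dk
from carbdock import pipeline as pl
from carbdock import synthetic_data as sd
from carbdock.conformers import ConformerLibrary

RESULTS = Path(__file__).resolve().parents[1] / "results"
N_PER_SET = 2000
SEED = 17


def main() -> None:
    ws = sd.make_aligned_workspace(sd.FixtureSpec(seed=3), variant="T")
    cfg = pl.ExperimentConfig(
        experiment="a723t_depro_scan",
        receptor=ws.receptor,
        species=ws.graph,
        docking=dk.DockingConfig(n_poses_per_set=N_PER_SET, seed=SEED),
        conformer_library=ConformerLibrary([ws.conformer]),
        outdir=RESULTS / "depro_scan",
    )
    res = pl.run_experiment(cfg)
    t = res.trace
    print(f"pooled {t.n0} poses over {res.manifest['n_sets']} sets")
    print(f"cascade: {t.n0} -> {t.n1} (constraints) -> {t.k1} "
          f"(total score) -> {t.k2} (interface)")
    print(res.report.summary())
    print(f"artifacts in {cfg.outdir}")


if __name__ == "__main__":
    main()
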