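"""Shared helpers for the test suite."""

import numpy as np

from carbdock.docking import Pose


def make_scored_pool(n, rng, all_pass=True):
    """Synthetic constraint-passing poses with distinct random scores."""
    poses = []
    for i in range(n):
        poses.append(Pose(
            pose_id=f"p:{i:06d}", set_id="s", conformer_id=0,
            quat=np.array([0.0, 0.0, 0.0, 1.0]),
            translation=np.zeros(3), ligand_coords=np.zeros((1, 3)),
            cst_scores={"carbocation": 0.0 if all_pass else 2.0},
            total_score=float(rng.normal()),
            interface_energy=float(rng.normal()),
        ))
    return poses
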