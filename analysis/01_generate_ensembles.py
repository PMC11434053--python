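"""Generate the two synthetic solvation ensembles and export their raw data.

Writes per-snapshot excitation sticks and ground-truth records to results/,
and the full trajectories (large) to scratch/.
"""
import os
import sys

import numpy as np

sys.path.insert(0, os.path.dirname(__file__))
from common import N_FRAMES, RESULTS, SCRATCH, ensure_dirs, ethanol_model, water_model

from colorspec.cli import _write_xyz_trajectory
from colorspec.synthetic import gen_sticks, gen_trajectory


def export(name, model):
    traj, gt = gen_trajectory(model, N_FRAMES)
    sticks = gen_sticks(traj, gt, model)
    _write_xyz_trajectory(traj, os.path.join(SCRATCH, f"{name}_trajectory.xyz"))
    np.savetxt(
        os.path.join(RESULTS, f"{name}_ground_truth.tsv"),
        np.column_stack(
            [gt.phi_deg, gt.mode_label, gt.shell_counts, gt.v_emb, gt.planarity_sq]
        ),
        header="phi_deg mode shell_count v_emb_au planarity_rad2",
        fmt="%.6f",
    )
    rows = [(s.snapshot_id, s.energies[0], s.strengths[0]) for s in sticks]
    np.savetxt(
        os.path.join(RESULTS, f"{name}_sticks.tsv"),
        np.array(rows),
        header="snapshot_id energy_eV oscillator_strength",
        fmt="%.6f",
    )
    print(
        f"{name}: {N_FRAMES} frames, mean shell count "
        f"{gt.shell_counts.mean():.2f}, mean stick energy "
        f"{np.mean([s.energies[0] for s in sticks]):.3f} eV"
    )


if __name__ == "__main__":
    ensure_dirs()
    export("water", water_model())
    export("ethanol", ethanol_model())
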