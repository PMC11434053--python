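"""Conformational analysis: dihedral distributions and conformer clustering.

Reproduces the torsion-level characterization: the inter-ring Φ distribution
shows four modes near the planar arrangements; frames are grouped into the
four 90°-wide Φ bins with populations and central structures; an RMSD-based
GROMOS clustering of a subsample is reported for comparison.
"""
import os
import sys

import numpy as np

sys.path.insert(0, os.path.dirname(__file__))
from common import RESULTS, ensure_dirs, water_model

from colorspec.conformers import (
    assign_phi_clusters,
    ddf,
    dihedral_series,
    gromos_cluster,
)
from colorspec.synthetic import SyntheticModel, gen_trajectory

if __name__ == "__main__":
    ensure_dirs()
    # torsion statistics need many frames but no solvent
    model = SyntheticModel(seed=water_model().seed, n_solvent=0)
    traj, _ = gen_trajectory(model, 5000)

    for name in ("PHI", "DELTA1", "DELTA3"):
        res = ddf(traj, name, bin_width=2.0)
        np.savetxt(
            os.path.join(RESULTS, f"ddf_{name.lower()}.tsv"),
            np.column_stack([res.centers, res.density]),
            header="angle_deg density_per_deg",
            fmt="%.6f",
        )
    phi = dihedral_series(traj, "PHI")
    clusters = assign_phi_clusters(phi)
    with open(os.path.join(RESULTS, "phi_clusters.tsv"), "w") as fh:
        fh.write("group\tpopulation\trepresentative_frame\trepresentative_phi_deg\n")
        for g in range(4):
            rep = clusters.representative_frames[g]
            fh.write(
                f"{g + 1}\t{clusters.populations[g]:.4f}\t{rep}\t"
                f"{phi[rep]:.1f}\n"
            )
    print("Φ group populations:", np.round(clusters.populations, 3))

    sub_model = SyntheticModel(seed=model.seed + 7, n_solvent=0)
    sub, _ = gen_trajectory(sub_model, 60)
    gro = gromos_cluster(sub, rmsd_cutoff=1.0)
    print(
        f"GROMOS clustering (60 frames, cutoff 1.0 Å): "
        f"{gro.populations.size} clusters, populations "
        f"{np.round(np.sort(gro.populations)[::-1][:4], 3)}"
    )
    np.savetxt(
        os.path.join(RESULTS, "gromos_labels.tsv"),
        np.column_stack([np.arange(gro.labels.size), gro.labels]),
        header="frame_index label",
        fmt="%d",
    )
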