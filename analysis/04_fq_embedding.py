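"""Polarizable embedding on droplet snapshots: FQ vs FQFμ.

Cuts spherical droplets around the chromophore, solves the constrained
polarization equations with the solute as a point-charge source, and reports
interaction energies and the embedding potential at the solute center.
"""
import os
import sys

import numpy as np

sys.path.insert(0, os.path.dirname(__file__))
from common import DROPLET_RADIUS, RESULTS, ensure_dirs, water_model

from colorspec import fq
from colorspec.synthetic import gen_trajectory
from colorspec.trajectory_io import extract_droplet, unwrap_molecules

N_SNAPSHOTS = 5

if __name__ == "__main__":
    ensure_dirs()
    model = water_model()
    traj, gt = gen_trajectory(model, N_SNAPSHOTS)
    params_fq = fq.FQParams.builtin("water_fq")
    params_mu = fq.FQParams.builtin("water_fqmu")
    rows = []
    for i, frame in enumerate(traj.frames):
        droplet = extract_droplet(
            unwrap_molecules(frame, traj.topology),
            traj.topology,
            DROPLET_RADIUS,
            source_frame_index=i,
        )
        sol = droplet.solute_atom_indices
        mm = droplet.solvent_atom_indices
        source = fq.SoluteSource(
            positions=droplet.frame.positions[sol],
            charges=np.full(sol.size, 1.0 / sol.size),  # +1 cation, smeared
        )
        ext = fq.source_fields(source, droplet.frame.positions[mm])
        center = droplet.frame.positions[sol].mean(axis=0)
        out = {"frame": i, "n_solvent_atoms": mm.size}
        for tag, params, mdl in (("fq", params_fq, "fq"), ("fqmu", params_mu, "fqmu")):
            kern = fq.assemble_kernels(droplet, params, model=mdl)
            chi = np.array(
                [params.chi(droplet.topology.atoms[j].element) for j in mm]
            )
            state = fq.solve_polarization(kern, chi, ext)
            out[f"E_int_{tag}_au"] = fq.interaction_energy(state, ext, mdl)
            out[f"v_emb_{tag}_au"] = fq.embedding_potential_at(state, center)[0]
        rows.append(out)
        print(
            f"frame {i}: {mm.size} MM atoms, "
            f"E_int FQ {out['E_int_fq_au']:+.5f} au, "
            f"FQFμ {out['E_int_fqmu_au']:+.5f} au, "
            f"v_emb(center) FQ {out['v_emb_fq_au']:+.5f} au"
        )
    keys = list(rows[0])
    with open(os.path.join(RESULTS, "fq_snapshots.tsv"), "w") as fh:
        fh.write("\t".join(keys) + "\n")
        for r in rows:
            fh.write("\t".join(f"{r[k]:.6f}" if isinstance(r[k], float) else str(r[k]) for k in keys) + "\n")
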