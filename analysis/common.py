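"""Shared study configuration for the analysis drivers.

Two synthetic solvation ensembles stand in for the MD runs: a water-like one
(tight hydrogen-bond shells, first peak 1.82 Å, occupancy ~0.97) and an
ethanol-like one (slightly longer shells at 1.86 Å, occupancy 0.85, and a
stronger per-neighbor embedding descriptor so the surrogate band red-shifts,
emulating the experimental water→ethanol solvatochromism).
"""
import os

from colorspec.synthetic import ExcitationModel, SolventShellModel, SyntheticModel

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")
SCRATCH = os.path.join(os.path.dirname(__file__), "..", "scratch")

N_FRAMES = 200          # snapshots per ensemble
N_SOLVENT = 150
FWHM_EV = 0.3
DROPLET_RADIUS = 18.0   # Å


def water_model(seed: int = 100) -> SyntheticModel:
    return SyntheticModel(seed=seed, n_solvent=N_SOLVENT)


def ethanol_model(seed: int = 200) -> SyntheticModel:
    return SyntheticModel(
        seed=seed,
        n_solvent=N_SOLVENT,
        shell=SolventShellModel(target_peak=1.86, width=0.06, occupancy=0.85),
        excitation=ExcitationModel(v_per_neighbor=-0.0116),
    )


def ensure_dirs() -> None:
    os.makedirs(RESULTS, exist_ok=True)
    os.makedirs(SCRATCH, exist_ok=True)
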