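"""Synthetic trajectories, solvation shells and excitation sticks with ground truth.

The generator emulates the statistical structure the analysis stages assume,
so the whole pipeline is testable without an MD or excited-state engine:

* a rigid two-ring chromophore stand-in (22 atoms) whose inter-ring torsion
  Φ is drawn from a four-mode wrapped (von Mises) mixture around the planar
  arrangements, and whose five hydroxyl torsions δ1–δ5 are drawn from a
  bimodal 0°/180° density;
* a polar solvent shell: each labeled donor hydrogen holds, with a
  configurable occupancy, one water-like molecule whose oxygen sits at a
  hydrogen-bond-like distance (Gaussian around the target peak) along the
  O–H direction; the remaining solvent fills the periodic box uniformly
  outside an excluded-volume radius of the solute;
* per-snapshot excitation sticks from a linear solvatochromic surrogate,

      E = E₀ + c·d_planar(Φ)² + k·v_emb + ε,   ε ~ N(0, σ²),

  where d_planar is the angular distance (radians) of Φ from the nearest
  planar configuration (0° or 180°) and v_emb is the recorded
  embedding-potential descriptor (or, on request, the FQ solver's classical
  embedding potential at the solute center).  This surrogate reproduces the
  two qualitative drivers of the real problem — conformation through ring
  planarity, solvation through the embedding potential — not the underlying
  electronic structure.

Everything is deterministic under a seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from . import fq as fq_mod
from .conformers import dihedral_angle, wrap_angle
from .spectra import StickSpectrum
from .topology import Atom, Frame, Topology, Trajectory
from .trajectory_io import extract_droplet


@dataclass
class PhiMode:
    center: float        # degrees
    concentration: float  # von Mises κ (larger = narrower)
    weight: float


@dataclass
class SolventShellModel:
    target_peak: float = 1.82    # Å, donor H ⋯ water O distance
    width: float = 0.06          # Å, Gaussian spread of the shell distance
    occupancy: float = 0.97      # mean neighbors per donor site


@dataclass
class ExcitationModel:
    e0: float = 2.90             # gas-phase-like excitation energy, eV
    stark_slope: float = 5.0     # k, eV per a.u. of embedding potential
    dihedral_coupling: float = 0.12  # c, eV per rad² of non-planarity
    noise_sigma: float = 0.05    # eV
    f0: float = 1.0              # oscillator strength scale
    v_per_neighbor: float = -0.004   # a.u. contribution per shell neighbor
    v_jitter: float = 0.002      # a.u. scatter of the recorded descriptor


@dataclass
class SyntheticModel:
    phi_modes: list = field(
        default_factory=lambda: [
            PhiMode(160.0, 20.0, 0.4),
            PhiMode(20.0, 20.0, 0.1),
            PhiMode(-20.0, 20.0, 0.1),
            PhiMode(-160.0, 20.0, 0.4),
        ]
    )
    hydroxyl_kappa: float = 10.0
    shell: SolventShellModel = field(default_factory=SolventShellModel)
    box_edge: float = 62.0       # Å
    n_solvent: int = 300         # total solvent molecules (shell + background)
    exclusion_radius: float = 3.0    # Å, solvent keep-out around solute atoms
    thermal_jitter: float = 0.02     # Å, per-atom coordinate noise on the solute
    excitation: ExcitationModel = field(default_factory=ExcitationModel)
    seed: int = 0

    def __post_init__(self) -> None:
        w = sum(m.weight for m in self.phi_modes)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"phi mode weights sum to {w}, expected 1")
        if any(m.concentration <= 0 for m in self.phi_modes):
            raise ValueError("mode concentrations must be positive")
        if self.shell.occupancy < 0 or self.excitation.noise_sigma < 0:
            raise ValueError("occupancy and noise must be nonnegative")


@dataclass
class GroundTruth:
    phi_deg: np.ndarray
    mode_label: np.ndarray
    deltas_deg: np.ndarray       # (n, 5) hydroxyl torsions
    shell_counts: np.ndarray
    v_emb: np.ndarray            # recorded embedding descriptor, a.u.
    planarity_sq: np.ndarray     # d_planar(Φ)² in rad²
    model: SyntheticModel | None = None


# ---------------------------------------------------------------- scaffold

_RING_R = 1.40      # Å hexagon circumradius
_CC_INTER = 1.48    # inter-ring bond
_CO_BOND = 1.36     # ring C – hydroxyl O
_OH_BOND = 0.97
_COH_ANGLE = 108.0  # degrees

#: atoms in the two-ring scaffold: 12 ring + 5×(O,H) hydroxyls
_N_SOLUTE = 22


def _hexagon(center, start_angle=0.0):
    ang = np.radians(start_angle + 60.0 * np.arange(6))
    return center + _RING_R * np.column_stack(
        [np.cos(ang), np.sin(ang), np.zeros(6)]
    )


def _place_by_internal(a, b, c, bond, angle_deg, torsion_deg):
    """Place atom d given positions a–b–c, the c–d bond length, the b–c–d
    angle and the a–b–c–d torsion (standard internal-coordinate placement)."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def solute_topology() -> tuple[Topology, dict]:
    """Topology of the 22-atom stand-in chromophore (one +1 molecule) and
    index metadata (ring atoms, hydroxyl triples, dihedral quads)."""
    elements = []
    labels: dict[int, str] = {}
    # ring A: indices 0..5; index 0 is the ring oxygen O1
    elements += ["O"] + ["C"] * 5
    labels[0] = "O1"
    # ring B: indices 6..11
    elements += ["C"] * 6
    # hydroxyls: (O, H) pairs attached to spread-out ring vertices
    oh_labels = [("O2", "H7"), ("O3", "H8"), ("O4", "H9"), ("O5", "H10"), ("O6", "H11")]
    oh_start = 12
    for o_lab, h_lab in oh_labels:
        labels[len(elements)] = o_lab
        elements.append("O")
        labels[len(elements)] = h_lab
        elements.append("H")
    atoms = [
        Atom(i, el, molecule_id=0, is_solute=True, site_label=labels.get(i))
        for i, el in enumerate(elements)
    ]
    # Φ over the inter-ring bond A3–B0; δ's over each C–O bond
    meta = {
        "phi_quad": (2, 3, 6, 7),
        "oh_start": oh_start,
    }
    dihedrals = {"PHI": meta["phi_quad"]}
    attach_carbons = [1, 5, 7, 9, 11]
    for k, c_idx in enumerate(attach_carbons):
        o_idx = oh_start + 2 * k
        h_idx = o_idx + 1
        # torsion reference: a ring neighbor of the attachment carbon
        nb = _ring_neighbor(c_idx)
        dihedrals[f"DELTA{k + 1}"] = (nb, c_idx, o_idx, h_idx)
    meta["attach_carbons"] = attach_carbons
    meta["oh_dihedrals"] = [f"DELTA{k + 1}" for k in range(5)]
    topo = Topology(atoms, qtot_per_molecule={0: 1.0}, dihedral_defs=dihedrals)
    return topo, meta


def _ring_neighbor(c_idx: int) -> int:
    if c_idx < 6:  # ring A
        return (c_idx + 1) % 6
    return 6 + ((c_idx - 6 + 1) % 6)


def build_solute(phi_deg: float, deltas_deg) -> np.ndarray:
    """Cartesian coordinates (Å) of the scaffold at a given Φ and hydroxyl
    torsions, centered near the origin."""
    pos = np.zeros((_N_SOLUTE, 3))
    pos[0:6] = _hexagon(np.zeros(3))
    b_attach = pos[3]                       # ring-A carbon bonded to ring B
    b0 = b_attach + np.array([-_CC_INTER, 0.0, 0.0])
    b_center = b0 + np.array([-_RING_R, 0.0, 0.0])
    ringB = _hexagon(b_center)
    pos[6:12] = ringB
    # rotate ring B about the inter-ring bond (x-axis through A3–B0) to set Φ
    topo_quad = (2, 3, 6, 7)
    for sign in (1.0, -1.0):
        rot = Rotation.from_rotvec(np.radians(sign * phi_deg) * np.array([1.0, 0, 0]))
        cand = b0 + rot.apply(ringB - b0)
        trial = pos.copy()
        trial[6:12] = cand
        got = dihedral_angle(Frame(trial[:12]), topo_quad) if abs(phi_deg) > 1e-9 else 0.0
        if abs(wrap_angle(got - phi_deg)) < 1e-6 or abs(phi_deg) <= 1e-9:
            pos[6:12] = cand
            break
    attach_carbons = [1, 5, 7, 9, 11]
    for k, c_idx in enumerate(attach_carbons):
        ring_center = np.zeros(3) if c_idx < 6 else pos[6:12].mean(axis=0)
        radial = pos[c_idx] - ring_center
        radial /= np.linalg.norm(radial)
        o_idx = 12 + 2 * k
        pos[o_idx] = pos[c_idx] + _CO_BOND * radial
        nb = _ring_neighbor(c_idx)
        pos[o_idx + 1] = _place_by_internal(
            pos[nb], pos[c_idx], pos[o_idx], _OH_BOND, _COH_ANGLE, deltas_deg[k]
        )
    return pos


# ---------------------------------------------------------------- solvent

_WATER_LOCAL = np.array(
    [
        [0.0, 0.0, 0.0],
        [0.9572, 0.0, 0.0],
        [0.9572 * np.cos(np.radians(104.52)), 0.9572 * np.sin(np.radians(104.52)), 0.0],
    ]
)


def _water_at(o_pos: np.ndarray, rng) -> np.ndarray:
    rot = Rotation.from_quat(_random_quat(rng))
    return o_pos + rot.apply(_WATER_LOCAL)


def _random_quat(rng) -> np.ndarray:
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)


def _sample_phi(model: SyntheticModel, rng) -> tuple[float, int]:
    weights = np.array([m.weight for m in model.phi_modes])
    k = int(rng.choice(len(weights), p=weights))
    mode = model.phi_modes[k]
    ang = np.degrees(rng.vonmises(np.radians(mode.center), mode.concentration))
    return float(wrap_angle(ang)), k


def planarity_deviation_sq(phi_deg) -> np.ndarray:
    """Squared angular distance (rad²) of Φ from the nearest planar value."""
    phi = np.atleast_1d(np.asarray(phi_deg, dtype=float))
    d0 = np.abs(wrap_angle(phi))
    d180 = np.abs(wrap_angle(phi - 180.0))
    return np.radians(np.minimum(d0, d180)) ** 2


def gen_trajectory(
    model: SyntheticModel, n_frames: int, seed: int | None = None
) -> tuple[Trajectory, GroundTruth]:
    """Generate a periodic-box trajectory plus its ground-truth record."""
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    solute_topo, meta = solute_topology()
    n_shell_sites = 5
    box = np.full(3, model.box_edge)
    center = box / 2

    atoms = list(solute_topo.atoms)
    for w in range(model.n_solvent):
        mol = 1 + w
        base = _N_SOLUTE + 3 * w
        atoms.append(Atom(base, "O", molecule_id=mol, is_solute=False))
        atoms.append(Atom(base + 1, "H", molecule_id=mol, is_solute=False))
        atoms.append(Atom(base + 2, "H", molecule_id=mol, is_solute=False))
    qtot = dict(solute_topo.qtot_per_molecule)
    topo = Topology(atoms, qtot_per_molecule=qtot, dihedral_defs=solute_topo.dihedral_defs)

    frames: list[Frame] = []
    phi_list, mode_list, delta_list = [], [], []
    count_list, v_list = [], []
    exc = model.excitation
    for fidx in range(n_frames):
        phi, mode_k = _sample_phi(model, rng)
        deltas = np.degrees(
            rng.vonmises(
                np.where(rng.random(n_shell_sites) < 0.5, 0.0, np.pi),
                model.hydroxyl_kappa,
            )
        )
        solute = build_solute(phi, deltas)
        if model.thermal_jitter > 0:
            solute = solute + rng.normal(0, model.thermal_jitter, solute.shape)
        solute = solute + center

        pos = np.zeros((topo.n_atoms, 3))
        pos[:_N_SOLUTE] = solute
        shell_count = 0
        placed = 0
        background_pool: list[int] = []
        shell_o_positions: list[np.ndarray] = []
        for site in range(min(n_shell_sites, model.n_solvent)):
            if rng.random() < model.shell.occupancy:
                o_idx = 12 + 2 * site
                h_idx = o_idx + 1
                base_dir = solute[h_idx] - solute[o_idx]
                base_dir /= np.linalg.norm(base_dir)
                other = np.delete(solute, h_idx, axis=0)
                # excluded volume: the shell oxygen may approach only its own
                # donor hydrogen; retry with a widening cone, and treat a
                # sterically buried site as unoccupied this frame
                ok = False
                for t in range(60):
                    direction = base_dir + (0.12 + 0.05 * t) * rng.normal(size=3)
                    direction /= np.linalg.norm(direction)
                    dist = rng.normal(model.shell.target_peak, model.shell.width)
                    o_pos = solute[h_idx] + dist * direction
                    ok = np.linalg.norm(other - o_pos, axis=1).min() > 2.2
                    if ok and shell_o_positions:
                        ok = (
                            np.linalg.norm(
                                np.array(shell_o_positions) - o_pos, axis=1
                            ).min()
                            > 2.5
                        )
                    if ok:
                        break
                if ok:
                    shell_o_positions.append(o_pos)
                    pos[
                        _N_SOLUTE + 3 * placed : _N_SOLUTE + 3 * placed + 3
                    ] = _water_at(o_pos, rng)
                    shell_count += 1
                else:
                    background_pool.append(placed)
            else:
                background_pool.append(placed)
            placed += 1
        background_pool.extend(range(placed, model.n_solvent))
        if background_pool:
            accepted = _uniform_solvent(
                len(background_pool), solute, box, model.exclusion_radius, rng
            )
            for slot, o_pos in zip(background_pool, accepted):
                pos[_N_SOLUTE + 3 * slot : _N_SOLUTE + 3 * slot + 3] = _water_at(
                    o_pos, rng
                )
        v = exc.v_per_neighbor * shell_count + rng.normal(0, exc.v_jitter)
        frames.append(Frame(pos, box=box.copy(), time=float(fidx)))
        phi_list.append(phi)
        mode_list.append(mode_k)
        delta_list.append(deltas)
        count_list.append(shell_count)
        v_list.append(v)

    gt = GroundTruth(
        phi_deg=np.array(phi_list),
        mode_label=np.array(mode_list),
        deltas_deg=np.array(delta_list),
        shell_counts=np.array(count_list),
        v_emb=np.array(v_list),
        planarity_sq=planarity_deviation_sq(np.array(phi_list)),
        model=model,
    )
    return Trajectory(topo, frames), gt


def _uniform_solvent(n: int, solute: np.ndarray, box: np.ndarray, excl: float, rng):
    """Uniform solvent oxygen positions outside the solute excluded volume."""
    out = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200:
            raise ValueError("infeasible solvent packing (density too high)")
        cand = rng.random((max(2 * (n - len(out)), 16), 3)) * box
        d = np.linalg.norm(
            cand[:, None, :] - solute[None, :, :], axis=-1
        )
        ok = cand[d.min(axis=1) > excl]
        out.extend(ok[: n - len(out)])
    return np.array(out)


# ---------------------------------------------------------------- sticks

def gen_sticks(
    traj: Trajectory,
    ground_truth: GroundTruth,
    model: SyntheticModel,
    embedding: str | None = None,
    seed: int | None = None,
    droplet_radius: float = 18.0,
    fq_params: "fq_mod.FQParams | None" = None,
) -> list[StickSpectrum]:
    """One bright excitation per frame from the solvatochromic surrogate.

    ``embedding="fq"`` replaces the recorded descriptor with the FQ solver's
    classical embedding potential at the solute geometric center, computed on
    a droplet cut from each frame with the solute as a point-charge source.
    """
    if ground_truth.phi_deg.shape[0] != traj.n_frames:
        raise ValueError("ground truth does not match trajectory")
    exc = model.excitation
    rng = np.random.default_rng((model.seed if seed is None else seed) + 1)
    sticks = []
    for i, frame in enumerate(traj.frames):
        if embedding == "fq":
            v = _fq_descriptor(frame, traj.topology, droplet_radius, fq_params, i)
        elif embedding is None:
            v = float(ground_truth.v_emb[i])
        else:
            raise ValueError(f"unknown embedding {embedding!r}")
        e = (
            exc.e0
            + exc.dihedral_coupling * float(ground_truth.planarity_sq[i])
            + exc.stark_slope * v
            + rng.normal(0, exc.noise_sigma)
        )
        f = exc.f0 * (1.0 + rng.uniform(-0.1, 0.1))
        sticks.append(StickSpectrum([e], [f], snapshot_id=i, method=embedding or "surrogate"))
    return sticks


def _fq_descriptor(frame, topology, radius, params, frame_index) -> float:
    from .trajectory_io import unwrap_molecules

    if params is None:
        params = fq_mod.FQParams.builtin("water_fq")
    droplet = extract_droplet(
        unwrap_molecules(frame, topology) if frame.box is not None else frame,
        topology,
        radius,
        source_frame_index=frame_index,
    )
    sol_idx = droplet.solute_atom_indices
    n_sol = sol_idx.size
    qtot_solute = sum(
        droplet.topology.qtot(m)
        for m in {droplet.topology.atoms[i].molecule_id for i in sol_idx}
    )
    source = fq_mod.SoluteSource(
        positions=droplet.frame.positions[sol_idx],
        charges=np.full(n_sol, qtot_solute / n_sol),
    )
    mm_idx = droplet.solvent_atom_indices
    if mm_idx.size == 0:
        return 0.0
    kernels = fq_mod.assemble_kernels(droplet, params, model="fq")
    ext = fq_mod.source_fields(source, droplet.frame.positions[mm_idx])
    chi = np.array(
        [params.chi(droplet.topology.atoms[i].element) for i in mm_idx]
    )
    state = fq_mod.solve_polarization(kernels, chi, ext)
    center = droplet.frame.positions[sol_idx].mean(axis=0)
    return float(fq_mod.embedding_potential_at(state, center)[0])


# ------------------------------------------------------------- recovery

@dataclass
class ParameterEstimates:
    e0: float
    dihedral_coupling: float
    stark_slope: float
    sigma: float
    ci: dict
    unidentifiable: set


def recover_parameters(
    sticks,
    ground_truth: GroundTruth,
    n_boot: int = 400,
    seed: int = 0,
) -> ParameterEstimates:
    """Least-squares recovery of (E₀, c, k, σ) from sticks + recorded
    descriptors, with seeded bootstrap percentile CIs."""
    sticks = list(sticks)
    if len(sticks) < 50:
        raise ValueError("need at least 50 sticks for recovery")
    y = np.array([s.energies[0] for s in sticks])
    n = y.size
    X = np.column_stack(
        [np.ones(n), ground_truth.planarity_sq[:n], ground_truth.v_emb[:n]]
    )
    names = ["e0", "dihedral_coupling", "stark_slope"]
    unident = {
        names[j] for j in (1, 2) if X[:, j].std() < 1e-12
    }
    cols = [j for j in range(3) if names[j] not in unident]
    Xr = X[:, cols]
    beta_r, res, *_ = np.linalg.lstsq(Xr, y, rcond=None)
    beta = np.full(3, np.nan)
    for b, j in zip(beta_r, cols):
        beta[j] = b
    resid = y - Xr @ beta_r
    dof = max(n - len(cols), 1)
    sigma = float(np.sqrt(resid @ resid / dof))

    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, len(cols)))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots[b], *_ = np.linalg.lstsq(Xr[idx], y[idx], rcond=None)
    ci = {}
    for col_pos, j in enumerate(cols):
        lo, hi = np.percentile(boots[:, col_pos], [2.5, 97.5])
        ci[names[j]] = (float(lo), float(hi))
    return ParameterEstimates(
        e0=float(beta[0]),
        dihedral_coupling=float(beta[1]),
        stark_slope=float(beta[2]),
        sigma=sigma,
        ci=ci,
        unidentifiable=unident,
    )
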