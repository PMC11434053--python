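"""Dihedral analysis and conformational clustering.

Two clustering routes are provided, mirroring how flexible chromophores are
handled in practice:

* ``assign_phi_clusters`` — four fixed 90°-wide bins of the inter-ring
  torsion Φ: [90, 180) → group 1, [0, 90) → group 2, [−90, 0) → group 3,
  [−180, −90) → group 4 (labels 0–3 in code, in that order).  Bin edges are
  half-open and lower-inclusive so the assignment is total and
  deterministic; Φ = 180° wraps to −180° first.
* ``gromos_cluster`` — neighbor-counting over a pairwise superposed-RMSD
  matrix: the frame with the most neighbors within the cutoff seeds a
  cluster, the cluster is removed, and the procedure repeats.  Ties break to
  the lowest frame index.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .topology import Frame, Trajectory

PHI_GROUP_EDGES = ((90.0, 180.0), (0.0, 90.0), (-90.0, 0.0), (-180.0, -90.0))


@dataclass
class DDFResult:
    """Normalized periodic dihedral distribution: density per degree."""

    centers: np.ndarray     # bin centers, degrees in (−180, 180]
    density: np.ndarray     # probability density per degree
    bin_width: float

    def __post_init__(self) -> None:
        total = float(np.sum(self.density) * self.bin_width)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"DDF not normalized (integral {total})")
        if np.any(self.density < 0):
            raise ValueError("DDF density must be nonnegative")


@dataclass
class ClusterResult:
    labels: np.ndarray              # per-frame group index
    populations: np.ndarray         # fraction per group
    representative_frames: list     # frame index per group (None if empty)
    method: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(float(self.populations.sum()) - 1.0) > 1e-12:
            raise ValueError("populations must sum to 1")


def dihedral_angle(frame: Frame, quad) -> float:
    """Signed torsion (degrees, (−180, 180]) over four atom indices.

    IUPAC convention: cis = 0°, sign by the right-hand rule about the
    central bond.
    """
    i, j, k, l = quad
    if len({i, j, k, l}) != 4:
        raise ValueError("dihedral requires 4 distinct atoms")
    p = frame.positions
    b1, b2, b3 = p[j] - p[i], p[k] - p[j], p[l] - p[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-8 or np.linalg.norm(n2) < 1e-8:
        raise ValueError("dihedral undefined: three atoms are collinear")
    x = n1 @ n2
    y = np.cross(n1, n2) @ (b2 / np.linalg.norm(b2))
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def dihedral_series(traj: Trajectory, name: str) -> np.ndarray:
    """Dihedral angle of every frame for a topology-named torsion."""
    quad = traj.topology.dihedral_defs.get(name)
    if quad is None:
        raise KeyError(f"dihedral {name!r} not defined in topology")
    idx = tuple(traj.topology.index_of(a) for a in quad)
    return np.array([dihedral_angle(f, idx) for f in traj.frames])


def ddf(traj: Trajectory, dihedral_name: str, bin_width: float = 1.0) -> DDFResult:
    """Normalized periodic histogram of a named torsion over all frames."""
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    if abs(round(360.0 / bin_width) * bin_width - 360.0) > 1e-9:
        raise ValueError("bin width must divide 360")
    angles = dihedral_series(traj, dihedral_name)
    nbins = int(round(360.0 / bin_width))
    edges = np.linspace(-180.0, 180.0, nbins + 1)
    counts, _ = np.histogram(angles, bins=edges)
    density = counts / (counts.sum() * bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DDFResult(centers=centers, density=density, bin_width=bin_width)


def wrap_angle(a):
    """Wrap to [−180, 180)."""
    return (np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0


def circular_distance(a, b):
    """Shortest angular distance in degrees, in [0, 180]."""
    return np.abs(wrap_angle(np.asarray(a) - np.asarray(b)))


def assign_phi_clusters(angles) -> ClusterResult:
    """Assign frames to the four Φ groups and compute populations.

    Representative frames minimize the mean circular distance to the other
    members of their group (ties → lowest frame index).
    """
    angles = wrap_angle(angles)
    labels = np.empty(angles.shape[0], dtype=int)
    for g, (lo, hi) in enumerate(PHI_GROUP_EDGES):
        labels[(angles >= lo) & (angles < hi)] = g
    populations = np.array(
        [(labels == g).mean() for g in range(4)]
    )
    reps = []
    for g in range(4):
        members = np.flatnonzero(labels == g)
        if members.size == 0:
            reps.append(None)
            continue
        reps.append(int(members[_central_by_circular(angles[members])]))
    return ClusterResult(
        labels=labels,
        populations=populations,
        representative_frames=reps,
        method="phi_bins",
        parameters={"edges": PHI_GROUP_EDGES},
    )


def _central_by_circular(angles: np.ndarray) -> int:
    """Index (within the group) minimizing mean circular distance to the rest."""
    if angles.size == 1:
        return 0
    d = circular_distance(angles[:, None], angles[None, :])
    mean_d = d.sum(axis=1) / (angles.size - 1)
    return int(np.argmin(mean_d))


def superposed_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """Mass-unweighted least-squares-superposed RMSD between two coordinate sets."""
    from scipy.spatial.transform import Rotation

    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    _, rssd = Rotation.align_vectors(xc, yc)
    return float(rssd / np.sqrt(x.shape[0]))


def pairwise_rmsd_matrix(traj: Trajectory, atom_indices: np.ndarray) -> np.ndarray:
    coords = traj.positions_array()[:, atom_indices, :]
    n = coords.shape[0]
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = superposed_rmsd(coords[i], coords[j])
    return M


def default_heavy_solute_subset(traj: Trajectory) -> np.ndarray:
    """Heavy (non-hydrogen) solute atoms — the default RMSD superposition set."""
    return np.array(
        [
            i
            for i, a in enumerate(traj.topology.atoms)
            if a.is_solute and a.element != "H"
        ],
        dtype=int,
    )


def gromos_cluster(
    traj: Trajectory,
    rmsd_cutoff: float,
    atom_subset: np.ndarray | None = None,
) -> ClusterResult:
    """GROMOS neighbor-counting clustering on superposed RMSD.

    Deterministic: the seeding frame is the one with the most neighbors
    within the cutoff, lowest index on ties.
    """
    if traj.n_frames < 1:
        raise ValueError("empty trajectory")
    if rmsd_cutoff <= 0:
        raise ValueError("cutoff must be positive")
    subset = (
        np.asarray(atom_subset, dtype=int)
        if atom_subset is not None
        else default_heavy_solute_subset(traj)
    )
    if subset.size == 0:
        raise ValueError("empty atom subset")
    if subset.max() >= traj.topology.n_atoms:
        raise ValueError("atom subset references missing atoms")
    M = pairwise_rmsd_matrix(traj, subset)
    n = traj.n_frames
    neighbors = M <= rmsd_cutoff
    remaining = np.ones(n, dtype=bool)
    labels = np.full(n, -1, dtype=int)
    reps: list[int] = []
    cluster = 0
    while remaining.any():
        counts = (neighbors & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(neighbors[center] & remaining)
        labels[members] = cluster
        reps.append(center)
        remaining[members] = False
        cluster += 1
    populations = np.bincount(labels, minlength=cluster) / n
    return ClusterResult(
        labels=labels,
        populations=populations,
        representative_frames=reps,
        method="gromos_rmsd",
        parameters={"cutoff": rmsd_cutoff, "n_subset_atoms": int(subset.size)},
    )


def representative_frame(
    traj: Trajectory,
    labels: np.ndarray,
    group: int,
    metric: str = "circular_dihedral",
    dihedral_name: str | None = None,
    atom_subset: np.ndarray | None = None,
) -> int:
    """Most central member of a group: minimum mean pairwise distance to the
    other members under the chosen metric (ties → lowest frame index)."""
    members = np.flatnonzero(np.asarray(labels) == group)
    if members.size == 0:
        raise ValueError(f"group {group} is empty")
    if members.size == 1:
        return int(members[0])
    if metric == "circular_dihedral":
        if dihedral_name is None:
            raise ValueError("circular metric needs a dihedral name")
        angles = dihedral_series(traj, dihedral_name)[members]
        return int(members[_central_by_circular(angles)])
    if metric == "rmsd":
        subset = (
            np.asarray(atom_subset, dtype=int)
            if atom_subset is not None
            else default_heavy_solute_subset(traj)
        )
        coords = traj.positions_array()[:, subset, :]
        best, best_val = members[0], np.inf
        for i in members:
            val = np.mean(
                [superposed_rmsd(coords[i], coords[j]) for j in members if j != i]
            )
            if val < best_val - 1e-15:
                best, best_val = i, val
        return int(best)
    raise ValueError(f"unknown metric {metric!r}")
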