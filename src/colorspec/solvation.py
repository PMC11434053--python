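"""Radial distribution functions, shell extrema, and running coordination numbers.

Intermolecular RDFs follow the standard convention

    g(r) = ⟨histogram of A–B minimum-image distances⟩ / (N_A · 4πr²Δr · ρ_B)

with ρ_B the mean number density of the B selection over the box, so that an
ideal gas gives g → 1.  Intramolecular pair correlations (pairs restricted to
the same molecule) are reported with shell-volume normalization only — a
per-molecule pair density, not referenced to a bulk density.

Extremum detection (first peak / first minimum) operates on a centered 3-bin
moving average of g; the reported position is always a bin center of the raw
grid, and the smoothing is never applied to the reported g itself.

The running coordination number is the shell integral
n(r) = 4π ρ_B ∫₀ʳ g(s) s² ds, evaluated by trapezoidal quadrature.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .topology import Topology, Trajectory


@dataclass
class RDFResult:
    r: np.ndarray                # bin centers, Å
    g: np.ndarray
    bin_width: float
    pair_spec: tuple
    rho_B: float | None          # Å⁻³; None for intramolecular mode
    frames_used: int
    mode: str = "intermolecular"

    def __post_init__(self) -> None:
        if np.any(self.g < 0):
            raise ValueError("g(r) must be nonnegative")


@dataclass
class CoordinationProfile:
    r: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.n) < -1e-12):
            raise ValueError("running coordination number must be nondecreasing")


def select_sites(topology: Topology, spec: str) -> np.ndarray:
    """Mini selection language: ``solute:X`` / ``solvent:X`` where X is a
    site label (e.g. ``H7``), an element, or ``H_donor`` for all labeled
    solute hydrogens."""
    try:
        scope, what = spec.split(":", 1)
    except ValueError:
        raise ValueError(f"selection {spec!r} must look like 'solute:H7'") from None
    if scope not in ("solute", "solvent"):
        raise ValueError(f"unknown selection scope {scope!r}")
    want_solute = scope == "solute"
    out = []
    for i, a in enumerate(topology.atoms):
        if a.is_solute != want_solute:
            continue
        if what == "H_donor":
            if a.element == "H" and a.site_label is not None:
                out.append(i)
        elif a.site_label == what or a.element == what:
            out.append(i)
    return np.array(out, dtype=int)


def _min_image_dist(dA: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is not None:
        dA = dA - box * np.round(dA / box)
    return np.linalg.norm(dA, axis=-1)


def rdf(
    traj: Trajectory,
    siteA,
    siteB,
    r_max: float = 10.0,
    bin_width: float = 0.02,
    mode: str = "intermolecular",
) -> RDFResult:
    """Pair correlation between two atom selections.

    ``siteA``/``siteB`` are atom-index arrays or selection strings
    understood by :func:`select_sites`.
    """
    topo = traj.topology
    if isinstance(siteA, str):
        siteA = select_sites(topo, siteA)
    if isinstance(siteB, str):
        siteB = select_sites(topo, siteB)
    siteA = np.asarray(siteA, dtype=int)
    siteB = np.asarray(siteB, dtype=int)
    if siteA.size == 0 or siteB.size == 0:
        raise ValueError("empty selection")
    if mode not in ("intermolecular", "intramolecular"):
        raise ValueError(f"unknown mode {mode!r}")

    mol = np.array([a.molecule_id for a in topo.atoms])
    same_mol = mol[siteA][:, None] == mol[siteB][None, :]
    same_atom = siteA[:, None] == siteB[None, :]
    if mode == "intermolecular":
        pair_mask = ~same_mol
    else:
        pair_mask = same_mol & ~same_atom
    if not pair_mask.any():
        raise ValueError("no pairs selected under the requested mode")

    nbins = int(round(r_max / bin_width))
    edges = np.linspace(0.0, nbins * bin_width, nbins + 1)
    counts = np.zeros(nbins)
    rho_sum = 0.0
    for frame in traj.frames:
        box = frame.box
        if box is not None and r_max > box.min() / 2:
            raise ValueError(
                f"r_max {r_max} Å exceeds half the smallest box edge"
            )
        d = frame.positions[siteA][:, None, :] - frame.positions[siteB][None, :, :]
        dist = _min_image_dist(d, box)[pair_mask]
        h, _ = np.histogram(dist, bins=edges)
        counts += h
        if box is not None:
            rho_sum += siteB.size / float(np.prod(box))
    n_frames = traj.n_frames
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 * np.pi * centers**2 * bin_width
    per_A = counts / (n_frames * siteA.size * shell)
    if mode == "intermolecular":
        if rho_sum == 0.0:
            raise ValueError("intermolecular RDF needs a periodic box for ρ_B")
        rho_B = rho_sum / n_frames
        g = per_A / rho_B
    else:
        rho_B = None
        g = per_A
    return RDFResult(
        r=centers,
        g=g,
        bin_width=bin_width,
        pair_spec=(siteA, siteB),
        rho_B=rho_B,
        frames_used=n_frames,
        mode=mode,
    )


def _smoothed(g: np.ndarray) -> np.ndarray:
    """Centered 3-bin moving average (edges keep raw values)."""
    s = g.copy()
    s[1:-1] = (g[:-2] + g[1:-1] + g[2:]) / 3.0
    return s


def first_peak(result: RDFResult) -> float:
    """Position (bin center, Å) of the first interior local maximum of g."""
    s = _smoothed(result.g)
    for i in range(1, s.size - 1):
        if s[i] > s[i - 1] and s[i] >= s[i + 1] and s[i] > 0:
            return float(result.r[i])
    raise ValueError("g(r) has no interior local maximum")


def first_minimum(result: RDFResult) -> float:
    """Position of the first local minimum after the first peak (leftmost bin
    of a flat valley)."""
    s = _smoothed(result.g)
    ipk = int(np.flatnonzero(result.r == first_peak(result))[0])
    for i in range(ipk + 1, s.size - 1):
        if s[i] < s[i - 1] and s[i] <= s[i + 1]:
            return float(result.r[i])
    raise ValueError(
        "no local minimum after the first peak before r_max; increase r_max"
    )


def coordination_profile(result: RDFResult) -> CoordinationProfile:
    """Running coordination number n(r) on the RDF grid."""
    if result.rho_B is None:
        raise ValueError("coordination numbers require an intermolecular RDF")
    r = np.concatenate([[0.0], result.r])
    integrand = np.concatenate([[0.0], result.g * result.r**2])
    n = 4.0 * np.pi * result.rho_B * np.concatenate(
        [[0.0], np.cumsum(np.diff(r) * 0.5 * (integrand[:-1] + integrand[1:]))]
    )
    return CoordinationProfile(r=r, n=n)


def rcn(result: RDFResult, r_limit: float) -> float:
    """n(r_limit): neighbors of B around an A site within r_limit."""
    if r_limit <= 0:
        raise ValueError("r_limit must be positive")
    if r_limit > result.r[-1] + result.bin_width / 2:
        raise ValueError("r_limit exceeds the RDF grid")
    prof = coordination_profile(result)
    return float(np.interp(r_limit, prof.r, prof.n))
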