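"""Stick-to-band spectral assembly, averaging, convergence, and shifts.

Per-snapshot vertical excitations (energy in eV, dimensionless oscillator
strength) are broadened with unit-area Gaussians of fixed FWHM on the energy
axis and averaged over snapshots; configuration-to-configuration scatter of
the sticks is what produces the inhomogeneous width of the final band on top
of the intrinsic FWHM.  Normalization to unit maximum, when requested, is
applied once at the end, after averaging.
"""
from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

from .units import HC_EV_NM, ev_to_nm, nm_ev, nm_to_ev  # noqa: F401 (re-export)

#: σ = FWHM / √(8 ln 2)
FWHM_TO_SIGMA = 1.0 / math.sqrt(8.0 * math.log(2.0))


@dataclass
class StickSpectrum:
    """Vertical excitations of one snapshot."""

    energies: np.ndarray            # eV
    strengths: np.ndarray           # oscillator strengths, ≥ 0
    snapshot_id: int | str | None = None
    method: str = ""
    max_states: int = 10

    def __post_init__(self) -> None:
        self.energies = np.atleast_1d(np.asarray(self.energies, dtype=float))
        self.strengths = np.atleast_1d(np.asarray(self.strengths, dtype=float))
        if self.energies.shape != self.strengths.shape:
            raise ValueError("energies and strengths must match")
        if np.any(self.energies <= 0):
            raise ValueError("excitation energies must be positive")
        if np.any(self.strengths < 0):
            raise ValueError("oscillator strengths must be nonnegative")
        if self.energies.size > self.max_states:
            raise ValueError(
                f"{self.energies.size} states exceed max_states={self.max_states}"
            )


@dataclass
class ConvolvedSpectrum:
    energy: np.ndarray              # uniform eV grid
    intensity: np.ndarray
    fwhm: float
    normalized: bool = False
    n_snapshots: int = 1
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be nonnegative")

    @property
    def grid_step(self) -> float:
        return float(self.energy[1] - self.energy[0])


def convolve_sticks(
    sticks: StickSpectrum,
    fwhm: float,
    grid_step: float = 0.005,
    grid: np.ndarray | None = None,
) -> ConvolvedSpectrum:
    """Broaden sticks with unit-area Gaussians of the given FWHM (eV).

    The default grid spans the sticks ± max(1 eV, 4·FWHM) so the band area
    equals Σ fₖ to better than 10⁻³ relative.
    """
    if sticks.energies.size == 0:
        raise ValueError("empty stick list")
    if fwhm <= 0:
        raise ValueError("FWHM must be positive")
    if grid_step > fwhm / 10 + 1e-15:
        raise ValueError("grid step must be ≤ FWHM/10")
    sigma = fwhm * FWHM_TO_SIGMA
    if grid is None:
        margin = max(1.0, 4.0 * fwhm)
        lo = sticks.energies.min() - margin
        hi = sticks.energies.max() + margin
        grid = np.arange(lo, hi + grid_step / 2, grid_step)
    diff = grid[:, None] - sticks.energies[None, :]
    gauss = np.exp(-0.5 * (diff / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))
    intensity = gauss @ sticks.strengths
    return ConvolvedSpectrum(energy=grid, intensity=intensity, fwhm=fwhm)


def _common_grid(spectra) -> np.ndarray:
    first = spectra[0].energy
    if all(
        s.energy.size == first.size and np.allclose(s.energy, first)
        for s in spectra[1:]
    ):
        return first
    steps = {round(s.grid_step, 12) for s in spectra}
    step = min(steps)
    lo = min(s.energy[0] for s in spectra)
    hi = max(s.energy[-1] for s in spectra)
    return np.arange(lo, hi + step / 2, step)


def _resample(spectrum: ConvolvedSpectrum, grid: np.ndarray) -> np.ndarray:
    if spectrum.energy.size == grid.size and np.allclose(spectrum.energy, grid):
        return spectrum.intensity
    return np.interp(grid, spectrum.energy, spectrum.intensity, left=0.0, right=0.0)


def average_spectra(spectra, normalize: bool = False) -> ConvolvedSpectrum:
    """Pointwise mean over snapshots (linear resampling onto the union grid
    when grids differ); optional unit-maximum normalization at the end."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra to average")
    grid = _common_grid(spectra)
    mean = np.mean([_resample(s, grid) for s in spectra], axis=0)
    if normalize and mean.max() > 0:
        mean = mean / mean.max()
    return ConvolvedSpectrum(
        energy=grid,
        intensity=mean,
        fwhm=spectra[0].fwhm,
        normalized=normalize,
        n_snapshots=sum(s.n_snapshots for s in spectra),
    )


def convergence_curve(
    spectra,
    subset_sizes,
    seed: int,
    n_resamples: int = 20,
    reference: ConvolvedSpectrum | None = None,
) -> dict[int, float]:
    """Mean max-abs distance between subset averages and the full average.

    Subsets are drawn without replacement with a seeded generator; by default
    the reference is the average over the full set.
    """
    spectra = list(spectra)
    total = len(spectra)
    rng = np.random.default_rng(seed)
    full = reference if reference is not None else average_spectra(spectra)
    grid = full.energy
    full_i = _resample(full, grid)
    out: dict[int, float] = {}
    for size in subset_sizes:
        if size > total:
            raise ValueError(f"subset size {size} exceeds {total} spectra")
        dists = []
        reps = 1 if size == total else n_resamples
        for _ in range(reps):
            pick = rng.choice(total, size=size, replace=False)
            sub = average_spectra([spectra[i] for i in pick])
            dists.append(float(np.max(np.abs(_resample(sub, grid) - full_i))))
        out[int(size)] = float(np.mean(dists))
    return out


def cluster_weighted_spectrum(
    per_cluster_spectra, populations, normalize: bool = False
) -> ConvolvedSpectrum:
    """Population-weighted combination of per-conformer spectra."""
    spectra = list(per_cluster_spectra)
    w = np.asarray(populations, dtype=float)
    if w.size != len(spectra):
        raise ValueError("one weight per cluster spectrum required")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"populations sum to {w.sum()}, expected 1")
    grid = _common_grid(spectra)
    combined = np.sum([wi * _resample(s, grid) for wi, s in zip(w, spectra)], axis=0)
    if normalize and combined.max() > 0:
        combined = combined / combined.max()
    return ConvolvedSpectrum(
        energy=grid,
        intensity=combined,
        fwhm=spectra[0].fwhm,
        normalized=normalize,
        n_snapshots=sum(s.n_snapshots for s in spectra),
    )


def peak_positions(spectrum: ConvolvedSpectrum, n_peaks: int | None = None):
    """Local maxima sorted by height: list of (energy eV, wavelength nm,
    relative height).  Returns fewer than requested (flagged) if the spectrum
    has fewer maxima."""
    from scipy.signal import find_peaks

    idx, _ = find_peaks(spectrum.intensity)
    if idx.size == 0:
        spectrum.flags["no_peaks"] = True
        return []
    order = idx[np.argsort(spectrum.intensity[idx])[::-1]]
    if n_peaks is not None:
        if order.size < n_peaks:
            spectrum.flags["fewer_peaks_than_requested"] = True
        order = order[:n_peaks]
    top = spectrum.intensity[order[0]]
    return [
        (
            float(spectrum.energy[i]),
            ev_to_nm(float(spectrum.energy[i])),
            float(spectrum.intensity[i] / top),
        )
        for i in order
    ]


def solvatochromic_shift(spectrum_a: ConvolvedSpectrum, spectrum_b: ConvolvedSpectrum):
    """Main-peak shift of b relative to a: (Δλ nm, ΔE eV), both positive for
    a red shift (b at longer wavelength / lower energy than a).

    ΔE is taken on the energy axis and Δλ on the wavelength axis
    independently; the two are not cross-converted.
    """
    peaks_a = peak_positions(spectrum_a, 1)
    peaks_b = peak_positions(spectrum_b, 1)
    if not peaks_a or not peaks_b:
        raise ValueError("both spectra need a main peak")
    ea, la, _ = peaks_a[0]
    eb, lb, _ = peaks_b[0]
    return (lb - la, ea - eb)


def read_sticks_tsv(path) -> list[StickSpectrum]:
    """Read sticks from TSV: columns ``snapshot_id energy_eV strength`` (or
    2 columns for a single snapshot)."""
    raw = np.loadtxt(path, ndmin=2)
    if raw.shape[1] == 2:
        return [StickSpectrum(raw[:, 0], raw[:, 1], snapshot_id=0)]
    out = []
    for sid in np.unique(raw[:, 0]):
        rows = raw[raw[:, 0] == sid]
        out.append(
            StickSpectrum(rows[:, 1], rows[:, 2], snapshot_id=int(sid))
        )
    return out


def write_spectrum_tsv(spectrum: ConvolvedSpectrum, path) -> None:
    wl = HC_EV_NM / spectrum.energy
    np.savetxt(
        path,
        np.column_stack([spectrum.energy, wl, spectrum.intensity]),
        header="energy_eV wavelength_nm intensity",
        fmt="%.6f",
    )
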