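"""Physical constants and unit conversions.

All conversion constants used anywhere in the package live here, so that
numerical results are reproducible bit-for-bit given a configuration.
Internal convention: lengths in Å at module interfaces, atomic units
(Bohr, Hartree, e) inside the electrostatics solver, energies in eV on
the spectroscopy side.
"""
from __future__ import annotations

#: 1 Å expressed in Bohr.
BOHR_PER_ANGSTROM = 1.8897259886
#: 1 Hartree expressed in eV.
EV_PER_HARTREE = 27.211386
#: hc in eV·nm: E[eV] = HC_EV_NM / λ[nm].
HC_EV_NM = 1239.84193
#: 1 eV expressed in kcal/mol.
KCALMOL_PER_EV = 23.0605


def nm_to_ev(wavelength_nm: float) -> float:
    """Photon energy in eV for a wavelength in nm."""
    if wavelength_nm <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength_nm}")
    return HC_EV_NM / wavelength_nm


def ev_to_nm(energy_ev: float) -> float:
    """Photon wavelength in nm for an energy in eV."""
    if energy_ev <= 0:
        raise ValueError(f"energy must be positive, got {energy_ev}")
    return HC_EV_NM / energy_ev


def nm_ev(value: float, direction: str) -> float:
    """Convert between nm and eV.

    Parameters
    ----------
    value : float
        Positive wavelength (nm) or energy (eV).
    direction : {"nm_to_ev", "ev_to_nm"}

    The map E = hc/λ is an involution pair: ``nm_ev(nm_ev(x, a), b) == x``
    to machine precision.
    """
    if direction == "nm_to_ev":
        return nm_to_ev(value)
    if direction == "ev_to_nm":
        return ev_to_nm(value)
    raise ValueError(f"unknown direction {direction!r}")


def angstrom_to_bohr(x):
    return x * BOHR_PER_ANGSTROM


def bohr_to_angstrom(x):
    return x / BOHR_PER_ANGSTROM
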