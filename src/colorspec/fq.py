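"""Fluctuating-charge (FQ) and fluctuating-charge-and-dipole (FQFμ) solver.

The MM environment of a droplet carries one fluctuating charge per atom
(FQ), optionally augmented by an induced point dipole per atom (FQFμ).
Charges minimize the electronegativity-equalization energy

    E(q, μ) = χᵀq + ½ qᵀ T_qq q + qᵀ T_qμ μ + ½ μᵀ T_μμ μ + qᵀ V(D) − μᵀ E(D)

subject to a fixed total charge Qtot per molecule, enforced through Lagrange
multipliers λ.  Stationarity gives the symmetric bordered linear system

    [ T_qq   1λ   T_qμ ] [q]   [ −χ  ]   [ −V(D) ]
    [ 1λᵀ    0    0    ] [λ] = [ Qtot] + [   0   ]
    [ T_qμᵀ  0    T_μμ ] [μ]   [  0  ]   [  E(D) ]

where V(D), E(D) are the external potential and field at the MM sites — here
produced classically by a point-charge/point-dipole surrogate of the solute
density.  The FQ system is the same with all dipole rows/columns discarded.

Kernels (selectable, defaults noted):

* charge–charge: Ohno-smeared Coulomb, J_ij = 1/√(r² + d²) with
  d_ij = 2/(η_i + η_j) (default), or bare 1/r; diagonal η_i.
* charge–dipole / dipole–dipole: point multipoles (default) or Gaussian
  (Thole-style) damped, with per-pair width a_ij = A·(α_i α_j)^{1/6}.
* dipole self-term: α_i⁻¹·I.

Everything in this module works in atomic units internally (Bohr, Hartree,
e); positions cross the interface in Å.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
import math

import numpy as np
import scipy.linalg

from .topology import Droplet
from .units import angstrom_to_bohr

#: condition-number threshold above which the bordered solve is refused
COND_LIMIT = 1e12
#: per-molecule charge-sum tolerance enforced after every solve (e)
CONSTRAINT_TOL = 1e-10


@dataclass
class FQParams:
    """Per-atom-type χ (a.u. energy/charge), η (a.u. energy/charge²) and
    optional α (a.u. volume).  α absent or zero ⇒ pure FQ type."""

    table: dict[str, tuple]  # type -> (chi, eta) or (chi, eta, alpha)
    qq_kernel: str = "ohno"          # "ohno" | "coulomb"
    mu_damping: str = "point"        # "point" | "gaussian"
    mu_damping_scale: float = 1.0    # A in a_ij = A (α_i α_j)^{1/6}

    def __post_init__(self) -> None:
        for t, row in self.table.items():
            chi, eta = row[0], row[1]
            alpha = row[2] if len(row) > 2 else 0.0
            if eta <= 0:
                raise ValueError(f"hardness must be positive for type {t!r}")
            if alpha < 0:
                raise ValueError(f"polarizability must be ≥ 0 for type {t!r}")

    def chi(self, t: str) -> float:
        return self._row(t)[0]

    def eta(self, t: str) -> float:
        return self._row(t)[1]

    def alpha(self, t: str) -> float:
        row = self._row(t)
        return row[2] if len(row) > 2 else 0.0

    def _row(self, t: str):
        try:
            return self.table[t]
        except KeyError:
            raise KeyError(f"no FQ parameters for atom type {t!r}") from None

    @classmethod
    def from_file(cls, path, **kw) -> "FQParams":
        """Plain-text table ``type χ η [α]`` (a.u.), ``#`` comments."""
        table = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                parts = line.split()
                table[parts[0]] = tuple(float(x) for x in parts[1:])
        return cls(table, **kw)

    @classmethod
    def builtin(cls, name: str, **kw) -> "FQParams":
        """Shipped parameter sets: ``water_fq``, ``water_fqmu``, ``ethanol_fq``."""
        ref = resources.files("colorspec") / "params" / f"{name}.tsv"
        with resources.as_file(ref) as path:
            return cls.from_file(path, **kw)


@dataclass
class SoluteSource:
    """Classical surrogate of the QM charge density: point charges and
    (optionally) point dipoles sitting on the solute atoms.

    positions: Å; charges: e; dipoles: a.u. (e·Bohr)."""

    positions: np.ndarray
    charges: np.ndarray
    dipoles: np.ndarray | None = None
    method: str = "point_charges"

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.charges = np.atleast_1d(np.asarray(self.charges, dtype=float))
        if self.dipoles is not None:
            self.dipoles = np.atleast_2d(np.asarray(self.dipoles, dtype=float))
        if not np.all(np.isfinite(self.positions)) or not np.all(
            np.isfinite(self.charges)
        ):
            raise ValueError("source must be finite")


@dataclass
class ExternalFieldAtSites:
    """Potential V (a.u.) and field E (a.u.) at each MM site."""

    V: np.ndarray
    E: np.ndarray

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        if self.E.shape != (self.V.shape[0], 3):
            raise ValueError("E must be (n, 3) matching V")


@dataclass
class KernelBlocks:
    Tqq: np.ndarray
    constraint: np.ndarray           # (n, m) molecule indicator
    qtot: np.ndarray                 # (m,)
    Tqmu: np.ndarray | None = None   # (n, 3n)
    Tmumu: np.ndarray | None = None  # (3n, 3n)
    model: str = "fq"
    positions_bohr: np.ndarray | None = None

    @property
    def n_atoms(self) -> int:
        return self.Tqq.shape[0]

    @property
    def n_molecules(self) -> int:
        return self.constraint.shape[1]

    def bordered_matrix(self) -> np.ndarray:
        n, m = self.n_atoms, self.n_molecules
        if self.model == "fq":
            A = np.zeros((n + m, n + m))
            A[:n, :n] = self.Tqq
            A[:n, n:] = self.constraint
            A[n:, :n] = self.constraint.T
            return A
        size = n + m + 3 * n
        A = np.zeros((size, size))
        A[:n, :n] = self.Tqq
        A[:n, n : n + m] = self.constraint
        A[n : n + m, :n] = self.constraint.T
        A[:n, n + m :] = self.Tqmu
        A[n + m :, :n] = self.Tqmu.T
        A[n + m :, n + m :] = self.Tmumu
        return A


@dataclass
class PolarizationState:
    """Solved induced charges (e), dipoles (a.u.) and multipliers, together
    with the MM site positions (Å) that generated them."""

    q: np.ndarray
    mu: np.ndarray
    lagrange: np.ndarray
    positions: np.ndarray
    model: str = "fq"


def _pairwise(positions_bohr: np.ndarray):
    d = positions_bohr[:, None, :] - positions_bohr[None, :, :]
    r = np.linalg.norm(d, axis=-1)
    return d, r


def source_fields(source: SoluteSource, mm_positions: np.ndarray) -> ExternalFieldAtSites:
    """Potential and field (a.u.) of the solute surrogate at MM sites (Å in)."""
    mm = angstrom_to_bohr(np.atleast_2d(np.asarray(mm_positions, dtype=float)))
    src = angstrom_to_bohr(source.positions)
    d = mm[:, None, :] - src[None, :, :]          # site i, source a
    r = np.linalg.norm(d, axis=-1)
    too_close = r < angstrom_to_bohr(1e-6)
    if np.any(too_close):
        i, a = np.argwhere(too_close)[0]
        raise ValueError(f"MM site {i} coincides with source site {a}")
    inv_r = 1.0 / r
    V = (source.charges * inv_r).sum(axis=1)
    E = (source.charges[None, :, None] * d * inv_r[..., None] ** 3).sum(axis=1)
    if source.dipoles is not None:
        mu = source.dipoles
        mudotr = np.einsum("ak,iak->ia", mu, d)
        V += (mudotr * inv_r**3).sum(axis=1)
        # E = (3 (μ·r̂) r̂ − μ) / r³
        rhat = d * inv_r[..., None]
        mudotrhat = np.einsum("ak,iak->ia", mu, rhat)
        E += (
            3 * mudotrhat[..., None] * rhat * inv_r[..., None] ** 3
            - mu[None, :, :] * inv_r[..., None] ** 3
        ).sum(axis=1)
    return ExternalFieldAtSites(V=V, E=E)


def _gaussian_f1(u: np.ndarray) -> np.ndarray:
    """erf(u) − (2u/√π) e^{−u²}: screening factor for r/r³ kernels."""
    from scipy.special import erf

    return erf(u) - (2 * u / math.sqrt(math.pi)) * np.exp(-(u**2))


def assemble_kernels(droplet: Droplet, params: FQParams, model: str = "fq") -> KernelBlocks:
    """Build T_qq, T_qμ, T_μμ and the per-molecule constraint block for the
    solvent atoms of a droplet."""
    if model not in ("fq", "fqmu"):
        raise ValueError(f"unknown model {model!r}")
    idx = droplet.solvent_atom_indices
    if idx.size == 0:
        raise ValueError("droplet has no solvent atoms")
    atoms = [droplet.topology.atoms[i] for i in idx]
    types = [a.element for a in atoms]
    eta = np.array([params.eta(t) for t in types])
    pos = angstrom_to_bohr(droplet.frame.positions[idx])
    n = len(atoms)

    d, r = _pairwise(pos)
    off = ~np.eye(n, dtype=bool)
    Tqq = np.zeros((n, n))
    if params.qq_kernel == "ohno":
        dij = 2.0 / (eta[:, None] + eta[None, :])
        Tqq[off] = 1.0 / np.sqrt(r[off] ** 2 + dij[off] ** 2)
    elif params.qq_kernel == "coulomb":
        Tqq[off] = 1.0 / r[off]
    else:
        raise ValueError(f"unknown qq kernel {params.qq_kernel!r}")
    Tqq[np.diag_indices(n)] = eta

    mol_ids = sorted({a.molecule_id for a in atoms})
    mol_pos = {m: k for k, m in enumerate(mol_ids)}
    C = np.zeros((n, len(mol_ids)))
    for i, a in enumerate(atoms):
        C[i, mol_pos[a.molecule_id]] = 1.0
    qtot = np.array([droplet.topology.qtot(m) for m in mol_ids])

    Tqmu = Tmumu = None
    if model == "fqmu":
        alpha = np.array([params.alpha(t) for t in types])
        if np.any(alpha <= 0):
            bad = types[int(np.argmin(alpha))]
            raise ValueError(
                f"FQFμ requires α > 0 for every type (α = 0 for {bad!r})"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            inv_r = np.where(off, 1.0 / np.where(off, r, 1.0), 0.0)
        if params.mu_damping == "gaussian":
            a_ij = params.mu_damping_scale * (alpha[:, None] * alpha[None, :]) ** (1 / 6)
            u = np.where(off, r / a_ij, 0.0)
            f1 = _gaussian_f1(u)
            g = (2 * u / math.sqrt(math.pi)) * np.exp(-(u**2))
            extra = 2 * u**2 * g
        elif params.mu_damping == "point":
            f1 = off.astype(float)
            extra = np.zeros((n, n))
        else:
            raise ValueError(f"unknown dipole damping {params.mu_damping!r}")
        # charge i – dipole j coupling: B_ij = f1 · (r_i − r_j)/r³
        B = f1[..., None] * d * inv_r[..., None] ** 3
        Tqmu = B.reshape(n, 3 * n)  # (i, j, xyz) -> (i, 3j+xyz)
        # dipole–dipole: T_ij = (δ − 3 r̂r̂ᵀ) f1 / r³ + extra · r̂r̂ᵀ / r³
        rhat = d * inv_r[..., None]
        outer = rhat[..., :, None] * rhat[..., None, :]
        eye = np.eye(3)
        Tij = (
            (eye[None, None] - 3 * outer) * (f1 * inv_r**3)[..., None, None]
            + outer * (extra * inv_r**3)[..., None, None]
        )
        Tmumu = np.zeros((3 * n, 3 * n))
        for i in range(n):
            for j in range(n):
                if i == j:
                    Tmumu[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] = eye / alpha[i]
                else:
                    Tmumu[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = Tij[i, j]
    return KernelBlocks(
        Tqq=Tqq,
        constraint=C,
        qtot=qtot,
        Tqmu=Tqmu,
        Tmumu=Tmumu,
        model=model,
        positions_bohr=pos,
    )


def solve_polarization(
    kernels: KernelBlocks,
    chi: np.ndarray,
    ext: ExternalFieldAtSites | None = None,
) -> PolarizationState:
    """Solve the constrained polarization system for charges, multipliers and
    (for FQFμ) dipoles."""
    n, m = kernels.n_atoms, kernels.n_molecules
    chi = np.asarray(chi, dtype=float)
    if chi.shape != (n,):
        raise ValueError(f"chi has shape {chi.shape}, expected ({n},)")
    if ext is not None and ext.V.shape[0] != n:
        raise ValueError("external field dimension mismatch")
    A = kernels.bordered_matrix()
    rhs = np.zeros(A.shape[0])
    rhs[:n] = -chi
    rhs[n : n + m] = kernels.qtot
    if ext is not None:
        rhs[:n] -= ext.V
        if kernels.model == "fqmu":
            rhs[n + m :] = ext.E.ravel()
    if A.shape[0] <= 600:
        cond = np.linalg.cond(A)
        if not np.isfinite(cond) or cond > COND_LIMIT:
            raise np.linalg.LinAlgError(
                f"bordered polarization matrix ill-conditioned (cond={cond:.2e})"
            )
    x = scipy.linalg.solve(A, rhs, assume_a="sym")
    q = x[:n]
    lam = x[n : n + m]
    mu = (
        x[n + m :].reshape(n, 3)
        if kernels.model == "fqmu"
        else np.zeros((n, 3))
    )
    resid = np.abs(kernels.constraint.T @ q - kernels.qtot)
    if np.any(resid > 1e3 * CONSTRAINT_TOL):
        raise np.linalg.LinAlgError(
            f"charge constraint violated (max residual {resid.max():.2e} e)"
        )
    from .units import bohr_to_angstrom

    positions = (
        bohr_to_angstrom(kernels.positions_bohr)
        if kernels.positions_bohr is not None
        else np.zeros((n, 3))
    )
    return PolarizationState(q=q, mu=mu, lagrange=lam, positions=positions, model=kernels.model)


def interaction_energy(
    state: PolarizationState, ext: ExternalFieldAtSites, model: str
) -> float:
    """Classical QM/MM interaction energy: Σ qV (FQ) − Σ μ·E (FQFμ), a.u."""
    if state.q.shape[0] != ext.V.shape[0]:
        raise ValueError("state/field dimension mismatch")
    if model == "fq":
        if np.any(state.mu != 0):
            raise ValueError("FQ energy requested for a state with nonzero dipoles")
        return float(state.q @ ext.V)
    if model == "fqmu":
        return float(state.q @ ext.V - np.einsum("ij,ij->", state.mu, ext.E))
    raise ValueError(f"unknown model {model!r}")


def embedding_potential_at(state: PolarizationState, points: np.ndarray) -> np.ndarray:
    """Electrostatic potential (a.u.) of the induced charges and dipoles at
    arbitrary probe points (Å) — the classical evaluation of the embedding
    potential v_emb that perturbs the chromophore Hamiltonian."""
    pts = angstrom_to_bohr(np.atleast_2d(np.asarray(points, dtype=float)))
    mm = angstrom_to_bohr(np.atleast_2d(state.positions))
    d = pts[:, None, :] - mm[None, :, :]
    r = np.linalg.norm(d, axis=-1)
    if np.any(r < angstrom_to_bohr(1e-6)):
        p, i = np.argwhere(r < angstrom_to_bohr(1e-6))[0]
        raise ValueError(f"probe point {p} coincides with MM atom {i}")
    inv_r = 1.0 / r
    v = (state.q * inv_r).sum(axis=1)
    if np.any(state.mu != 0):
        v += (np.einsum("jk,pjk->pj", state.mu, d) * inv_r**3).sum(axis=1)
    return v
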