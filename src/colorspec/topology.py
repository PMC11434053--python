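"""Core in-memory containers: atoms, topologies, frames, trajectories, droplets.

Lengths are Å everywhere in this module.  A :class:`Topology` partitions its
atoms into molecules; the solute (the chromophore) is a flagged subset of
molecules, everything else — solvent and counterions — is treated as
environment.  Named dihedrals (the inter-ring torsion Φ and the hydroxyl
torsions δ1–δ5 in the anthocyanidin case) are stored as atom-id quadruples on
the topology.
"""
from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np


@dataclass(frozen=True)
class Atom:
    """One classical site.

    ``site_label`` carries the chemistry-facing name of hydrogen-bond donor /
    acceptor sites (e.g. donor hydrogens "H7"–"H11", acceptor oxygens
    "O1"–"O6"); it is optional for atoms that never appear in a selection.
    """

    atom_id: int
    element: str
    molecule_id: int
    is_solute: bool = False
    site_label: str | None = None


@dataclass
class Topology:
    atoms: list[Atom]
    #: net charge (e) per molecule, used as the Qtot constraint of the
    #: polarization solver; defaults to 0 for unlisted molecules.
    qtot_per_molecule: dict[int, float] = field(default_factory=dict)
    #: named dihedrals: name -> (i, j, k, l) atom ids.
    dihedral_defs: dict[str, tuple[int, int, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [a.atom_id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate atom_id in topology")
        for name, quad in self.dihedral_defs.items():
            if len(set(quad)) != 4:
                raise ValueError(f"dihedral {name!r} must reference 4 distinct atoms")
            known = set(ids)
            if not set(quad) <= known:
                raise ValueError(f"dihedral {name!r} references unknown atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def molecules(self) -> dict[int, list[int]]:
        """molecule_id -> ordered atom_id list (order of appearance)."""
        mols: dict[int, list[int]] = {}
        for a in self.atoms:
            mols.setdefault(a.molecule_id, []).append(a.atom_id)
        return mols

    def qtot(self, molecule_id: int) -> float:
        return self.qtot_per_molecule.get(molecule_id, 0.0)

    @property
    def solute_atom_ids(self) -> np.ndarray:
        return np.array([a.atom_id for a in self.atoms if a.is_solute], dtype=int)

    @property
    def solvent_molecule_ids(self) -> list[int]:
        out: list[int] = []
        seen: set[int] = set()
        for a in self.atoms:
            if not a.is_solute and a.molecule_id not in seen:
                seen.add(a.molecule_id)
                out.append(a.molecule_id)
        return out

    def elements(self) -> np.ndarray:
        return np.array([a.element for a in self.atoms])

    def index_of(self, atom_id: int) -> int:
        """Positional index of an atom_id (ids are not required to be dense)."""
        idx = self.__dict__.get("_id_index")
        if idx is None:
            idx = {a.atom_id: i for i, a in enumerate(self.atoms)}
            self.__dict__["_id_index"] = idx
        try:
            return idx[atom_id]
        except KeyError:
            raise KeyError(atom_id) from None


@dataclass
class Frame:
    """Positions (N, 3) in Å plus an optional orthorhombic box (3 edge lengths)."""

    positions: np.ndarray
    box: np.ndarray | None = None
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (N, 3)")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise ValueError("box must be 3 positive edge lengths")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]


@dataclass
class Trajectory:
    topology: Topology
    frames: list[Frame]

    def __post_init__(self) -> None:
        n = self.topology.n_atoms
        for i, f in enumerate(self.frames):
            if f.n_atoms != n:
                raise ValueError(
                    f"frame {i} has {f.n_atoms} atoms, topology has {n}"
                )
        times = [f.time for f in self.frames]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be nondecreasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def positions_array(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) stacked positions."""
        return np.stack([f.positions for f in self.frames])


@dataclass
class Droplet:
    """A finite spherical cut: whole solute plus whole solvent molecules whose
    reference atom lies within ``radius`` of ``center``.  No box."""

    topology: Topology
    frame: Frame
    radius: float
    center: np.ndarray
    source_frame_index: int | None = None

    def __post_init__(self) -> None:
        if self.frame.box is not None:
            raise ValueError("droplet frames carry no periodic box")
        self.center = np.asarray(self.center, dtype=float)

    @property
    def n_atoms(self) -> int:
        return self.frame.n_atoms

    @property
    def solvent_atom_indices(self) -> np.ndarray:
        return np.array(
            [i for i, a in enumerate(self.topology.atoms) if not a.is_solute],
            dtype=int,
        )

    @property
    def solute_atom_indices(self) -> np.ndarray:
        return np.array(
            [i for i, a in enumerate(self.topology.atoms) if a.is_solute], dtype=int
        )
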