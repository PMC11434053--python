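"""Trajectory reading/writing, PBC unwrapping, and spherical droplet extraction.

File parsing is delegated to MDAnalysis (XYZ, GRO, PDB readers); this module
builds the package's molecule-aware :class:`~colorspec.topology.Topology` on
top of the parsed coordinates, from residue records (GRO/PDB) or from explicit
hints (XYZ, which carries no molecule information).

Conventions
-----------
* Lengths are Å internally; GRO files (nm) are converted on read.
* Only orthorhombic boxes are supported; triclinic input is rejected.
* A droplet is the whole solute plus every whole solvent molecule whose
  reference atom (its first atom, e.g. the water oxygen) lies within the cut
  radius of the solute geometric center.  Counterions are single-atom solvent
  molecules and follow the same distance rule.
"""
from __future__ import annotations

import os
import warnings

import numpy as np

from .topology import Atom, Droplet, Frame, Topology, Trajectory

_ELEMENTS = {
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne", "Na", "Mg", "Al",
    "Si", "P", "S", "Cl", "Ar", "K", "Ca", "Br", "I", "Fe", "Zn", "Cu", "Mn",
}


class TrajectoryParseError(ValueError):
    pass


def _guess_element(name: str) -> str:
    """Element from an atom name (e.g. 'OW'→'O', 'Cl-'→'Cl', 'HW1'→'H')."""
    stripped = "".join(c for c in name if c.isalpha())
    if not stripped:
        raise TrajectoryParseError(f"cannot infer element from atom name {name!r}")
    two = stripped[:2].capitalize()
    if two in _ELEMENTS:
        return two
    one = stripped[0].upper()
    if one in _ELEMENTS:
        return one
    raise TrajectoryParseError(f"unknown element symbol in atom name {name!r}")


def _scan_xyz_counts(path: str) -> list[int]:
    """Atom count of each frame in an XYZ file (header scan only)."""
    counts = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            try:
                n = int(header.split()[0])
            except ValueError as exc:
                raise TrajectoryParseError(
                    f"{path}: bad XYZ frame header {header!r}"
                ) from exc
            counts.append(n)
            fh.readline()  # comment
            for _ in range(n):
                if not fh.readline():
                    raise TrajectoryParseError(
                        f"{path}: truncated frame {len(counts) - 1}"
                    )
    return counts


def _box_from_dimensions(dims) -> np.ndarray | None:
    if dims is None:
        return None
    dims = np.asarray(dims, dtype=float)
    if np.all(dims[:3] == 0):
        return None
    if not np.allclose(dims[3:], 90.0, atol=1e-3):
        raise TrajectoryParseError(
            f"triclinic box (angles {dims[3:]}) not supported; orthorhombic only"
        )
    return dims[:3].copy()


def _molecule_layout_from_hints(n_atoms: int, hints: dict) -> list[int]:
    """Per-atom molecule index from XYZ topology hints."""
    if "molecule_sizes" in hints:
        sizes = list(hints["molecule_sizes"])
    elif "solute_n_atoms" in hints:
        s = int(hints["solute_n_atoms"])
        w = int(hints.get("solvent_molecule_size", 3))
        rest = n_atoms - s
        if rest % w:
            raise TrajectoryParseError(
                f"{rest} solvent atoms not divisible by molecule size {w}"
            )
        sizes = [s] + [w] * (rest // w)
    else:
        sizes = [n_atoms]  # single molecule
    if sum(sizes) != n_atoms:
        raise TrajectoryParseError(
            f"molecule sizes sum to {sum(sizes)}, file has {n_atoms} atoms"
        )
    mol_of = []
    for m, size in enumerate(sizes):
        mol_of.extend([m] * size)
    return mol_of


def read_trajectory(paths, format: str, topology_hints: dict | None = None) -> Trajectory:
    """Read one or more trajectory files into a :class:`Trajectory`.

    Parameters
    ----------
    paths : str or list of str
    format : {"xyz", "gro", "pdb"}
    topology_hints : dict, optional
        ``solute_resnames``: residue names flagged as solute (GRO/PDB;
        default: the first residue).  ``molecule_sizes`` or
        ``solute_n_atoms`` + ``solvent_molecule_size``: molecule layout for
        XYZ.  ``n_solute_molecules``: how many leading molecules are solute
        (XYZ, default 1).  ``site_labels``: atom index -> label.
        ``qtot_per_molecule``, ``dihedral_defs``: forwarded to the topology.
    """
    import MDAnalysis as mda

    hints = dict(topology_hints or {})
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    fmt = format.lower()
    if fmt not in ("xyz", "gro", "pdb"):
        raise ValueError(f"unsupported format {format!r}")

    frames: list[Frame] = []
    topology: Topology | None = None
    n_expected: int | None = None
    frame_counter = 0
    for path in paths:
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        if fmt == "xyz":
            counts = _scan_xyz_counts(path)
            for k, c in enumerate(counts):
                if n_expected is None:
                    n_expected = c
                elif c != n_expected:
                    raise TrajectoryParseError(
                        f"frame {frame_counter + k} has {c} atoms, expected {n_expected}"
                    )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(path, format=fmt, to_guess=())
        if n_expected is None:
            n_expected = len(u.atoms)
        elif len(u.atoms) != n_expected:
            raise TrajectoryParseError(
                f"frame {frame_counter} has {len(u.atoms)} atoms, expected {n_expected}"
            )
        if topology is None:
            topology = _build_topology(u, fmt, hints)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for ts in u.trajectory:
                box = _box_from_dimensions(ts.dimensions)
                time = float(ts.time) if ts.time is not None else float(frame_counter)
                frames.append(
                    Frame(ts.positions.astype(float).copy(), box=box, time=time)
                )
                frame_counter += 1
    assert topology is not None
    # MDAnalysis may report 0 ps for every frame of formats without time
    times = [f.time for f in frames]
    if any(b < a for a, b in zip(times, times[1:])):
        for i, f in enumerate(frames):
            f.time = float(i)
    return Trajectory(topology, frames)


def _build_topology(u, fmt: str, hints: dict) -> Topology:
    names = [a.name for a in u.atoms]
    if fmt == "xyz":
        mol_of = _molecule_layout_from_hints(len(names), hints)
        n_solute_mols = int(hints.get("n_solute_molecules", 1))
        solute_of = [m < n_solute_mols for m in mol_of]
    else:
        resindices = u.atoms.resindices
        mol_of = [int(r) for r in resindices]
        solute_resnames = hints.get("solute_resnames")
        if solute_resnames is None:
            first = u.atoms.resindices[0]
            solute_of = [int(r) == int(first) for r in resindices]
        else:
            solute_of = [rn in set(solute_resnames) for rn in u.atoms.resnames]
    site_labels = dict(hints.get("site_labels", {}))
    atoms = [
        Atom(
            atom_id=i,
            element=_guess_element(nm),
            molecule_id=mol_of[i],
            is_solute=solute_of[i],
            site_label=site_labels.get(i),
        )
        for i, nm in enumerate(names)
    ]
    return Topology(
        atoms,
        qtot_per_molecule=dict(hints.get("qtot_per_molecule", {})),
        dihedral_defs=dict(hints.get("dihedral_defs", {})),
    )


def unwrap_molecules(frame: Frame, topology: Topology) -> Frame:
    """Make every molecule whole by minimum-image shifts relative to its first atom.

    Requires a periodic box.  Raises if a molecule still spans more than half
    the box afterward (the minimum-image reconstruction is then ambiguous).
    """
    if frame.box is None:
        raise ValueError("unwrap requires a periodic box")
    box = frame.box
    pos = frame.positions.copy()
    for mol_id, atom_ids in topology.molecules.items():
        idx = np.array([topology.index_of(a) for a in atom_ids])
        ref = pos[idx[0]]
        d = pos[idx] - ref
        pos[idx] = pos[idx] - box * np.round(d / box)
        ext = pos[idx].max(axis=0) - pos[idx].min(axis=0)
        if np.any(ext > box / 2 + 1e-9):
            raise ValueError(
                f"molecule {mol_id} spans more than half the box after unwrapping"
            )
    return Frame(pos, box=box.copy(), time=frame.time)


def extract_droplet(
    frame: Frame,
    topology: Topology,
    radius: float,
    center_rule: str = "solute_geometric_center",
    keep_counterions: bool = True,
    source_frame_index: int | None = None,
) -> Droplet:
    """Cut a spherical droplet of whole solvent molecules around the solute.

    The solute is always retained entirely; a solvent molecule is retained iff
    its reference atom (first atom of the molecule) lies within ``radius`` of
    the solute geometric center, using the minimum image when a box is
    present.  Retained molecules are shifted to the image nearest the center,
    and the box is removed.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if center_rule != "solute_geometric_center":
        raise ValueError(f"unknown center rule {center_rule!r}")
    solute_ids = topology.solute_atom_ids
    if solute_ids.size == 0:
        raise ValueError("no solute atoms flagged in topology")
    box = frame.box
    if box is not None and radius > box.min() / 2:
        raise ValueError(
            f"radius {radius} Å exceeds half the smallest box edge "
            f"({box.min() / 2:.2f} Å); droplet would self-overlap"
        )
    pos = frame.positions
    solute_idx = np.array([topology.index_of(a) for a in solute_ids])
    center = pos[solute_idx].mean(axis=0)

    mols = topology.molecules
    atoms_by_id = {a.atom_id: a for a in topology.atoms}
    solute_mols = sorted({atoms_by_id[a].molecule_id for a in solute_ids})

    new_atoms: list[Atom] = []
    new_pos: list[np.ndarray] = []
    new_qtot: dict[int, float] = {}
    id_map: dict[int, int] = {}
    next_mol = 0

    def _take(mol_id: int, shift: np.ndarray, is_solute_mol: bool) -> None:
        nonlocal next_mol
        for aid in mols[mol_id]:
            a = atoms_by_id[aid]
            id_map[aid] = len(new_atoms)
            new_atoms.append(
                Atom(
                    atom_id=len(new_atoms),
                    element=a.element,
                    molecule_id=next_mol,
                    is_solute=a.is_solute if is_solute_mol else False,
                    site_label=a.site_label,
                )
            )
            new_pos.append(pos[topology.index_of(aid)] + shift)
        new_qtot[next_mol] = topology.qtot(mol_id)
        next_mol += 1

    for mol_id in solute_mols:
        _take(mol_id, np.zeros(3), True)
    for mol_id, atom_ids in mols.items():
        if mol_id in solute_mols:
            continue
        if not keep_counterions and len(atom_ids) == 1:
            continue
        ref = pos[topology.index_of(atom_ids[0])]
        disp = ref - center
        if box is not None:
            disp_mi = disp - box * np.round(disp / box)
        else:
            disp_mi = disp
        if np.linalg.norm(disp_mi) <= radius:
            _take(mol_id, disp_mi - disp, False)

    dihedrals = {
        name: tuple(id_map[a] for a in quad)
        for name, quad in topology.dihedral_defs.items()
        if all(a in id_map for a in quad)
    }
    new_topo = Topology(new_atoms, qtot_per_molecule=new_qtot, dihedral_defs=dihedrals)
    return Droplet(
        topology=new_topo,
        frame=Frame(np.array(new_pos), box=None, time=frame.time),
        radius=radius,
        center=center,
        source_frame_index=source_frame_index,
    )


def write_droplet(droplet: Droplet, path: str, format: str = "xyz") -> None:
    """Write a droplet to XYZ or PDB; solute first, solvent grouped by molecule."""
    fmt = format.lower()
    pos = droplet.frame.positions
    if fmt == "xyz":
        with open(path, "w") as fh:
            fh.write(f"{droplet.n_atoms}\n")
            c = droplet.center
            fh.write(
                f"colorspec droplet radius={droplet.radius:.3f} "
                f"center={c[0]:.4f},{c[1]:.4f},{c[2]:.4f}\n"
            )
            for a, p in zip(droplet.topology.atoms, pos):
                fh.write(f"{a.element:<2s} {p[0]:14.6f} {p[1]:14.6f} {p[2]:14.6f}\n")
    elif fmt == "pdb":
        import MDAnalysis as mda

        mols = droplet.topology.molecules
        resindex = np.array([a.molecule_id for a in droplet.topology.atoms])
        n_res = len(mols)
        solute_mols = {a.molecule_id for a in droplet.topology.atoms if a.is_solute}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe.empty(
                droplet.n_atoms,
                n_residues=n_res,
                atom_resindex=resindex,
                residue_segindex=np.zeros(n_res, dtype=int),
                trajectory=True,
            )
            u.add_TopologyAttr("names", [a.element for a in droplet.topology.atoms])
            u.add_TopologyAttr("elements", [a.element for a in droplet.topology.atoms])
            u.add_TopologyAttr(
                "resnames",
                ["SLT" if m in solute_mols else "SOL" for m in sorted(mols)],
            )
            u.add_TopologyAttr("resids", np.arange(1, n_res + 1))
            u.atoms.positions = pos
            u.atoms.write(path)
    else:
        raise ValueError(f"unsupported droplet format {format!r}")


def droplet_read_hints(droplet: Droplet) -> dict:
    """Topology hints that make a written droplet round-trip through read_trajectory."""
    sizes = [len(v) for _, v in sorted(droplet.topology.molecules.items())]
    n_solute_mols = len(
        {a.molecule_id for a in droplet.topology.atoms if a.is_solute}
    )
    return {
        "molecule_sizes": sizes,
        "n_solute_molecules": n_solute_mols,
        "solute_resnames": {"SLT"},
    }
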