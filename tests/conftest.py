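import numpy as np
import pytest

from colorspec.topology import Atom, Droplet, Frame, Topology


@pytest.fixture
def rng():
    return np.random.default_rng(20240914)


def make_droplet(molecules, qtot=None, solute_positions=None):
    """Build a Droplet from a list of molecules, each a list of
    (element, xyz) tuples.  An optional phantom solute atom 'X' is prepended
    so the droplet has a nonempty solute region.

    molecules: solvent molecules only.
    """
    atoms, pos = [], []
    aid = 0
    if solute_positions is None:
        solute_positions = [(50.0, 50.0, 50.0)]
    for p in solute_positions:
        atoms.append(Atom(aid, "X", molecule_id=0, is_solute=True))
        pos.append(p)
        aid += 1
    for m, mol in enumerate(molecules, start=1):
        for el, p in mol:
            atoms.append(Atom(aid, el, molecule_id=m, is_solute=False))
            pos.append(p)
            aid += 1
    q = {0: 0.0}
    q.update({m: (qtot or {}).get(m, 0.0) for m in range(1, len(molecules) + 1)})
    topo = Topology(atoms, qtot_per_molecule=q)
    frame = Frame(np.array(pos, dtype=float))
    center = np.asarray(solute_positions, dtype=float).mean(axis=0)
    return Droplet(topology=topo, frame=frame, radius=1e6, center=center)


@pytest.fixture
def water_like_droplet():
    """One bent 3-site solvent molecule, neutral, far from the phantom solute."""
    return make_droplet(
        [[("H", (0.76, 0.59, 0.0)), ("O", (0.0, 0.0, 0.0)), ("H", (-0.76, 0.59, 0.0))]]
    )
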