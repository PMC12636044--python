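import numpy as np
import pytest

from memhairpin import synth
from memhairpin.io import Frame, Trajectory


@pytest.fixture(scope="session")
def ideal_helix():
    return synth.build_ideal_helix(synth.HelixBuildSpec(20))


@pytest.fixture(scope="session")
def hairpin():
    return synth.build_hairpin(14, 4, 14)


@pytest.fixture(scope="session")
def membrane_pg100():
    return synth.build_membrane_slab(
        synth.MembraneSlabSpec(nx=12, ny=12, pg_fraction=1.0), seed=1)


def make_wiggle_trajectory(structure, n_frames=30, sigma=0.02, seed=2, dt=1.0):
    """Frames of a structure plus isotropic Gaussian coordinate noise."""
    rng = np.random.default_rng(seed)
    frames = [Frame(time=i * dt,
                    coordinates=structure.coordinates
                    + rng.normal(0.0, sigma, structure.coordinates.shape))
              for i in range(n_frames)]
    return Trajectory(atoms=structure.atoms, frames=frames)


def mdtraj_from_structure(structure):
    """Convert a Structure to a one-frame mdtraj Trajectory (oracle helper)."""
    import mdtraj as md
    from mdtraj.core import element as elem

    top = md.Topology()
    chain = top.add_chain()
    res = None
    last = None
    for a in structure.atoms:
        if a.residue_index != last:
            res = top.add_residue(a.residue_name, chain)
            last = a.residue_index
        top.add_atom(a.name, elem.get_by_symbol(a.element), res)
    return md.Trajectory(structure.coordinates[None], top)
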