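import numpy as np
import pytest

from confe.structure import Atom, Topology
from confe import synthetic


def make_atom(name="CA", element="C", resname="GLY", resid=1, **kw):
    defaults = dict(charge=0.0, rmin_half=1.9, epsilon=0.1,
                    gb_radius=1.5, gb_screen=0.8)
    defaults.update(kw)
    return Atom(name=name, element=element, resname=resname, resid=resid,
                **defaults)


@pytest.fixture
def single_atom_topology():
    return Topology([make_atom()])


@pytest.fixture
def chain_topology():
    """Linear 8-atom CA chain (5 rotatable torsions)."""
    return synthetic.make_toy_topology(8, atoms_per_residue=1)


@pytest.fixture
def peptide_topology():
    """3-residue N/CA/C/O toy chain (12 atoms, 11 bonds)."""
    return synthetic.make_toy_topology(3, atoms_per_residue=4)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
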