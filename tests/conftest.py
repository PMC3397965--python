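import numpy as np
import pytest

from liddock.structure import Atom, Residue, Structure, assign_atom_classes
from liddock.synthetic import ToyComplexSpec, make_toy_complex


@pytest.fixture(scope="session")
def toy_complex():
    """Default toy receptor-lid system (shared; treat as read-only)."""
    return make_toy_complex(ToyComplexSpec())


@pytest.fixture()
def classified_base():
    """Small classified 3-residue structure with donors and acceptors."""
    res = [
        Residue("SER", 1, "A", [Atom("CA", "C", [0, 0, 0]),
                                Atom("OG", "O", [1.0, 0, 0]),
                                Atom("HG", "H", [1.95, 0, 0])]),
        Residue("GLY", 2, "A", [Atom("CA", "C", [4, 0, 0]),
                                Atom("O", "O", [5, 0, 0])]),
        Residue("ALA", 3, "A", [Atom("CA", "C", [0, 4, 0]),
                                Atom("CB", "C", [1, 4, 0])]),
    ]
    return assign_atom_classes(Structure(res))


def make_chain(n_res=3, spacing=3.8, chain_id="A", charges=None):
    """Simple CA-only chain helper for analysis tests."""
    residues = []
    for i in range(n_res):
        q = charges[i] if charges else 0.0
        residues.append(Residue("GLY", i + 1, chain_id,
                                [Atom("CA", "C", [i * spacing, 0, 0],
                                      partial_charge=q)]))
    return assign_atom_classes(Structure(residues))
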