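import numpy as np
import pytest

from corestab.structure_io import AtomRecord, Structure
from corestab.synthetic_data import make_helix, make_hairpin, make_extended


@pytest.fixture(scope="session")
def helix12():
    return make_helix(12)


@pytest.fixture(scope="session")
def hairpin6():
    return make_hairpin(6)


@pytest.fixture(scope="session")
def extended10():
    return make_extended(10)


def chain_of_atoms(spec, residue_name, chain_id="A", seq=1):
    """Build one residue from (name, element, xyz) triples."""
    atoms = [AtomRecord(i + 1, name, el, residue_name, seq, "", chain_id,
                        np.asarray(xyz, float))
             for i, (name, el, xyz) in enumerate(spec)]
    return atoms


@pytest.fixture
def lysine_residue():
    """A lone lysine with idealised bond distances along the side chain."""
    spec = [
        ("N", "N", (0.0, 0.0, 0.0)),
        ("CA", "C", (1.46, 0.0, 0.0)),
        ("C", "C", (2.0, 1.4, 0.0)),
        ("O", "O", (3.2, 1.6, 0.0)),
        ("CB", "C", (2.0, -1.0, 1.0)),
        ("CG", "C", (3.5, -1.2, 1.1)),
        ("CD", "C", (4.1, -2.2, 2.1)),
        ("CE", "C", (5.6, -2.4, 2.2)),
        ("NZ", "N", (6.2, -3.4, 3.1)),
    ]
    return Structure(chain_of_atoms(spec, "LYS"), "lys")
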