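from pathlib import Path

import numpy as np
import pytest

from sitescan import parse_pdb
from sitescan.fixtures import ToyAtom, ToyStructureSpec, make_toy_structure

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def mini_pdb_text() -> str:
    return (DATA / "mini.pdb").read_text()


@pytest.fixture()
def mini_structure(mini_pdb_text):
    return parse_pdb(mini_pdb_text, structure_id="mini")


@pytest.fixture(scope="session")
def chain14_pdb_text() -> str:
    return (DATA / "chain14.pdb").read_text()


@pytest.fixture()
def chain14_structure(chain14_pdb_text):
    return parse_pdb(chain14_pdb_text, structure_id="chain14")


@pytest.fixture()
def three_atom_toy():
    """The worked microenvironment example: C at r=0.5, N at 2.0, O at 7.6."""
    spec = ToyStructureSpec(atoms=[
        ToyAtom("C", "CA", "ALA", "A", 1, 0.5, (1.0, 0.0, 0.0)),
        ToyAtom("N", "N", "GLY", "A", 2, 2.0, (0.0, 1.0, 0.0)),
        ToyAtom("O", "O", "SER", "A", 3, 7.6, (0.0, 0.0, 1.0)),
    ])
    return make_toy_structure(spec)
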