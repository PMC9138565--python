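import numpy as np
import pytest

from scrsasa.structure_io import Atom, BACKBONE_ATOMS, RadiiTable, Structure
from scrsasa.synthetic_data import build_peptide, helix_spec, strand_spec

ELEMENT_RADII = {"C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85}


def make_atom(name, element, x, y, z, serial=1, res_name="ALA", res_seq=1,
              chain="A"):
    """Hand-built Atom with the default radii and derived flags."""
    return Atom(
        serial=serial, name=name, element=element, res_name=res_name,
        res_seq=res_seq, chain=chain, x=float(x), y=float(y), z=float(z),
        radius=ELEMENT_RADII[element],
        is_backbone=name in BACKBONE_ATOMS,
        is_polar=element in ("N", "O"),
    )


@pytest.fixture(scope="session")
def radii():
    return RadiiTable()


@pytest.fixture(scope="session")
def helix10():
    """Ideal 10-residue poly-Ala alpha helix."""
    return build_peptide(helix_spec("A" * 10))


@pytest.fixture(scope="session")
def gag_structure():
    """Gly-Ala-Gly tripeptide in an extended conformation."""
    return build_peptide(strand_spec("GAG", id="GAG"))


@pytest.fixture(scope="session")
def mixed_strand():
    """Extended peptide covering all 20 residue types."""
    return build_peptide(strand_spec("ACDEFGHIKLMNPQRSTVWY", id="all20"))


def coords_of(structure) -> np.ndarray:
    return np.array([[a.x, a.y, a.z] for a in structure.atoms()])
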