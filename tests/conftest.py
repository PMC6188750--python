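import numpy as np
import pytest

from pepterface.structure_model import AtomRecord, StructureModel


def make_model(atom_rows, peptide_chain="P", receptor_chains=None):
    """Build a StructureModel from (name, element, residue, chain, resnum, xyz)
    rows; serials are assigned in row order."""
    atoms = []
    chains = []
    for i, (name, element, residue, chain, resnum, xyz) in enumerate(atom_rows):
        atoms.append(
            AtomRecord(
                serial=i + 1, name=name, element=element, residue=residue,
                chain=chain, resnum=resnum, icode="",
                coord=tuple(float(v) for v in xyz),
            )
        )
        if chain not in chains:
            chains.append(chain)
    if receptor_chains is None:
        receptor_chains = frozenset(c for c in chains if c != peptide_chain)
    return StructureModel(
        atoms=atoms, peptide_chain=peptide_chain,
        receptor_chains=frozenset(receptor_chains),
    )


def random_rotation(rng):
    """Uniform-ish random rotation matrix via QR."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    return q * np.sign(np.diag(r))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
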