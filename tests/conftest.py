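import pytest

from molsimnet.chem_io import MoleculeRecord, standardize
from molsimnet.synthetic import (
    SyntheticLibrarySpec,
    generate_combinatorial_libraries,
    separation_gap,
)


def record(smiles: str, mol_id: str = "m") -> MoleculeRecord:
    """Standardized record from a raw SMILES string."""
    return standardize(
        MoleculeRecord(id=mol_id, smiles_raw=smiles, smiles_canonical=smiles, heavy_atom_count=0)
    )


@pytest.fixture(scope="session")
def default_library():
    """The six-scaffold 157-molecule combinatorial library (seed 0)."""
    return generate_combinatorial_libraries(SyntheticLibrarySpec(seed=0))


@pytest.fixture(scope="session")
def library_gap(default_library):
    """(min intra, max inter) ECFP_4 Tanimoto of the default library."""
    records, reference = default_library
    return separation_gap(records, reference)
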