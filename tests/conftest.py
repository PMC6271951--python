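import pytest

from oxascreen import chem_core, library_builder


@pytest.fixture(scope="session")
def scaffold():
    return library_builder.amino_oxazole_scaffold()


@pytest.fixture
def block():
    """Factory: SMILES + id -> BuildingBlock."""

    def _make(smiles: str, block_id: str) -> library_builder.BuildingBlock:
        return library_builder.make_block(chem_core.parse_molecule(smiles, id=block_id))

    return _make


@pytest.fixture
def single_site_blocks(block):
    """Three diverse blocks restricted to one attachment point each."""
    blocks = [
        block("Cc1ccccc1", "01"),
        block("CCCCCC", "02"),
        block("CCc1ccncc1", "03"),
    ]
    return [
        library_builder.BuildingBlock(b.id, b.mol, (b.attachment_atoms[0],))
        for b in blocks
    ]
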