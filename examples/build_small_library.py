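"""Enumerate a small combinatorial amino-oxazole library.

Three building blocks are coupled pairwise to the amide nitrogen of the
2-amino-oxazole-5-carboxamide scaffold; every attachment-point combination
within the 18-heavy-atom R-group budget is emitted and near-duplicate
products are removed at Tanimoto 0.95.
"""

from oxascreen import chem_core as cc, library_builder as lb

blocks = [
    lb.make_block(cc.parse_molecule(smiles, block_id))
    for smiles, block_id in [
        ("Cc1ccccc1", "00000001"),   # toluene: benzyl-type attachment
        ("OCCCCC", "00000002"),      # pentanol
        ("CCNCC", "00000003"),       # diethylamine
    ]
]
blocks = lb.filter_blocks(blocks, min_heavy=4, max_heavy=12)
scaffold = lb.amino_oxazole_scaffold()

library = list(lb.enumerate_library(scaffold, blocks))
print(f"{len(blocks)} blocks -> {len(library)} distinct compounds\n")
for compound in library[:6]:
    heavy = cc.heavy_atom_count(compound.assembled)
    print(f"{compound.identifier}  heavy={heavy}  {compound.assembled.canonical_string}")

# Each identifier encodes the R1 and R2 block ids and an attachment-isomer
# combination number; heavy counts include the 9-atom scaffold.
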