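"""Combinatorial amino-oxazole library construction.

Building blocks (small organic fragments of 6-12 heavy atoms) are attached
pairwise to the amide nitrogen of a 2-amino-1,3-oxazole-5-carboxamide
scaffold, through any hydrogenated C, N, O or S atom of each block.  A pair
of blocks can therefore yield several chemically distinct compounds, one per
attachment-point combination; products are deduplicated by fingerprint
similarity at a Tanimoto threshold (default 0.95).
"""

from __future__ import annotations

import itertools
import random
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from rdkit import Chem

from . import chem_core
from .chem_core import BitFingerprint, Molecule, fingerprint, heavy_atom_count, tanimoto

#: 2-amino-1,3-oxazole-5-carboxamide: the fixed scaffold whose primary amide
#: nitrogen carries both R-groups.
SCAFFOLD_SMILES = "NC(=O)c1cnc(N)o1"

_ATTACHABLE = ("C", "N", "O", "S")


class CouplingError(ValueError):
    """Raised for invalid attachment atoms."""


class BudgetExceededError(ValueError):
    """Raised when a block pair exceeds the combined heavy-atom budget."""


@dataclass(frozen=True)
class BuildingBlock:
    """A fragment eligible for coupling at R1/R2."""

    id: str
    mol: Molecule
    attachment_atoms: tuple[int, ...]


@dataclass(frozen=True)
class ScaffoldSpec:
    """The scaffold and the index of its coupling (amide) nitrogen."""

    mol: Molecule
    coupling_atom: int
    arity: int = 2


@dataclass(frozen=True)
class CombinatorialCompound:
    identifier: str
    r1: tuple[str, int]  # (block id, attachment atom index)
    r2: tuple[str, int]
    combination_index: int
    assembled: Molecule


def attachment_points(mol: Molecule) -> tuple[int, ...]:
    """Indices of C/N/O/S atoms bearing at least one hydrogen, canonical order."""
    return tuple(
        a.GetIdx()
        for a in mol.rdkit_mol.GetAtoms()
        if a.GetSymbol() in _ATTACHABLE and a.GetTotalNumHs() >= 1
    )


def make_block(mol: Molecule) -> BuildingBlock:
    return BuildingBlock(id=mol.id, mol=mol, attachment_atoms=attachment_points(mol))


def amino_oxazole_scaffold() -> ScaffoldSpec:
    """The default 2-amino-oxazole-5-carboxamide scaffold.

    The coupling atom is the primary amide nitrogen (two hydrogens before
    substitution), located by pattern matching rather than a hard-coded index.
    """
    mol = chem_core.parse_molecule(SCAFFOLD_SMILES, id="amino-oxazole")
    match = mol.rdkit_mol.GetSubstructMatch(Chem.MolFromSmarts("[NX3H2][CX3]=O"))
    if not match:
        raise CouplingError("scaffold has no primary amide nitrogen")
    return ScaffoldSpec(mol=mol, coupling_atom=match[0])


def filter_blocks(
    blocks: Sequence[BuildingBlock], min_heavy: int = 6, max_heavy: int = 12
) -> list[BuildingBlock]:
    """Keep blocks whose heavy-atom count lies in [min_heavy, max_heavy]."""
    return [
        b for b in blocks if min_heavy <= heavy_atom_count(b.mol) <= max_heavy
    ]


def dedupe_by_similarity(
    blocks: Sequence[BuildingBlock], threshold: float = 0.95
) -> list[BuildingBlock]:
    """Greedy leader-pass redundancy removal in input order.

    A block is kept iff its Tanimoto similarity to every previously kept
    block is strictly below ``threshold``; the kept set is therefore pairwise
    sub-threshold and the pass is idempotent.
    """
    kept: list[BuildingBlock] = []
    kept_fps: list[BitFingerprint] = []
    for b in blocks:
        fp = fingerprint(b.mol)
        if all(tanimoto(fp, k) < threshold for k in kept_fps):
            kept.append(b)
            kept_fps.append(fp)
    return kept


def _remove_one_hydrogen(atom: Chem.Atom) -> None:
    # explicit Hs (e.g. aromatic [nH]) must be decremented by hand; implicit
    # Hs are recomputed by sanitization after the new bond is added
    if atom.GetNumExplicitHs() > 0:
        atom.SetNumExplicitHs(atom.GetNumExplicitHs() - 1)


def couple_blocks(
    scaffold: ScaffoldSpec,
    b1: BuildingBlock,
    ap1: int,
    b2: BuildingBlock,
    ap2: int,
    budget: int = 18,
    combination_index: int = 0,
) -> CombinatorialCompound:
    """Attach two blocks to the scaffold's amide nitrogen.

    ``ap1``/``ap2`` are atom indices into each block's canonical atom order.
    Raises :class:`BudgetExceededError` when the blocks together exceed the
    heavy-atom budget and :class:`CouplingError` for invalid attachment atoms.
    """
    n1, n2 = heavy_atom_count(b1.mol), heavy_atom_count(b2.mol)
    if n1 + n2 > budget:
        raise BudgetExceededError(
            f"blocks {b1.id}+{b2.id} have {n1 + n2} heavy atoms (> {budget})"
        )
    if ap1 not in b1.attachment_atoms:
        raise CouplingError(f"atom {ap1} of block {b1.id} is not attachable")
    if ap2 not in b2.attachment_atoms:
        raise CouplingError(f"atom {ap2} of block {b2.id} is not attachable")

    scaf_mol = scaffold.mol.rdkit_mol
    combo = Chem.RWMol(Chem.CombineMols(Chem.CombineMols(scaf_mol, b1.mol.rdkit_mol), b2.mol.rdkit_mol))
    off1 = scaf_mol.GetNumAtoms()
    off2 = off1 + b1.mol.rdkit_mol.GetNumAtoms()
    n_atom = combo.GetAtomWithIdx(scaffold.coupling_atom)
    _remove_one_hydrogen(n_atom)
    _remove_one_hydrogen(n_atom)
    _remove_one_hydrogen(combo.GetAtomWithIdx(off1 + ap1))
    _remove_one_hydrogen(combo.GetAtomWithIdx(off2 + ap2))
    combo.AddBond(scaffold.coupling_atom, off1 + ap1, Chem.BondType.SINGLE)
    combo.AddBond(scaffold.coupling_atom, off2 + ap2, Chem.BondType.SINGLE)
    product = combo.GetMol()
    Chem.SanitizeMol(product)

    identifier = compound_identifier_from_parts(b1.id, b2.id, combination_index)
    assembled = chem_core.from_rdkit(product, id=identifier)
    return CombinatorialCompound(
        identifier=identifier,
        r1=(b1.id, ap1),
        r2=(b2.id, ap2),
        combination_index=combination_index,
        assembled=assembled,
    )


def enumerate_library(
    scaffold: ScaffoldSpec,
    blocks: Sequence[BuildingBlock],
    budget: int = 18,
    dedupe_threshold: float = 0.95,
) -> Iterator[CombinatorialCompound]:
    """Enumerate every compound from unordered block pairs within budget.

    Both R-groups bond to the same amide nitrogen, so (b1, b2) and (b2, b1)
    give the same molecule; enumeration therefore runs over unordered pairs
    of (block, attachment-point) sites.  Self-pairing is allowed.  Products
    are deduplicated on the fly by a greedy leader pass over assembled-product
    fingerprints at ``dedupe_threshold``; order is deterministic.
    """
    kept_fps: list[BitFingerprint] = []
    for i, j in itertools.combinations_with_replacement(range(len(blocks)), 2):
        b1, b2 = blocks[i], blocks[j]
        if heavy_atom_count(b1.mol) + heavy_atom_count(b2.mol) > budget:
            continue
        if i == j:
            ap_pairs = itertools.combinations_with_replacement(b1.attachment_atoms, 2)
        else:
            ap_pairs = itertools.product(b1.attachment_atoms, b2.attachment_atoms)
        for combination, (ap1, ap2) in enumerate(ap_pairs):
            compound = couple_blocks(
                scaffold, b1, ap1, b2, ap2, budget=budget,
                combination_index=combination,
            )
            fp = fingerprint(compound.assembled)
            if all(tanimoto(fp, k) < dedupe_threshold for k in kept_fps):
                kept_fps.append(fp)
                yield compound


def sample_library(
    stream: Iterable[CombinatorialCompound], n: int, seed: int
) -> list[CombinatorialCompound]:
    """Uniform sample of ``n`` compounds without replacement (reservoir
    algorithm, so the stream is never materialized).  Deterministic per seed;
    the sample preserves stream order."""
    rng = random.Random(seed)
    reservoir: list[CombinatorialCompound] = []
    size = 0
    for item in stream:
        if size < n:
            reservoir.append(item)
        else:
            k = rng.randrange(size + 1)
            if k < n:
                reservoir[k] = item
        size += 1
    if n > size:
        raise ValueError(f"requested sample of {n} from a library of {size}")
    return reservoir


_ID_RE = re.compile(r"^ao-(?P<r1>[^-]+)-(?P<r2>[^-]+)-(?P<combo>\d{3,4})$")


def compound_identifier_from_parts(r1_id: str, r2_id: str, combination: int) -> str:
    """``ao-<R1 id>-<R2 id>-<combination>`` with the index zero-padded to 4."""
    return f"ao-{r1_id}-{r2_id}-{combination:04d}"


def compound_identifier(compound: CombinatorialCompound) -> str:
    return compound_identifier_from_parts(
        compound.r1[0], compound.r2[0], compound.combination_index
    )


def parse_identifier(identifier: str) -> tuple[str, str, int]:
    """Split an ``ao-…`` identifier into (R1 id, R2 id, combination number).

    Accepts both 3- and 4-digit combination fields.
    """
    m = _ID_RE.match(identifier)
    if m is None:
        raise ValueError(f"not a valid compound identifier: {identifier!r}")
    return m.group("r1"), m.group("r2"), int(m.group("combo"))


def write_manifest(path, compounds: Iterable[CombinatorialCompound]) -> None:
    """TSV manifest: identifier, R1/R2 block ids, combination, heavy atoms."""
    with open(path, "w") as fh:
        fh.write("identifier\tr1_id\tr2_id\tcombination\theavy_atoms\n")
        for c in compounds:
            fh.write(
                f"{c.identifier}\t{c.r1[0]}\t{c.r2[0]}\t"
                f"{c.combination_index}\t{heavy_atom_count(c.assembled)}\n"
            )
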