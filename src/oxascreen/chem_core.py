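"""Molecular representation, fingerprints, Tanimoto similarity and descriptors.

Everything downstream (library enumeration, deduplication, block clustering)
works through this thin layer over RDKit so that the fingerprint type, the
Tanimoto conventions and the descriptor definitions are fixed in one place.

Fingerprints are hashed linear-path (topological) fingerprints, paths of
1-7 bonds folded into 2048 bits.  With this family of fingerprints the
conventional similarity thresholds used throughout the pipeline (0.7 for
chemotype clustering, 0.95 for redundancy removal) behave as practitioners
expect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

RDLogger.DisableLog("rdApp.*")

#: Elements admitted in building blocks and assembled compounds: the SMILES
#: organic subset plus the halogens.
ALLOWED_ELEMENTS = frozenset(
    {"B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I", "H"}
)

FINGERPRINT_BITS = 2048
_MIN_PATH = 1
_MAX_PATH = 7


class MoleculeParseError(ValueError):
    """Raised when a SMILES string cannot be parsed or contains odd elements."""


class FingerprintLengthError(ValueError):
    """Raised when two fingerprints of different lengths are compared."""


@dataclass(frozen=True)
class Molecule:
    """An organic small molecule with a canonical SMILES identity.

    ``canonical_string`` is the RDKit canonical SMILES; two Molecule objects
    describe the same structure iff their canonical strings are equal.
    """

    id: str
    canonical_string: str
    rdkit_mol: Chem.Mol

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Molecule):
            return NotImplemented
        return self.canonical_string == other.canonical_string

    def __hash__(self) -> int:
        return hash(self.canonical_string)

    @property
    def atoms(self) -> list[tuple[str, int, int]]:
        """(element symbol, formal charge, implicit+explicit H count) per atom."""
        return [
            (a.GetSymbol(), a.GetFormalCharge(), a.GetTotalNumHs())
            for a in self.rdkit_mol.GetAtoms()
        ]

    @property
    def bonds(self) -> list[tuple[int, int, float, bool]]:
        """(begin index, end index, bond order, aromatic flag) per bond."""
        return [
            (
                b.GetBeginAtomIdx(),
                b.GetEndAtomIdx(),
                b.GetBondTypeAsDouble(),
                b.GetIsAromatic(),
            )
            for b in self.rdkit_mol.GetBonds()
        ]


@dataclass(frozen=True)
class BitFingerprint:
    """A fixed-length binary fingerprint (bit positions stored as frozenset)."""

    bits: frozenset[int]
    length: int

    @property
    def popcount(self) -> int:
        return len(self.bits)


@dataclass(frozen=True)
class PropertyProfile:
    """Physicochemical descriptors used for library profiling.

    molecular_weight in Da, tpsa in squared angstroms, logp unitless
    (Crippen atom-contribution estimate), hbd/hba/heavy_atoms are counts.
    """

    molecular_weight: float
    logp: float
    tpsa: float
    hbd: int
    hba: int
    heavy_atoms: int


def parse_molecule(text: str, id: str = "") -> Molecule:
    """Parse a SMILES string into a canonicalized :class:`Molecule`.

    Raises :class:`MoleculeParseError` naming ``id`` on malformed input or
    on elements outside the organic subset + halogens.
    """
    raw = Chem.MolFromSmiles(text)
    if raw is None:
        raise MoleculeParseError(f"cannot parse SMILES for {id!r}: {text!r}")
    for atom in raw.GetAtoms():
        if atom.GetSymbol() not in ALLOWED_ELEMENTS:
            raise MoleculeParseError(
                f"molecule {id!r} contains disallowed element {atom.GetSymbol()!r}"
            )
    canonical = Chem.MolToSmiles(raw)
    # re-parse from the canonical form so atom order is the canonical order
    mol = Chem.MolFromSmiles(canonical)
    return Molecule(id=id, canonical_string=canonical, rdkit_mol=mol)


def from_rdkit(mol: Chem.Mol, id: str = "") -> Molecule:
    """Wrap an existing RDKit Mol, canonicalizing it."""
    return parse_molecule(Chem.MolToSmiles(mol), id=id)


def heavy_atom_count(mol: Molecule) -> int:
    """Number of non-hydrogen atoms."""
    return mol.rdkit_mol.GetNumHeavyAtoms()


def fingerprint(mol: Molecule) -> BitFingerprint:
    """Hashed linear-path topological fingerprint, 2048 bits, paths 1-7 bonds."""
    bv = Chem.RDKFingerprint(
        mol.rdkit_mol, minPath=_MIN_PATH, maxPath=_MAX_PATH, fpSize=FINGERPRINT_BITS
    )
    return BitFingerprint(bits=frozenset(bv.GetOnBits()), length=FINGERPRINT_BITS)


def tanimoto(a: BitFingerprint, b: BitFingerprint) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| over set bits.

    Two all-zero fingerprints compare as identical (1.0); an all-zero
    against a non-empty fingerprint gives 0.0.
    """
    if a.length != b.length:
        raise FingerprintLengthError(
            f"fingerprint lengths differ: {a.length} vs {b.length}"
        )
    if a.popcount == 0 and b.popcount == 0:
        return 1.0
    union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    return len(a.bits & b.bits) / union


def _is_amide_nitrogen(atom: Chem.Atom) -> bool:
    for nbr in atom.GetNeighbors():
        if nbr.GetSymbol() != "C":
            continue
        for bond in nbr.GetBonds():
            other = bond.GetOtherAtom(nbr)
            if (
                other.GetSymbol() == "O"
                and bond.GetBondType() == Chem.BondType.DOUBLE
            ):
                return True
    return False


def hydrogen_bond_acceptors(mol: Molecule) -> int:
    """H-bond acceptor count: every N and O except pyrrole-type NH and amide N.

    This is a deliberately simple, documented convention; conventions differ
    between software packages and the counts are used for profiling only.
    """
    n = 0
    for atom in mol.rdkit_mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym == "O":
            n += 1
        elif sym == "N":
            if atom.GetIsAromatic() and atom.GetTotalNumHs() >= 1:
                continue  # pyrrole-type NH donates its lone pair to the ring
            if _is_amide_nitrogen(atom):
                continue
            n += 1
    return n


def hydrogen_bond_donors(mol: Molecule) -> int:
    """H-bond donor count: N or O bearing at least one hydrogen."""
    return sum(
        1
        for a in mol.rdkit_mol.GetAtoms()
        if a.GetSymbol() in ("N", "O") and a.GetTotalNumHs() >= 1
    )


def descriptor_profile(mol: Molecule) -> PropertyProfile:
    """Compute the physicochemical property profile of a molecule."""
    m = mol.rdkit_mol
    return PropertyProfile(
        molecular_weight=Descriptors.MolWt(m),
        logp=Crippen.MolLogP(m),
        tpsa=rdMolDescriptors.CalcTPSA(m),
        hbd=hydrogen_bond_donors(mol),
        hba=hydrogen_bond_acceptors(mol),
        heavy_atoms=m.GetNumHeavyAtoms(),
    )


def rule_of_five_pass(p: PropertyProfile) -> bool:
    """Lipinski rule-of-five with inclusive bounds:
    MW ≤ 500 Da, logP ≤ 5, donors ≤ 5, acceptors ≤ 10."""
    return (
        p.molecular_weight <= 500.0
        and p.logp <= 5.0
        and p.hbd <= 5
        and p.hba <= 10
    )


# ---------------------------------------------------------------------------
# file formats


def read_smiles_file(path: str | Path) -> list[Molecule]:
    """Read a SMILES file: one ``SMILES<whitespace>ID`` record per line.

    Blank lines and lines starting with '#' are skipped.  A missing ID
    defaults to the 1-based line number.
    """
    mols = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            mol_id = parts[1].strip() if len(parts) > 1 else str(lineno)
            mols.append(parse_molecule(smiles, id=mol_id))
    return mols


def write_smiles_file(path: str | Path, mols: Iterable[Molecule]) -> None:
    with open(path, "w") as fh:
        for m in mols:
            fh.write(f"{m.canonical_string}\t{m.id}\n")


def write_sdf(path: str | Path, mols: Iterable[Molecule]) -> None:
    """Write molecules as a V2000 SD file."""
    writer = Chem.SDWriter(str(path))
    try:
        for m in mols:
            rd = Chem.Mol(m.rdkit_mol)
            rd.SetProp("_Name", m.id)
            writer.write(rd)
    finally:
        writer.close()
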