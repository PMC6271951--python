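"""Distance-based classification of protein-ligand contacts.

Contacts between docked compounds and binding-site residues are classified
into five classes -- hydrogen bond, halogen bond, aromatic, hydrophobic and
destabilizing (hydrophilic-hydrophobic) -- from atom roles and interatomic
distances, then aggregated into per-residue interaction profiles: the
fraction of compounds touching each residue and the class composition of
its contacts.  Halogen bonds are a first-class category here (ligand
halogen within range of a protein N/O/S), rather than being folded into the
hydrophilic-hydrophobic class.

Geometry is deliberately simple: heavy-atom distance cutoffs, no angle
terms (hydrogens are frequently absent from PDB inputs), with aromaticity
taken from ring membership.  All cutoffs are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

CONTACT_CLASSES = ("hbond", "halogen_bond", "aromatic", "hydrophobic", "destabilizing")

_HALOGENS = {"F", "Cl", "Br", "I"}
_KNOWN_ELEMENTS = {"H", "B", "C", "N", "O", "P", "S"} | _HALOGENS


@dataclass(frozen=True)
class ContactCutoffs:
    """Heavy-atom distance cutoffs (angstroms) per contact class."""

    hbond: float = 3.5
    halogen_bond: float = 3.6
    aromatic: float = 5.0
    hydrophobic: float = 4.5
    destabilizing: float = 4.0

    @property
    def maximum(self) -> float:
        return max(self.hbond, self.halogen_bond, self.aromatic,
                   self.hydrophobic, self.destabilizing)


DEFAULT_CUTOFFS = ContactCutoffs()


@dataclass(frozen=True)
class AtomSite:
    element: str
    coordinates: tuple[float, float, float]
    residue_number: int
    residue_name: str
    chain: str
    molecule_role: str  # "protein" or "ligand"
    roles: frozenset[str] = frozenset()

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coordinates, dtype=float)


@dataclass(frozen=True)
class Contact:
    protein_atom: AtomSite
    ligand_atom: AtomSite
    distance: float
    contact_class: str


@dataclass(frozen=True)
class ResidueInteractionProfile:
    residue_number: int
    fraction_of_compounds: float
    composition: Mapping[str, float]  # per-class fractions summing to 1


def assign_roles(
    element: str,
    neighbor_elements: Sequence[str] = (),
    n_hydrogens: int = 0,
    formal_charge: int = 0,
    is_aromatic: bool = False,
) -> frozenset[str]:
    """Interaction roles of one heavy atom from its element and environment.

    donor: N/O carrying >= 1 H; acceptor: N/O not positively charged;
    aromatic: ring member (caller-determined); hydrophobic: C or S bonded
    only to C/S/H; hydrophilic: any N/O; halogen: F/Cl/Br/I (exclusive of
    the hydrophobic/hydrophilic axis).  Roles may overlap except
    hydrophobic vs hydrophilic, which are mutually exclusive by definition.
    """
    if element not in _KNOWN_ELEMENTS:
        raise ValueError(f"unknown element {element!r}")
    roles: set[str] = set()
    if element in _HALOGENS:
        roles.add("halogen")
        return frozenset(roles)
    if element in ("N", "O"):
        roles.add("hydrophilic")
        if n_hydrogens >= 1:
            roles.add("donor")
        if formal_charge <= 0:
            roles.add("acceptor")
    elif element in ("C", "S"):
        heavy = [e for e in neighbor_elements if e != "H"]
        if all(e in ("C", "S") for e in heavy):
            roles.add("hydrophobic")
    if is_aromatic:
        roles.add("aromatic")
    return frozenset(roles)


def classify_pair(
    protein_atom: AtomSite,
    ligand_atom: AtomSite,
    distance: float,
    cutoffs: ContactCutoffs = DEFAULT_CUTOFFS,
) -> str | None:
    """Contact class of one atom pair, or None if no class applies.

    Precedence: hbond > halogen_bond > aromatic > hydrophobic >
    destabilizing; exactly one class per qualifying pair.
    """
    p, l = protein_atom.roles, ligand_atom.roles
    if distance <= cutoffs.hbond and (
        ("donor" in p and "acceptor" in l) or ("acceptor" in p and "donor" in l)
    ):
        return "hbond"
    if (
        distance <= cutoffs.halogen_bond
        and "halogen" in l
        and protein_atom.element in ("N", "O", "S")
    ):
        return "halogen_bond"
    if distance <= cutoffs.aromatic and "aromatic" in p and "aromatic" in l:
        return "aromatic"
    if distance <= cutoffs.hydrophobic and "hydrophobic" in p and "hydrophobic" in l:
        return "hydrophobic"
    if distance <= cutoffs.destabilizing and (
        ("hydrophilic" in p and "hydrophobic" in l)
        or ("hydrophobic" in p and "hydrophilic" in l)
    ):
        return "destabilizing"
    return None


def detect_contacts(
    protein_sites: Sequence[AtomSite],
    ligand_sites: Sequence[AtomSite],
    cutoffs: ContactCutoffs = DEFAULT_CUTOFFS,
) -> list[Contact]:
    """Classify every qualifying protein-ligand heavy-atom pair."""
    protein = [a for a in protein_sites if a.element != "H"]
    ligand = [a for a in ligand_sites if a.element != "H"]
    if not protein or not ligand:
        raise ValueError("empty protein or ligand")
    pmat = np.array([a.xyz for a in protein])
    lmat = np.array([a.xyz for a in ligand])
    dists = cdist(pmat, lmat)
    contacts = []
    for i, j in zip(*np.nonzero(dists <= cutoffs.maximum)):
        d = float(dists[i, j])
        cls = classify_pair(protein[i], ligand[j], d, cutoffs)
        if cls is not None:
            contacts.append(
                Contact(protein_atom=protein[i], ligand_atom=ligand[j],
                        distance=d, contact_class=cls)
            )
    return contacts


def residue_profiles(
    contacts_per_compound: Sequence[Sequence[Contact]],
    binding_residues: Sequence[int],
) -> list[ResidueInteractionProfile]:
    """Aggregate classified contacts over a compound set.

    Per residue: the fraction of compounds forming >= 1 contact with it, and
    the class composition over all of that residue's contacts (empty when no
    compound touches it).
    """
    n_compounds = len(contacts_per_compound)
    profiles = []
    for res in binding_residues:
        touching = 0
        counts: dict[str, int] = {}
        for contacts in contacts_per_compound:
            hit = False
            for c in contacts:
                if c.protein_atom.residue_number == res:
                    hit = True
                    counts[c.contact_class] = counts.get(c.contact_class, 0) + 1
            touching += hit
        total = sum(counts.values())
        composition = (
            {cls: counts[cls] / total for cls in sorted(counts)} if total else {}
        )
        profiles.append(
            ResidueInteractionProfile(
                residue_number=res,
                fraction_of_compounds=touching / n_compounds if n_compounds else 0.0,
                composition=composition,
            )
        )
    return profiles


def halogen_contributions(
    contacts_per_compound: Sequence[Sequence[Contact]],
) -> dict[int, float]:
    """Per-residue share of all halogen bonds (shares sum to 1 when any
    halogen bond exists; empty dict otherwise)."""
    counts: dict[int, int] = {}
    for contacts in contacts_per_compound:
        for c in contacts:
            if c.contact_class == "halogen_bond":
                res = c.protein_atom.residue_number
                counts[res] = counts.get(res, 0) + 1
    total = sum(counts.values())
    return {res: n / total for res, n in sorted(counts.items())} if total else {}


# ---------------------------------------------------------------------------
# PDB input/output

_BOND_CUTOFF = 1.9  # heavy-heavy covalent bond inference, angstroms
_H_BOND_CUTOFF = 1.3  # hydrogen attachment


def _infer_roles(elements, coords, aromatic_flags=None):
    """Assign roles to every heavy atom of one molecule from inferred
    connectivity.  Rings of 5-6 atoms are treated as aromatic -- adequate
    for the planar rings encountered here; documented approximation."""
    import networkx as nx

    n = len(elements)
    coords = np.asarray(coords, dtype=float)
    heavy = [i for i in range(n) if elements[i] != "H"]
    hydro = [i for i in range(n) if elements[i] == "H"]
    dists = cdist(coords, coords)
    graph = nx.Graph()
    graph.add_nodes_from(heavy)
    for ii, i in enumerate(heavy):
        for j in heavy[ii + 1:]:
            if dists[i, j] <= _BOND_CUTOFF:
                graph.add_edge(i, j)
    in_ring = set()
    for cycle in nx.cycle_basis(graph):
        if len(cycle) in (5, 6):
            in_ring.update(cycle)
    roles = {}
    for i in heavy:
        neighbors = [elements[j] for j in graph.neighbors(i)]
        n_h = sum(1 for j in hydro if dists[i, j] <= _H_BOND_CUTOFF)
        aromatic = i in in_ring if aromatic_flags is None else aromatic_flags[i]
        roles[i] = assign_roles(
            elements[i], neighbors, n_hydrogens=n_h, is_aromatic=aromatic
        )
    return roles


def read_complex(
    path: str | Path,
    ligand_resnames: Sequence[str] = ("LIG",),
    ligand_chain: str | None = None,
) -> tuple[list[AtomSite], list[AtomSite]]:
    """Read a PDB complex into protein and ligand atom sites.

    The ligand is identified by residue name (default ``LIG``) or, when
    ``ligand_chain`` is given, by chain id.  Roles are assigned from
    distance-inferred connectivity.
    """
    from Bio.PDB import PDBParser

    structure = PDBParser(QUIET=True).get_structure("complex", str(path))
    raw: list[tuple[str, np.ndarray, int, str, str, str]] = []
    for model in structure:
        for chain in model:
            for residue in chain:
                resname = residue.get_resname().strip()
                resnum = residue.get_id()[1]
                is_ligand = (
                    chain.get_id() == ligand_chain
                    if ligand_chain is not None
                    else resname in ligand_resnames
                )
                for atom in residue:
                    element = atom.element.strip().capitalize()
                    raw.append((
                        element, atom.get_coord(), resnum, resname,
                        chain.get_id(), "ligand" if is_ligand else "protein",
                    ))
        break  # first model only

    sites: list[AtomSite] = []
    for part in ("protein", "ligand"):
        idx = [i for i, r in enumerate(raw) if r[5] == part]
        elements = [raw[i][0] for i in idx]
        coords = [raw[i][1] for i in idx]
        roles = _infer_roles(elements, coords) if idx else {}
        for local, i in enumerate(idx):
            element, coord, resnum, resname, chain_id, role = raw[i]
            sites.append(
                AtomSite(
                    element=element,
                    coordinates=tuple(float(x) for x in coord),
                    residue_number=resnum,
                    residue_name=resname,
                    chain=chain_id,
                    molecule_role=role,
                    roles=roles.get(local, frozenset()),
                )
            )
    protein = [s for s in sites if s.molecule_role == "protein"]
    ligand = [s for s in sites if s.molecule_role == "ligand"]
    return protein, ligand


def write_complex(
    path: str | Path,
    protein_sites: Sequence[AtomSite],
    ligand_sites: Sequence[AtomSite],
) -> None:
    """Write atom sites as a minimal PDB file (protein as ATOM, ligand as
    HETATM)."""
    serial = 1
    with open(path, "w") as fh:
        for sites, record in ((protein_sites, "ATOM"), (ligand_sites, "HETATM")):
            counters: dict[tuple[int, str], int] = {}
            for a in sites:
                key = (a.residue_number, a.element)
                counters[key] = counters.get(key, 0) + 1
                name = f"{a.element}{counters[key]}"[:4]
                x, y, z = a.coordinates
                fh.write(
                    f"{record:<6}{serial:>5} {name:<4} {a.residue_name:<3} "
                    f"{a.chain}{a.residue_number:>4}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {a.element:>2}\n"
                )
                serial += 1
        fh.write("END\n")


def write_profiles_tsv(path, profiles: Iterable[ResidueInteractionProfile]) -> None:
    with open(path, "w") as fh:
        header = "\t".join(CONTACT_CLASSES)
        fh.write(f"residue_number\tfraction_of_compounds\t{header}\n")
        for p in profiles:
            comp = "\t".join(
                f"{p.composition.get(cls, 0.0):.6f}" for cls in CONTACT_CLASSES
            )
            fh.write(f"{p.residue_number}\t{p.fraction_of_compounds:.6f}\t{comp}\n")


def write_halogen_shares_tsv(path, shares: Mapping[int, float]) -> None:
    with open(path, "w") as fh:
        fh.write("residue_number\thalogen_share\n")
        for res, share in sorted(shares.items()):
            fh.write(f"{res}\t{share:.6f}\n")
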