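"""Seeded generators emulating every input of the screening pipeline.

The external docking engine, the vendor building-block catalogue, the
PSI-BLAST-style sequence profiles and the docked 3D complexes are all
replaced by deterministic generators with *planted* statistical structure,
so every downstream stage can be tested quantitatively without downloads:

* building blocks are drawn from a bundled pool of curated fragments that
  contains tagged similarity families (chemotype families similar at
  Tanimoto >= 0.7 to their leader, and near-redundant homolog series at
  pairwise Tanimoto >= 0.95);
* docking records follow a latent-quality model: each compound has a
  Gram-negative and a Gram-positive quality coupled at a configurable rank
  correlation (Gaussian copula), the four docking scores are monotone maps
  of the group quality plus noise, and the anchor-RMSD pass event is an
  independent Bernoulli per isoform;
* sequence profiles are Dirichlet draws around the protein background with
  near-point-mass conserved positions;
* 3D complexes place probe atoms at distances that realize a prescribed
  list of (residue, contact class) pairs exactly.

All randomness flows through explicit integer seeds; there is no global
state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import chem_core
from .conservation_profiler import (
    ISOFORMS,
    IsoformSpec,
    SequenceProfile,
    load_background_composition,
)
from .interaction_profiler import AtomSite
from .library_builder import (
    BuildingBlock,
    compound_identifier_from_parts,
    make_block,
    parse_identifier,
)
from .screening_postprocess import DockingRecord


@dataclass(frozen=True)
class PlantedCluster:
    """A block set whose compounds get a latent-quality boost in one group."""

    block_ids: frozenset[str]
    position: str  # "R1" or "R2"
    group: str  # "gram_negative" or "gram_positive"
    effect: float  # latent-quality units


@dataclass(frozen=True)
class CompoundSpec:
    """A lightweight compound: identifier plus its R1/R2 block ids."""

    identifier: str
    r1_block: str
    r2_block: str


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for the synthetic docking campaign.

    ``anchor_pass_prob`` is the per-isoform probability that the docked
    anchor lands within 2 A of the reference; ``group_correlation`` is the
    target *rank* correlation between the Gram-negative and Gram-positive
    latent qualities; ``score_noise_sd`` is the standard deviation of the
    per-isoform, per-score noise relative to a unit-variance quality.
    """

    seed: int = 0
    n_compounds: int = 2000
    isoforms: tuple[IsoformSpec, ...] = ISOFORMS
    anchor_pass_prob: float = 0.755
    group_correlation: float = 0.8
    planted_clusters: tuple[PlantedCluster, ...] = ()
    score_noise_sd: float = 0.25

    def __post_init__(self):
        if not 0.0 < self.anchor_pass_prob <= 1.0:
            raise ValueError("anchor_pass_prob must be in (0, 1]")
        if not -1.0 <= self.group_correlation <= 1.0:
            raise ValueError("group_correlation must be in [-1, 1]")
        for p in self.planted_clusters:
            if not math.isfinite(p.effect):
                raise ValueError("planted effect sizes must be finite")


# ---------------------------------------------------------------------------
# building blocks


def _load_pool() -> pd.DataFrame:
    source = resources.files("oxascreen.data") / "fragment_pool.tsv"
    with resources.as_file(source) as p:
        df = pd.read_csv(p, sep="\t", comment="#", dtype={"id": str})
    return df.fillna({"family": ""})


def generate_building_blocks(
    n: int,
    seed: int,
    heavy_range: tuple[int, int] = (6, 12),
) -> list[BuildingBlock]:
    """Deterministic sample of ``n`` distinct fragments from the bundled pool,
    restricted to the heavy-atom range."""
    pool = _load_pool()
    mols = [chem_core.parse_molecule(s, id=i) for s, i in zip(pool.smiles, pool.id)]
    lo, hi = heavy_range
    eligible = [m for m in mols if lo <= chem_core.heavy_atom_count(m) <= hi]
    if n > len(eligible):
        raise ValueError(
            f"requested {n} blocks but the pool holds {len(eligible)} in range"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(eligible), size=n, replace=False)
    return [make_block(eligible[i]) for i in sorted(picked)]


def generate_block_families(
    n_families: int,
    members_per_family: int,
    seed: int,
    level: str = "chemotype",
) -> list[BuildingBlock]:
    """Blocks with planted family structure, family members contiguous.

    ``level="chemotype"`` uses the pool's Tanimoto >= 0.7 families (for
    clustering tests); ``level="redundant"`` uses the >= 0.95 homolog series
    (for redundancy-removal tests).  When a family holds fewer distinct
    structures than requested, members are padded with id-aliased duplicates
    of existing structures -- emulating the same fragment listed by several
    vendors.
    """
    pool = _load_pool()
    prefix = {"chemotype": "fam", "redundant": "ser"}.get(level)
    if prefix is None:
        raise ValueError(f"unknown family level {level!r}")
    groups = [
        (fam, sub) for fam, sub in pool.groupby("family") if fam.startswith(prefix)
    ]
    if n_families > len(groups):
        raise ValueError(
            f"requested {n_families} families but only {len(groups)} are bundled"
        )
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(len(groups), size=n_families, replace=False))
    blocks: list[BuildingBlock] = []
    for gi in chosen:
        fam, sub = groups[gi]
        rows = list(sub.itertuples(index=False))
        for k in range(members_per_family):
            row = rows[k % len(rows)]
            alias = row.id if k < len(rows) else f"{row.id}{k:02d}"
            blocks.append(make_block(chem_core.parse_molecule(row.smiles, id=alias)))
    return blocks


def generate_compound_specs(
    blocks: Sequence[BuildingBlock], n: int, seed: int
) -> list[CompoundSpec]:
    """Random R1/R2 pairings of the given blocks, with unique identifiers
    following the ``ao-<R1>-<R2>-<combination>`` scheme."""
    rng = np.random.default_rng(seed)
    ids = [b.id for b in blocks]
    counts: dict[tuple[str, str], int] = {}
    specs = []
    for _ in range(n):
        r1, r2 = (ids[k] for k in rng.integers(0, len(ids), size=2))
        combo = counts.get((r1, r2), 0)
        counts[(r1, r2)] = combo + 1
        specs.append(
            CompoundSpec(
                identifier=compound_identifier_from_parts(r1, r2, combo),
                r1_block=r1,
                r2_block=r2,
            )
        )
    return specs


# ---------------------------------------------------------------------------
# docking records


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_docking_records(
    compounds: Sequence[CompoundSpec], params: SimulationParams
) -> list[DockingRecord]:
    """Synthetic per-compound x per-isoform docking records.

    Latent model: (q_neg, q_pos) are standard bivariate normal with Pearson
    correlation 2*sin(pi*rho/6) so that their *rank* (Spearman) correlation
    equals ``params.group_correlation``.  Planted clusters shift the stated
    group's quality for compounds carrying a member block at the stated
    position.  Scores are monotone in the group quality (affinity decreasing,
    fitness/binding/energy increasing) plus independent noise; the anchor
    pass event is an independent Bernoulli(anchor_pass_prob) per isoform,
    with passing RMSDs uniform on [0, 2) and failing ones uniform on
    [2.05, 8).
    """
    n = len(compounds)
    rng = np.random.default_rng(params.seed)
    rho_s = params.group_correlation
    rho_p = 2.0 * math.sin(math.pi * rho_s / 6.0)
    cov = np.array([[1.0, rho_p], [rho_p, 1.0]])
    lat = rng.standard_normal((n, 2)) @ np.linalg.cholesky(cov).T
    quality = {"gram_negative": lat[:, 0].copy(), "gram_positive": lat[:, 1].copy()}

    for planted in params.planted_clusters:
        attr = "r1_block" if planted.position == "R1" else "r2_block"
        mask = np.array(
            [getattr(c, attr) in planted.block_ids for c in compounds]
        )
        quality[planted.group][mask] += planted.effect

    records: list[DockingRecord] = []
    sd = params.score_noise_sd
    for iso in params.isoforms:
        group = "gram_negative" if iso.gram == "negative" else "gram_positive"
        q = quality[group]
        noise = rng.standard_normal((4, n)) * sd
        affinity = -q + noise[0]
        fitness = _sigmoid(q + noise[1])
        binding = _sigmoid(q + noise[2])
        energy = 10.0 * q + 10.0 * noise[3]
        passes = rng.random(n) < params.anchor_pass_prob
        rmsd = np.where(
            passes, 2.0 * rng.random(n), 2.05 + 5.95 * rng.random(n)
        )
        for i, c in enumerate(compounds):
            records.append(
                DockingRecord(
                    compound_id=c.identifier,
                    isoform=iso.code,
                    anchor_rmsd=float(rmsd[i]),
                    affinity=float(affinity[i]),
                    fitness=float(fitness[i]),
                    binding=float(binding[i]),
                    energy=float(energy[i]),
                )
            )
    return records


# ---------------------------------------------------------------------------
# sequence profiles


def generate_profile(
    n_positions: int,
    conserved_positions: Sequence[int],
    concentration: float,
    seed: int,
) -> SequenceProfile:
    """Dirichlet profile around the bundled background composition.

    ``conserved_positions`` (1-based) receive a 0.995 point mass on one
    random amino acid (entropy < 0.1 bits); the remaining positions are
    Dirichlet(concentration * background) draws, approaching the background
    composition (and its entropy) as the concentration grows.
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    background = load_background_composition()
    rng = np.random.default_rng(seed)
    conserved = set(conserved_positions)
    rows = []
    for pos in range(1, n_positions + 1):
        if pos in conserved:
            freq = np.full(20, 0.005 / 19)
            freq[rng.integers(0, 20)] = 0.995
        else:
            freq = rng.dirichlet(concentration * background)
        rows.append(freq)
    return SequenceProfile(
        positions=tuple(range(1, n_positions + 1)), frequencies=np.array(rows)
    )


# ---------------------------------------------------------------------------
# 3D complexes

_SPACING = 15.0  # angstroms between prescription sites; beyond every cutoff

_RING_RADIUS = 1.39


def _ring(center: np.ndarray) -> list[np.ndarray]:
    return [
        center
        + _RING_RADIUS * np.array([math.cos(a), math.sin(a), 0.0])
        for a in np.linspace(0.0, 2.0 * math.pi, 6, endpoint=False)
    ]


def generate_complex(
    prescription: Sequence[tuple[int, str]], seed: int = 0
) -> tuple[list[AtomSite], list[AtomSite]]:
    """A toy protein-ligand complex realizing exactly the prescribed
    (residue number, contact class) pairs under the default cutoffs.

    Each prescription is realized by a dedicated probe-atom group placed far
    (15 A) from every other group, so no unintended contacts arise; the whole
    complex is rigidly translated by a seeded random offset.  Returns
    (protein sites, ligand sites), writable via
    :func:`oxascreen.interaction_profiler.write_complex`.
    """
    rng = np.random.default_rng(seed)
    shift = rng.uniform(-5.0, 5.0, size=3)

    protein: list[AtomSite] = []
    ligand: list[AtomSite] = []

    def padd(element, pos, resnum, roles):
        protein.append(
            AtomSite(
                element=element,
                coordinates=tuple(np.asarray(pos) + shift),
                residue_number=resnum,
                residue_name="PRB",
                chain="A",
                molecule_role="protein",
                roles=frozenset(roles),
            )
        )

    def ladd(element, pos, roles):
        ligand.append(
            AtomSite(
                element=element,
                coordinates=tuple(np.asarray(pos) + shift),
                residue_number=1,
                residue_name="LIG",
                chain="L",
                molecule_role="ligand",
                roles=frozenset(roles),
            )
        )

    if not prescription:
        # a contact-free complex: one probe on each side, far beyond any cutoff
        padd("C", np.zeros(3), 1, {"hydrophobic"})
        ladd("C", np.array([100.0, 0.0, 0.0]), {"hydrophobic"})
        return protein, ligand

    for k, (resnum, contact_class) in enumerate(prescription):
        base = np.array([_SPACING * k, 0.0, 0.0])
        if contact_class == "hbond":
            padd("N", base, resnum, {"donor", "acceptor", "hydrophilic"})
            padd("H", base + (0.0, 0.0, -1.0), resnum, set())
            ladd("O", base + (0.0, 0.0, 2.9), {"acceptor", "hydrophilic"})
        elif contact_class == "halogen_bond":
            padd("N", base, resnum, {"donor", "acceptor", "hydrophilic"})
            padd("H", base + (0.0, 0.0, -1.0), resnum, set())
            ladd("Cl", base + (0.0, 0.0, 3.2), {"halogen"})
        elif contact_class == "aromatic":
            for p in _ring(base):
                padd("C", p, resnum, {"aromatic", "hydrophobic"})
            for p in _ring(base + (0.0, 0.0, 3.8)):
                ladd("C", p, {"aromatic", "hydrophobic"})
        elif contact_class == "hydrophobic":
            padd("C", base, resnum, {"hydrophobic"})
            ladd("C", base + (0.0, 0.0, 3.9), {"hydrophobic"})
        elif contact_class == "destabilizing":
            padd("C", base, resnum, {"hydrophobic"})
            ladd("O", base + (0.0, 0.0, 3.5), {"acceptor", "hydrophilic"})
        else:
            raise ValueError(f"unsupported contact class {contact_class!r}")
    return protein, ligand
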