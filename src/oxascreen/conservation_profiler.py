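"""Shannon-entropy conservation profiling of the BC ATP binding site.

The ATP binding site of bacterial biotin carboxylase (BC) is described by a
bundled table of 21 residue positions (E. coli numbering) carrying, per
position, the sequence entropy of a PSI-BLAST-style profile, a
ligand-binding probability/confidence pair, and the residue identity in
seven bacterial isoforms: four Gram-negative (Ec, Hi, Pa, Mc) and three
Gram-positive (Ef, Sp, Sa).  This module loads that table, computes entropy
statistics, classifies positional conservation, and derives the residue
substitutions needed to model a non-E. coli isoform on the E. coli
structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Alphabetical one-letter amino-acid order used for all 20-vectors.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_SUM_TOL = 1e-6


@dataclass(frozen=True)
class IsoformSpec:
    code: str
    name: str
    gram: str  # "negative" or "positive"


ISOFORMS: tuple[IsoformSpec, ...] = (
    IsoformSpec("Ec", "Escherichia coli", "negative"),
    IsoformSpec("Hi", "Haemophilus influenzae", "negative"),
    IsoformSpec("Pa", "Pseudomonas aeruginosa", "negative"),
    IsoformSpec("Mc", "Moraxella catarrhalis", "negative"),
    IsoformSpec("Ef", "Enterococcus faecalis", "positive"),
    IsoformSpec("Sp", "Streptococcus pneumoniae", "positive"),
    IsoformSpec("Sa", "Staphylococcus aureus", "positive"),
)

ISOFORM_CODES = tuple(s.code for s in ISOFORMS)
GRAM_NEGATIVE = tuple(s.code for s in ISOFORMS if s.gram == "negative")
GRAM_POSITIVE = tuple(s.code for s in ISOFORMS if s.gram == "positive")


def isoform(code: str) -> IsoformSpec:
    for s in ISOFORMS:
        if s.code == code:
            return s
    raise KeyError(f"unknown BC isoform code {code!r}")


@dataclass(frozen=True)
class BindingSitePosition:
    residue_number: int
    entropy_bits: float
    ligand_probability: float
    ligand_confidence: float
    residues: Mapping[str, str]  # isoform code -> one-letter amino acid


@dataclass(frozen=True)
class SequenceProfile:
    """Per-position amino-acid frequency vectors (positions x 20)."""

    positions: tuple[int, ...]
    frequencies: np.ndarray

    def __post_init__(self):
        freqs = np.asarray(self.frequencies, dtype=float)
        if freqs.shape != (len(self.positions), 20):
            raise ValueError("frequencies must be (n_positions, 20)")
        _validate_frequencies(freqs)
        object.__setattr__(self, "frequencies", freqs)


def _validate_frequencies(freq: np.ndarray) -> None:
    if np.any(freq < 0):
        raise ValueError("negative frequency entries")
    sums = freq.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > _SUM_TOL):
        raise ValueError(f"frequency vectors must sum to 1 (got {sums})")


def shannon_entropy(freq: Sequence[float]) -> float:
    """H = -sum p*log2(p) in bits, with 0*log2(0) taken as 0."""
    p = np.asarray(freq, dtype=float)
    _validate_frequencies(p)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def background_max_entropy(background: Sequence[float]) -> float:
    """Entropy of a background (generic protein-like) composition."""
    return shannon_entropy(background)


def load_background_composition(path: str | Path | None = None) -> np.ndarray:
    """Bundled Swiss-Prot-style amino-acid composition, normalized to sum 1,
    in :data:`AMINO_ACIDS` order."""
    if path is None:
        source = resources.files("oxascreen.data") / "aa_background.tsv"
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    freq = df.set_index("aa")["frequency"].reindex(list(AMINO_ACIDS))
    if freq.isna().any():
        raise ValueError("background composition missing amino acids")
    values = freq.to_numpy(dtype=float)
    return values / values.sum()


def entropy_summary(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1) standard deviation of entropies."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty entropy list")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def load_binding_site_table(
    path: str | Path | None = None,
) -> list[BindingSitePosition]:
    """Load the bundled BC binding-site residue table (21 positions)."""
    if path is None:
        source = resources.files("oxascreen.data") / "binding_site_residues.tsv"
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"residue_number", "entropy", "ligand_probability", "ligand_confidence"}
    missing = required.union(ISOFORM_CODES) - set(df.columns)
    if missing:
        raise ValueError(f"binding-site table missing columns: {sorted(missing)}")
    rows = []
    for _, row in df.iterrows():
        rows.append(
            BindingSitePosition(
                residue_number=int(row["residue_number"]),
                entropy_bits=float(row["entropy"]),
                ligand_probability=float(row["ligand_probability"]),
                ligand_confidence=float(row["ligand_confidence"]),
                residues={code: str(row[code]) for code in ISOFORM_CODES},
            )
        )
    return rows


def classify_position_conservation(
    pos: BindingSitePosition, isoforms: Sequence[IsoformSpec] = ISOFORMS
) -> str:
    """Classify a position as ``conserved_all``, ``gram_specific`` or
    ``variable`` from its per-isoform residue identities.

    ``gram_specific`` means uniform within each Gram group but different
    between the two groups (e.g. M169 in Gram-negative vs I169 in
    Gram-positive species).
    """
    neg = {pos.residues[s.code] for s in isoforms if s.gram == "negative"}
    pos_ = {pos.residues[s.code] for s in isoforms if s.gram == "positive"}
    if len(neg | pos_) == 1:
        return "conserved_all"
    if len(neg) == 1 and len(pos_) == 1:
        return "gram_specific"
    return "variable"


def mutated_binding_site(
    target: str,
    table: Sequence[BindingSitePosition] | None = None,
    reference: str = "Ec",
) -> list[tuple[int, str, str]]:
    """Substitutions (residue number, from, to) turning the reference
    isoform's binding site into the target's.  Positions where the two agree
    are omitted; reference -> reference is empty."""
    isoform(target)  # validate code
    isoform(reference)
    if table is None:
        table = load_binding_site_table()
    subs = []
    for pos in table:
        src, dst = pos.residues[reference], pos.residues[target]
        if src != dst:
            subs.append((pos.residue_number, src, dst))
    return subs


# ---------------------------------------------------------------------------
# profile input


def read_profile_tsv(path: str | Path) -> SequenceProfile:
    """TSV with a ``position`` column followed by the 20 amino-acid columns."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(AMINO_ACIDS) - set(df.columns)
    if missing:
        raise ValueError(f"profile missing amino-acid columns: {sorted(missing)}")
    freqs = df[list(AMINO_ACIDS)].to_numpy(dtype=float)
    return SequenceProfile(
        positions=tuple(int(p) for p in df["position"]), frequencies=freqs
    )


def write_profile_tsv(path: str | Path, profile: SequenceProfile) -> None:
    df = pd.DataFrame(profile.frequencies, columns=list(AMINO_ACIDS))
    df.insert(0, "position", profile.positions)
    df.to_csv(path, sep="\t", index=False)


def profile_from_alignment(path: str | Path, pseudocount: float = 0.0) -> SequenceProfile:
    """Column amino-acid frequencies of a FASTA multiple alignment.

    Gap characters and letters outside the 20 standard amino acids are
    ignored; columns with no countable residues are dropped.
    """
    from Bio import AlignIO

    alignment = AlignIO.read(str(path), "fasta")
    index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    positions, rows = [], []
    for col in range(alignment.get_alignment_length()):
        counts = np.full(20, pseudocount, dtype=float)
        for record in alignment:
            aa = record.seq[col].upper()
            if aa in index:
                counts[index[aa]] += 1.0
        total = counts.sum()
        if total > 0:
            positions.append(col + 1)
            rows.append(counts / total)
    return SequenceProfile(positions=tuple(positions), frequencies=np.array(rows))


def profile_entropies(profile: SequenceProfile) -> np.ndarray:
    return np.array([shannon_entropy(f) for f in profile.frequencies])
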