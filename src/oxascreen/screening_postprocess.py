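"""Post-processing of multi-isoform docking results.

A virtual screen of the amino-oxazole library against the seven BC isoforms
produces one record per compound x isoform carrying the anchor RMSD (how far
the docked amino-oxazole substructure sits from its reference pose) and four
docking scores.  This module implements everything downstream of the docking
engine:

* anchor-consistency filtering (compound kept iff the anchor is reproduced
  within a cutoff in *every* isoform),
* the joint-probability estimate of per-docking accuracy, p = f^(1/k),
* SUM-rule consensus ranking: scores are rank-fused per isoform, then the
  per-isoform consensus ranks are fused across the isoforms of a Gram group,
* Pearson rank correlation between consensus lists, and
* simple threshold counting of benchmark pose RMSDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .conservation_profiler import GRAM_NEGATIVE, GRAM_POSITIVE, ISOFORM_CODES

#: The four docking scores and the direction in which a value is *better*.
#: Affinity is a predicted ln Ki, so lower is better; fitness and binding
#: are probabilities in [0, 1]; the refinement interaction energy is
#: reported such that top-ranked compounds carry large positive values.
SCORE_DIRECTIONS: dict[str, str] = {
    "affinity": "lower",
    "fitness": "higher",
    "binding": "higher",
    "energy": "higher",
}

GROUPS: dict[str, tuple[str, ...]] = {
    "gram_negative": GRAM_NEGATIVE,
    "gram_positive": GRAM_POSITIVE,
    "all": ISOFORM_CODES,
}


@dataclass(frozen=True)
class DockingRecord:
    compound_id: str
    isoform: str
    anchor_rmsd: float
    affinity: float
    fitness: float
    binding: float
    energy: float

    def __post_init__(self):
        if self.anchor_rmsd < 0:
            raise ValueError(f"negative anchor RMSD for {self.compound_id}")
        for name in ("fitness", "binding"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(
                    f"{name}={v} outside [0,1] for {self.compound_id}"
                )

    def score(self, name: str) -> float:
        if name not in SCORE_DIRECTIONS:
            raise KeyError(f"unknown docking score {name!r}")
        return getattr(self, name)


@dataclass(frozen=True)
class RankedList:
    """A consensus-ordered compound list.

    ``ids`` is the final deterministic ordering (best first, ties broken by
    compound id); ``rank_values`` maps each id to its 1-based rank with ties
    averaged; ``sums`` holds the underlying fused rank sums (equal to
    ``rank_values`` for a single-score ranking).
    """

    ids: tuple[str, ...]
    rank_values: Mapping[str, float]
    sums: Mapping[str, float]

    def __len__(self) -> int:
        return len(self.ids)

    def relative_rank(self, compound_id: str) -> float:
        return self.rank_values[compound_id] / len(self.ids)

    def relative_ranks(self, order: Sequence[str] | None = None) -> np.ndarray:
        ids = self.ids if order is None else order
        n = len(self.ids)
        return np.array([self.rank_values[i] / n for i in ids])


def _make_ranked(ids: Sequence[str], keys: np.ndarray) -> RankedList:
    """Rank ``ids`` ascending by ``keys`` (average ranks for ties, final
    ordering tie-broken by id)."""
    ranks = stats.rankdata(keys, method="average")
    rank_values = dict(zip(ids, ranks))
    sums = dict(zip(ids, (float(k) for k in keys)))
    order = sorted(ids, key=lambda i: (sums[i], i))
    return RankedList(ids=tuple(order), rank_values=rank_values, sums=sums)


def anchor_consistency_filter(
    records: Iterable[DockingRecord],
    isoforms: Sequence[str] = ISOFORM_CODES,
    cutoff: float = 2.0,
) -> set[str]:
    """Compounds whose anchor RMSD is <= cutoff in *all* listed isoforms.

    A compound missing a record for any listed isoform fails.  When several
    records exist for the same compound x isoform, all must pass.
    """
    if not isoforms:
        raise ValueError("empty isoform set")
    wanted = set(isoforms)
    seen: dict[str, set[str]] = {}
    failed: set[str] = set()
    for r in records:
        if r.isoform not in wanted:
            continue
        seen.setdefault(r.compound_id, set()).add(r.isoform)
        if r.anchor_rmsd > cutoff:
            failed.add(r.compound_id)
    return {
        cid for cid, isos in seen.items() if isos == wanted and cid not in failed
    }


def docking_accuracy(pass_fraction: float, k: int) -> float:
    """Per-docking accuracy from the joint pass fraction over k independent
    dockings: p = f^(1/k)."""
    if not 0.0 < pass_fraction <= 1.0:
        raise ValueError(f"pass fraction must be in (0, 1], got {pass_fraction}")
    if k < 1:
        raise ValueError("k must be >= 1")
    return pass_fraction ** (1.0 / k)


def rank_by_score(
    records: Sequence[DockingRecord],
    score: str,
    direction: str | None = None,
) -> RankedList:
    """Rank one isoform's records by a single score (rank 1 = best).

    ``direction`` overrides the documented default for that score; ties get
    average ranks.
    """
    if direction is None:
        direction = SCORE_DIRECTIONS[score]  # KeyError for unknown scores
    ids = [r.compound_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("rank_by_score requires one record per compound")
    values = np.array([r.score(score) for r in records], dtype=float)
    keys = values if direction == "lower" else -values
    return _make_ranked(ids, keys)


def fuse_scores_sum(rank_lists: Sequence[RankedList]) -> RankedList:
    """SUM-rule data fusion: fused score = sum of per-list ranks, re-ranked
    ascending (smaller rank sum = better)."""
    if not rank_lists:
        raise ValueError("no rank lists to fuse")
    id_set = set(rank_lists[0].ids)
    for rl in rank_lists[1:]:
        if set(rl.ids) != id_set:
            raise ValueError("rank lists cover different compound sets")
    ids = sorted(id_set)
    sums = np.array(
        [sum(rl.rank_values[i] for rl in rank_lists) for i in ids]
    )
    return _make_ranked(ids, sums)


def fuse_isoform(
    records: Sequence[DockingRecord],
    scores: Sequence[str] = ("affinity", "fitness", "binding", "energy"),
    directions: Mapping[str, str] | None = None,
) -> RankedList:
    """Per-isoform consensus: rank by each docking score, then SUM-fuse."""
    directions = dict(directions or {})
    lists = [rank_by_score(records, s, directions.get(s)) for s in scores]
    return fuse_scores_sum(lists)


def group_consensus(
    fused_by_isoform: Mapping[str, RankedList], group: str
) -> RankedList:
    """Cross-isoform consensus for ``gram_negative``, ``gram_positive`` or
    ``all``: SUM-rule fusion of the per-isoform fused lists of the group."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    members = [c for c in GROUPS[group] if c in fused_by_isoform]
    if not members:
        raise ValueError(f"no isoform lists available for group {group!r}")
    return fuse_scores_sum([fused_by_isoform[c] for c in members])


def rank_correlation(list_a: RankedList, list_b: RankedList) -> float:
    """Pearson correlation of relative ranks over the shared compound set."""
    if set(list_a.ids) != set(list_b.ids):
        raise ValueError("ranked lists cover different compounds")
    if len(list_a) < 2:
        raise ValueError("need at least two compounds")
    order = sorted(list_a.ids)
    r, _ = stats.pearsonr(list_a.relative_ranks(order), list_b.relative_ranks(order))
    return float(r)


def count_poses_within(rmsds: Sequence[float], cutoff: float = 2.0) -> int:
    """Number of pose RMSDs strictly below the cutoff."""
    arr = np.asarray(rmsds, dtype=float)
    if np.any(arr < 0):
        raise ValueError("negative RMSD")
    return int((arr < cutoff).sum())


# ---------------------------------------------------------------------------
# file formats and bundled fixtures


_RECORD_COLUMNS = [
    "compound_id", "isoform", "anchor_rmsd", "affinity", "fitness", "binding", "energy",
]


def read_docking_records(path: str | Path) -> list[DockingRecord]:
    """Read a docking-record TSV (one row per compound x isoform); value
    ranges are validated by the record constructor."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"docking records missing columns: {sorted(missing)}")
    return [
        DockingRecord(
            compound_id=str(r.compound_id),
            isoform=str(r.isoform),
            anchor_rmsd=float(r.anchor_rmsd),
            affinity=float(r.affinity),
            fitness=float(r.fitness),
            binding=float(r.binding),
            energy=float(r.energy),
        )
        for r in df.itertuples(index=False)
    ]


def write_docking_records(path: str | Path, records: Iterable[DockingRecord]) -> None:
    df = pd.DataFrame([r.__dict__ for r in records], columns=_RECORD_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def write_ranked_list(path: str | Path, ranked: RankedList) -> None:
    """TSV: rank, relative_rank, compound_id, fused_sum (best first)."""
    n = len(ranked)
    with open(path, "w") as fh:
        fh.write("rank\trelative_rank\tcompound_id\tfused_sum\n")
        for pos, cid in enumerate(ranked.ids, start=1):
            fh.write(
                f"{pos}\t{ranked.rank_values[cid] / n:.6g}\t{cid}\t"
                f"{ranked.sums[cid]:.6g}\n"
            )


def load_crossdock_benchmark() -> pd.DataFrame:
    """Bundled cross-docking benchmark table (14 ligands, per-method RMSDs)."""
    source = resources.files("oxascreen.data") / "crossdock_benchmark.tsv"
    with resources.as_file(source) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def load_top_compound_scores() -> list[DockingRecord]:
    """Bundled docking scores of five top-ranked compounds (Ec and Sp)."""
    source = resources.files("oxascreen.data") / "top_compound_scores.tsv"
    with resources.as_file(source) as p:
        return read_docking_records(p)
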