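"""Building-block clustering and BEDROC enrichment of R-group chemotypes.

To ask *which* fragment families drive good consensus ranks, building blocks
are grouped into chemotype clusters by greedy leader clustering at a
Tanimoto threshold (default 0.7).  For each cluster and R-group position the
compounds carrying a member block at that position are treated as "actives"
inside the consensus-ranked library, and their early enrichment is scored
with BEDROC (Boltzmann-enhanced discrimination of ROC; exponential weight
``alpha``, default 20 — the standard early-recognition setting).  The
difference between the Gram-negative and Gram-positive scores of a cluster
(delta-BEDROC) highlights chemotypes with group-specific preference; |delta|
above 0.05 is conventionally flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .chem_core import fingerprint, tanimoto
from .library_builder import BuildingBlock, parse_identifier
from .screening_postprocess import RankedList

DELTA_FLAG_THRESHOLD = 0.05


@dataclass(frozen=True)
class BlockCluster:
    cluster_id: int
    members: tuple[str, ...]  # block ids, leader first


@dataclass(frozen=True)
class EnrichmentCell:
    cluster_id: int
    position: str  # "R1" or "R2"
    group: str  # "gram_negative" or "gram_positive"
    bedroc: float
    n_actives: int
    n_total: int


def cluster_blocks(
    blocks: Sequence[BuildingBlock], threshold: float = 0.7
) -> list[BlockCluster]:
    """Greedy leader clustering in input order.

    Each block joins the first existing cluster whose *leader* it matches at
    Tanimoto >= threshold, else founds a new cluster.  Deterministic given
    input order; leaders re-cluster to themselves (idempotent on leaders).
    """
    leaders: list = []  # fingerprints of cluster leaders
    clusters: list[list[str]] = []
    for b in blocks:
        fp = fingerprint(b.mol)
        for ci, leader_fp in enumerate(leaders):
            if tanimoto(fp, leader_fp) >= threshold:
                clusters[ci].append(b.id)
                break
        else:
            leaders.append(fp)
            clusters.append([b.id])
    return [
        BlockCluster(cluster_id=i, members=tuple(m)) for i, m in enumerate(clusters)
    ]


def cluster_representative(
    cluster: BlockCluster, blocks: Mapping[str, BuildingBlock]
) -> str:
    """The member maximizing mean Tanimoto to its co-members (lowest id on
    ties); a singleton represents itself."""
    if not cluster.members:
        raise ValueError("empty cluster")
    if len(cluster.members) == 1:
        return cluster.members[0]
    fps = {m: fingerprint(blocks[m].mol) for m in cluster.members}
    best_id, best_mean = None, -1.0
    for m in sorted(cluster.members):
        mean = np.mean(
            [tanimoto(fps[m], fps[o]) for o in cluster.members if o != m]
        )
        if mean > best_mean + 1e-12:
            best_id, best_mean = m, mean
    return best_id


def bedroc(n_total: int, active_ranks: Sequence[int], alpha: float = 20.0) -> float:
    """BEDROC early-recognition enrichment score in [0, 1].

    ``active_ranks`` are the 1-based ranks of the actives within an ordered
    list of ``n_total`` compounds.  Degenerate inputs (no actives, or all
    compounds active) are rejected: the underlying formula is singular there.
    """
    n = len(active_ranks)
    if n == 0:
        raise ValueError("BEDROC undefined with no actives")
    if n >= n_total:
        raise ValueError("BEDROC undefined when every compound is active")
    ranks = np.asarray(active_ranks, dtype=float)
    if np.any(ranks < 1) or np.any(ranks > n_total):
        raise ValueError("active ranks must lie in [1, n_total]")
    ra = n / n_total
    s = float(np.exp(-alpha * ranks / n_total).sum())
    rie = s / ((n / n_total) * (1.0 - math.exp(-alpha)) / (math.exp(alpha / n_total) - 1.0))
    factor = ra * math.sinh(alpha / 2.0) / (
        math.cosh(alpha / 2.0) - math.cosh(alpha / 2.0 - alpha * ra)
    )
    constant = 1.0 / (1.0 - math.exp(alpha * (1.0 - ra)))
    return rie * factor + constant


def position_actives(
    ranking: RankedList, cluster: BlockCluster, position: str
) -> list[int]:
    """1-based ranks of compounds whose block at ``position`` ("R1" or "R2")
    belongs to the cluster.  Compound identifiers must follow the
    ``ao-<R1>-<R2>-<combination>`` scheme."""
    if position not in ("R1", "R2"):
        raise ValueError(f"position must be 'R1' or 'R2', got {position!r}")
    members = set(cluster.members)
    idx = 0 if position == "R1" else 1
    ranks = []
    for pos, cid in enumerate(ranking.ids, start=1):
        parts = parse_identifier(cid)  # raises on malformed ids
        if parts[idx] in members:
            ranks.append(pos)
    return ranks


def enrichment_cells(
    ranking: RankedList,
    clusters: Sequence[BlockCluster],
    position: str,
    group: str,
    alpha: float = 20.0,
) -> list[EnrichmentCell]:
    """BEDROC per cluster at one position against one group's consensus.

    Clusters whose membership is degenerate for the ranking (no actives, or
    all compounds active) are skipped: BEDROC is undefined there.
    """
    n_total = len(ranking)
    cells = []
    for cluster in clusters:
        ranks = position_actives(ranking, cluster, position)
        if not ranks or len(ranks) >= n_total:
            continue
        cells.append(
            EnrichmentCell(
                cluster_id=cluster.cluster_id,
                position=position,
                group=group,
                bedroc=bedroc(n_total, ranks, alpha=alpha),
                n_actives=len(ranks),
                n_total=n_total,
            )
        )
    return cells


def delta_bedroc(cell_neg: EnrichmentCell, cell_pos: EnrichmentCell) -> float:
    """BEDROC(Gram-negative) - BEDROC(Gram-positive) for one cluster/position."""
    if (cell_neg.cluster_id, cell_neg.position) != (cell_pos.cluster_id, cell_pos.position):
        raise ValueError("delta-BEDROC requires matching cluster and position")
    return cell_neg.bedroc - cell_pos.bedroc


def is_flagged(delta: float, threshold: float = DELTA_FLAG_THRESHOLD) -> bool:
    """Whether a delta-BEDROC value indicates group-specific enrichment."""
    return abs(delta) > threshold


def write_enrichment_table(path, cells: Iterable[EnrichmentCell]) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tposition\tgroup\tbedroc\tn_actives\tn_total\n")
        for c in cells:
            fh.write(
                f"{c.cluster_id}\t{c.position}\t{c.group}\t{c.bedroc:.6f}\t"
                f"{c.n_actives}\t{c.n_total}\n"
            )


def write_delta_table(
    path,
    deltas: Iterable[tuple[int, str, float]],
    threshold: float = DELTA_FLAG_THRESHOLD,
) -> None:
    """TSV of (cluster, position, delta) rows with a flag column."""
    with open(path, "w") as fh:
        fh.write("cluster_id\tposition\tdelta_bedroc\tflagged\n")
        for cluster_id, position, delta in deltas:
            fh.write(
                f"{cluster_id}\t{position}\t{delta:.6f}\t"
                f"{int(is_flagged(delta, threshold))}\n"
            )


def write_cluster_members(path, clusters: Iterable[BlockCluster]) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tblock_id\tis_leader\n")
        for c in clusters:
            for i, m in enumerate(c.members):
                fh.write(f"{c.cluster_id}\t{m}\t{int(i == 0)}\n")
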