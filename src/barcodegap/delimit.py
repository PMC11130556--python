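"""Distance-threshold species delimitation and congruence scoring.

Objective clustering: putative species are the connected components of the
graph with an edge wherever the pairwise distance is strictly below a
threshold (single linkage; the conventional barcode threshold of 3% is the
default).  On top of that, every distinct single-linkage partition is ranked
by a transparent relative barcode-gap statistic — these are "ASAP-like"
ranked partitions, explicitly not the published ASAP probability score.

Any partition (from here or an external tool) can be classified against
reference species labels: each species comes out congruent, split, lumped or
mixed.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distances import DistanceMatrix

DEFAULT_THRESHOLD = 0.03


@dataclass
class Partition:
    """A clustering of records; cluster ids are contiguous from 1 in
    first-seen record order."""

    assignment: dict[str, int]
    threshold: float | None = None

    @property
    def k(self) -> int:
        return len(set(self.assignment.values()))

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = defaultdict(list)
        for rid, cid in self.assignment.items():
            out[cid].append(rid)
        return dict(out)


@dataclass
class RankedPartition:
    partition: Partition
    gap_score: float
    rank: int
    # threshold interval (low, high] on which this partition is obtained
    interval: tuple[float, float]


class CongruenceStatus(enum.Enum):
    CONGRUENT = "congruent"
    SPLIT = "split"
    LUMPED = "lumped"
    MIXED = "mixed"


@dataclass
class PartitionComparison:
    status: dict[str, CongruenceStatus]

    @property
    def counts(self) -> dict[CongruenceStatus, int]:
        c = {s: 0 for s in CongruenceStatus}
        for s in self.status.values():
            c[s] += 1
        return c

    @property
    def n_congruent(self) -> int:
        return self.counts[CongruenceStatus.CONGRUENT]


def _require_defined(m: DistanceMatrix) -> None:
    if m.has_undefined:
        raise ValueError("distance matrix has undefined entries; cannot cluster")


def _relabel_first_seen(labels: np.ndarray, ids: list[str]) -> dict[str, int]:
    mapping: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for rid, raw in zip(ids, labels):
        if raw not in mapping:
            mapping[raw] = len(mapping) + 1
        assignment[rid] = mapping[raw]
    return assignment


def single_linkage_clusters(m: DistanceMatrix, t: float = DEFAULT_THRESHOLD) -> Partition:
    """Connected components of the graph with an edge wherever d < t.

    The comparison is strict, so records exactly at the threshold stay apart.
    Cluster ids are assigned 1, 2, ... in first-seen record order, making the
    labelling deterministic for a given matrix.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    _require_defined(m)
    adj = csr_matrix((m.d < t) & ~np.eye(len(m.ids), dtype=bool))
    _, raw = connected_components(adj, directed=False)
    return Partition(assignment=_relabel_first_seen(raw, m.ids), threshold=t)


def merge_heights(m: DistanceMatrix) -> list[float]:
    """Strictly increasing single-linkage merge heights.

    Clustering is constant for thresholds within (h_i, h_{i+1}]: any t in that
    interval joins exactly the edges with d <= h_i.
    """
    _require_defined(m)
    if len(m.ids) < 2:
        raise ValueError("merge heights need at least 2 records")
    Z = linkage(m.condensed(), method="single")
    heights = sorted(set(float(h) for h in Z[:, 2]))
    return heights


def ranked_partitions(m: DistanceMatrix, max_results: int = 10) -> list[RankedPartition]:
    """Candidate partitions ranked by relative barcode-gap width.

    One candidate per merge-height interval: the partition obtained just above
    height h_i (edges d <= h_i merged) is scored
    ``(h_{i+1} - h_i) / h_{i+1}`` — the relative width of the distance gap it
    sits in — with the maximum observed distance standing in for the height
    above the final merge.  Sorted by score descending, ties broken by fewer
    clusters.  A degenerate matrix (all distances equal) yields the single
    one-cluster candidate with score 0.
    """
    if len(m.ids) < 3:
        raise ValueError("ranked partitions need at least 3 records")
    heights = merge_heights(m)
    d_max = float(np.nanmax(m.d))
    candidates: list[tuple[float, int, Partition, tuple[float, float]]] = []
    for i, h in enumerate(heights):
        h_next = heights[i + 1] if i + 1 < len(heights) else d_max
        # partition valid on (h, h_next]: strict d < t with t just above h
        part = single_linkage_clusters(m, t=np.nextafter(h, 1.0))
        part.threshold = h
        score = (h_next - h) / h_next if h_next > 0 else 0.0
        candidates.append((score, part.k, part, (h, h_next)))
    candidates.sort(key=lambda c: (-c[0], c[1]))
    out = []
    for rank, (score, _, part, interval) in enumerate(candidates[:max_results], start=1):
        out.append(RankedPartition(partition=part, gap_score=score, rank=rank,
                                   interval=interval))
    return out


def compare_partition(
    p: Partition, labels: Mapping[str, str]
) -> PartitionComparison:
    """Classify every reference species against a partition.

    congruent — the species' records form exactly one cluster holding no other
    species' records; split — they occupy two or more clusters, none shared
    with another species; lumped — all in one cluster that also holds other
    species; mixed — anything else (spread over several clusters of which at
    least one is shared).
    """
    missing = [rid for rid in p.assignment if rid not in labels]
    if missing:
        raise ValueError(f"records without a species label: {missing}")
    by_species: dict[str, set[int]] = defaultdict(set)
    for rid, cid in p.assignment.items():
        by_species[labels[rid]].add(cid)
    cluster_species: dict[int, set[str]] = defaultdict(set)
    for rid, cid in p.assignment.items():
        cluster_species[cid].add(labels[rid])
    status: dict[str, CongruenceStatus] = {}
    for sp, cids in by_species.items():
        pure = all(cluster_species[c] == {sp} for c in cids)
        if len(cids) == 1:
            status[sp] = CongruenceStatus.CONGRUENT if pure else CongruenceStatus.LUMPED
        else:
            status[sp] = CongruenceStatus.SPLIT if pure else CongruenceStatus.MIXED
    return PartitionComparison(status=status)


def write_partition_tsv(p: Partition, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# record_id\tcluster_id\n")
        for rid, cid in p.assignment.items():
            fh.write(f"{rid}\t{cid}\n")


def read_partition_tsv(path: str | Path) -> Partition:
    assignment: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rid, cid = line.split("\t")[:2]
            assignment[rid] = int(cid)
    if not assignment:
        raise ValueError(f"no assignments found in {path}")
    return Partition(assignment=assignment)


def ranked_partitions_report(ranked: list[RankedPartition]) -> str:
    lines = ["rank\tk\tinterval_low\tinterval_high\tgap_score"]
    for rp in ranked:
        lines.append(
            f"{rp.rank}\t{rp.partition.k}\t{rp.interval[0]:.6f}\t"
            f"{rp.interval[1]:.6f}\t{rp.gap_score:.4f}"
        )
    return "\n".join(lines) + "\n"


def write_comparison_tsv(cmp: PartitionComparison, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("species\tstatus\n")
        for sp, st in cmp.status.items():
            fh.write(f"{sp}\t{st.value}\n")
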