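"""Best-first single-linkage read clustering.

Scored overlaps are sorted from most to least compatible (descending score
D, with deterministic tie-breaking) and processed in one pass: each overlap
merges the clusters of its two reads unless the union would exceed the
cluster-size cap.  Sorting dominates the cost, O(n log n + n) overall,
thanks to a path-compressed union-find.  The cap is what makes the
best-first order matter: without it the partition would collapse to the
connected components of the filtered overlap graph.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from math import inf
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

from .io_qc import SequencingRead, write_fastq
from .overlaps import ScoredOverlap

logger = logging.getLogger(__name__)

DEFAULT_MAX_CLUSTER = 3000
DEFAULT_MIN_CLUSTER = 3


class DisjointSet:
    """Union-find with path compression and union by size."""

    def __init__(self) -> None:
        self._parent: Dict[str, str] = {}
        self._size: Dict[str, int] = {}

    def add(self, x: str) -> None:
        if x not in self._parent:
            self._parent[x] = x
            self._size[x] = 1

    def find(self, x: str) -> str:
        self.add(x)
        root = x
        while self._parent[root] != root:
            root = self._parent[root]
        while self._parent[x] != root:  # path compression
            self._parent[x], x = root, self._parent[x]
        return root

    def size(self, x: str) -> int:
        return self._size[self.find(x)]

    def union(self, a: str, b: str) -> str:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return ra
        if self._size[ra] < self._size[rb]:
            ra, rb = rb, ra
        self._parent[rb] = ra
        self._size[ra] += self._size[rb]
        return ra


@dataclass
class ClusterSet:
    """A partition of reads into clusters (dense integer ids from 0)."""

    assignments: Dict[str, int] = field(default_factory=dict)
    clusters: Dict[int, List[str]] = field(default_factory=dict)
    max_size: float = DEFAULT_MAX_CLUSTER
    n_singletons: int = 0

    def validate(self) -> None:
        seen: set[str] = set()
        for cid, members in self.clusters.items():
            if len(members) > self.max_size:
                raise AssertionError(f"cluster {cid} exceeds max_size")
            for rid in members:
                if rid in seen or self.assignments.get(rid) != cid:
                    raise AssertionError(f"read {rid} not uniquely assigned")
                seen.add(rid)
        if seen != set(self.assignments):
            raise AssertionError("assignments and clusters disagree")


def sort_by_score(scored: Iterable[ScoredOverlap]) -> List[ScoredOverlap]:
    """Sort overlaps best-first: descending D, ties by higher identity,
    longer overlap, then lexicographic (id_a, id_b).  Stable."""
    return sorted(scored, key=lambda s: (-s.D, -s.i, -s.o, s.id_a, s.id_b))


def single_linkage_cluster(
    ordered: Sequence[ScoredOverlap],
    max_size: float = DEFAULT_MAX_CLUSTER,
    all_read_ids: Optional[Iterable[str]] = None,
) -> ClusterSet:
    """One-pass size-capped single-linkage over best-first-sorted overlaps.

    For each overlap (a, b), the clusters of a and b are merged when they
    are distinct and their combined size stays within ``max_size``.  Reads
    named in ``all_read_ids`` but in no retained overlap become singletons.
    With ``max_size = inf`` the result equals the connected components of
    the overlap graph.  Raises if the input is not sorted descending by D.
    """
    ds = DisjointSet()
    prev_d = inf
    for s in ordered:
        if s.D > prev_d + 1e-12:
            raise ValueError("overlaps are not sorted descending by score")
        prev_d = s.D
        ds.add(s.id_a)
        ds.add(s.id_b)
        if ds.find(s.id_a) != ds.find(s.id_b):
            if ds.size(s.id_a) + ds.size(s.id_b) <= max_size:
                ds.union(s.id_a, s.id_b)
    if all_read_ids is not None:
        for rid in all_read_ids:
            ds.add(rid)

    by_root: Dict[str, List[str]] = {}
    for rid in ds._parent:
        by_root.setdefault(ds.find(rid), []).append(rid)
    # dense ids, deterministic: clusters ordered by their smallest member id
    groups = sorted(by_root.values(), key=lambda m: min(m))
    cs = ClusterSet(max_size=max_size)
    for cid, members in enumerate(groups):
        members.sort()
        cs.clusters[cid] = members
        for rid in members:
            cs.assignments[rid] = cid
    cs.n_singletons = sum(1 for m in cs.clusters.values() if len(m) == 1)
    return cs


def emit_cluster_reads(
    clusters: ClusterSet,
    reads: Mapping[str, SequencingRead],
    outdir: str | Path,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER,
) -> Path:
    """Write one FASTQ per assembly-eligible cluster plus a manifest TSV.

    Clusters smaller than ``min_cluster_size`` are routed to an
    ``unclustered.fastq`` pool (reported, excluded from local assembly).
    Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rid in clusters.assignments:
        if rid not in reads:
            raise KeyError(f"read {rid!r} assigned to a cluster but missing from the store")
    unclustered: List[SequencingRead] = []
    manifest_rows = []
    for cid in sorted(clusters.clusters):
        members = clusters.clusters[cid]
        if len(members) < min_cluster_size:
            unclustered.extend(reads[rid] for rid in members)
            continue
        write_fastq((reads[rid] for rid in members), outdir / f"cluster_{cid}.fastq")
        manifest_rows.append((cid, len(members)))
    write_fastq(unclustered, outdir / "unclustered.fastq")
    manifest = outdir / "manifest.tsv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["cluster_id", "n_reads"])
        for row in manifest_rows:
            w.writerow(row)
    with open(outdir / "assignments.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["read_id", "cluster_id"])
        for rid in sorted(clusters.assignments):
            w.writerow([rid, clusters.assignments[rid]])
    logger.info(
        "clustering: %d clusters written, %d reads unclustered",
        len(manifest_rows),
        len(unclustered),
    )
    return manifest
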