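"""Per-cluster strain-aware assembly on an iterated overlap graph.

Each read cluster is assembled by (1) computing dovetail overlaps among the
cluster sequences at a strict identity threshold, (2) collapsing maximal
branch-free paths of the transitively-reduced layout graph into
quality-weighted consensus super-reads, and (3) repeating on the
super-reads until no merge happens.  The strict identity (default 0.99) is
the strain-separation mechanism: a single mismatch inside a typical
short-read overlap already pushes the overlap below threshold, so reads
from different strains do not join wherever they differ, while the
consensus removes sequencing errors within a strain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .dna import CODE_BASE, encode
from .graph import (
    AssemblyGraph,
    GEdge,
    Node,
    Support,
    build_graph,
    chain_offsets,
    linear_paths,
    resolve_containment,
    transitive_reduce,
)
from .io_qc import SequencingRead
from .overlaps import OverlapParams, find_overlaps_detailed, score_overlap, filter_overlaps

logger = logging.getLogger(__name__)


class InconsistentOffsets(ValueError):
    """Path offsets imply sub-threshold agreement; the path is rejected."""


def polish_reads(
    reads: Mapping[str, SequencingRead],
    scored: Sequence,
    min_share: float = 0.8,
    min_votes: int = 3,
) -> int:
    """Correct sequencing errors in reads by overlap-pileup majority vote.

    Every permissively-filtered overlap (the clustering-stage set, identity
    >= 0.9) stacks the partner's bases onto the read.  A base is replaced
    only when the winning alternative holds at least ``min_share`` of the
    column's votes (and ``min_votes`` absolute): true strain variants sit
    near 50/50 in mixed pileups and are left untouched, while isolated
    sequencing errors are outvoted.  Only substitution-style overlaps
    (equal spans on both sequences) contribute.  Returns the number of
    corrected bases; reads are modified in place.
    """
    enc: Dict[str, np.ndarray] = {
        rid: encode(r.bases) for rid, r in reads.items()
    }
    votes: Dict[str, np.ndarray] = {}

    def _votes_for(rid: str) -> np.ndarray:
        v = votes.get(rid)
        if v is None:
            v = np.zeros((4, len(enc[rid])), dtype=np.int16)
            own = enc[rid]
            ok = own < 4
            v[own[ok], np.nonzero(ok)[0]] += 1
            votes[rid] = v
        return v

    for s in scored:
        h = s.hit
        if (h.a_end - h.a_start) != (h.b_end - h.b_start):
            continue  # indel-containing overlap; skip for pileup purposes
        a_seg = enc[h.id_a][h.a_start : h.a_end]
        b_seg = enc[h.id_b][h.b_start : h.b_end]
        if h.strand != "same":
            b_seg = (3 - b_seg[::-1]) % 4  # reverse complement (N-safe below)
            b_valid = enc[h.id_b][h.b_start : h.b_end][::-1] < 4
        else:
            b_valid = b_seg < 4
        a_valid = a_seg < 4
        va = _votes_for(h.id_a)
        idx = np.arange(h.a_start, h.a_end)
        m = b_valid
        va[b_seg[m] % 4, idx[m]] += 1
        vb = _votes_for(h.id_b)
        if h.strand == "same":
            a_to_b = a_seg
            idx_b = np.arange(h.b_start, h.b_end)
            mm = a_valid
        else:
            a_to_b = (3 - a_seg[::-1]) % 4
            idx_b = np.arange(h.b_start, h.b_end)
            mm = a_valid[::-1]
        vb[a_to_b[mm] % 4, idx_b[mm]] += 1

    n_corrected = 0
    for rid, v in votes.items():
        own = enc[rid]
        total = v.sum(axis=0)
        winner = np.argmax(v, axis=0).astype(np.uint8)
        wcount = v[winner, np.arange(v.shape[1])]
        fix = (
            (winner != own)
            & (own < 4)
            & (wcount >= min_votes)
            & (wcount >= min_share * total)
        )
        if fix.any():
            read = reads[rid]
            codes = own.copy()
            codes[fix] = winner[fix]
            read.bases = CODE_BASE[codes].tobytes().decode("ascii")
            n_corrected += int(fix.sum())
    return n_corrected


@dataclass(slots=True)
class LocalParams:
    """Thresholds for the local (within-cluster) assembly stage."""

    local_min_identity: float = 0.99
    local_min_ovlen: int = 30
    # layout edges must span a substantial fraction of a read so that
    # SNP-free micro-overlaps between near-identical strains never join
    # reads that a longer overlap would separate
    local_min_ovlen_frac: float = 0.6
    # layout edges and containments tolerate at most this many mismatching
    # columns; with pileup-polished reads a budget of 0 is what separates
    # strains (any surviving disagreement marks a linked variant)
    max_overlap_mismatch: int = 0
    # consensus columns supported by fewer reads than this are trimmed
    # from super-read tips (tip bases covered once cannot be error-checked)
    min_tip_depth: int = 2
    max_iterations: int = 20
    min_contig_out: int = 300
    consensus_min_node_identity: float = 0.9

    def overlap_params(self) -> OverlapParams:
        return OverlapParams(
            min_ovlen=self.local_min_ovlen,
            min_identity=self.local_min_identity,
            min_ovlen_frac=self.local_min_ovlen_frac,
            max_mismatch=self.max_overlap_mismatch,
        )


@dataclass(slots=True)
class SuperRead:
    """A consensus sequence with the placements of its supporting reads."""

    id: str
    sequence: str
    support: List[Support]
    quals: np.ndarray
    depth_profile: np.ndarray

    def __len__(self) -> int:
        return len(self.sequence)


def _as_nodes(cluster_seqs) -> Dict[str, Node]:
    """Accept reads, (id, seq) pairs or a mapping; produce graph nodes."""
    nodes: Dict[str, Node] = {}

    def add(rid: str, seq: str, quals: Optional[np.ndarray]) -> None:
        if quals is None:
            quals = np.full(len(seq), 30, dtype=np.uint8)
        nodes[rid] = Node(
            id=rid, seq=seq, quals=np.asarray(quals, dtype=np.uint8),
            support=[(rid, 0, 0, len(seq))],
        )

    if isinstance(cluster_seqs, Mapping):
        for rid, val in cluster_seqs.items():
            add(rid, val, None) if isinstance(val, str) else add(rid, val[0], val[1])
        return nodes
    for item in cluster_seqs:
        if isinstance(item, SequencingRead):
            add(item.read_id, item.bases, item.quals)
        elif isinstance(item, Node):
            nodes[item.id] = item
        else:
            rid, seq = item[0], item[1]
            add(rid, seq, item[2] if len(item) > 2 else None)
    return nodes


def build_cluster_graph(cluster_seqs, params: LocalParams = LocalParams()) -> AssemblyGraph:
    """Overlap graph over the cluster sequences at local thresholds.

    Vertices are the cluster sequences (orientation-normalized); edges are
    filtered dovetail overlaps; containments are recorded on the graph and
    carry no edges.  Orientation conflicts drop the lower-scoring overlap.
    """
    nodes = _as_nodes(cluster_seqs)
    op = params.overlap_params()
    seq_map = {nid: n.seq for nid, n in nodes.items()}
    dovetails, containments = find_overlaps_detailed(seq_map, op)
    scored = list(
        filter_overlaps(
            (
                score_overlap(h, len(seq_map[h.id_a]), len(seq_map[h.id_b]), op)
                for h in dovetails
            ),
            op,
        )
    )
    containments = [
        h
        for h in containments
        if h.aln_len - h.n_match <= op.allowed_mismatches(h.aln_len)
    ]
    return build_graph(nodes, scored, containments)


def consensus(
    path_reads: Sequence[Tuple[Union[SequencingRead, Node, str], int, int]],
    super_id: str = "superread",
    min_node_identity: float = 0.9,
) -> SuperRead:
    """Quality-weighted majority consensus of reads placed on a common frame.

    ``path_reads`` holds (read, offset, orientation) triples; orientation 1
    means the reverse complement is laid out.  Ties go to the base carried
    by the highest-quality single read, then alphabetically.  A placement
    implying < ``min_node_identity`` agreement with the consensus, or a
    zero-coverage column, raises :class:`InconsistentOffsets`.
    """
    from .dna import revcomp  # local import to avoid cycle noise

    placed: List[Tuple[str, np.ndarray, int, List[Support]]] = []
    for read, offset, orient in path_reads:
        if isinstance(read, Node):
            seq, quals, support = read.seq, read.quals, read.support
        elif isinstance(read, SequencingRead):
            seq, quals = read.bases, read.quals
            support = [(read.read_id, 0, 0, len(seq))]
        else:
            seq = read
            quals = np.full(len(seq), 30, dtype=np.uint8)
            support = []
        if orient:
            seq = revcomp(seq)
            quals = quals[::-1]
            support = [
                (rid, len(seq) - (off + rlen), o ^ 1, rlen)
                for rid, off, o, rlen in support
            ]
        if offset < 0:
            raise InconsistentOffsets("negative placement offset")
        placed.append((seq, np.asarray(quals, dtype=np.uint16), offset, support))

    total = max(off + len(seq) for seq, _, off, _ in placed)
    weights = np.zeros((4, total), dtype=np.int64)
    maxq = np.zeros((4, total), dtype=np.int64)
    depth = np.zeros(total, dtype=np.int32)
    for seq, quals, off, _ in placed:
        codes = encode(seq)
        valid = codes < 4
        idx = off + np.nonzero(valid)[0]
        c = codes[valid]
        q = quals[valid]
        weights[c, idx] += q
        np.maximum.at(maxq, (c, idx), q)
        depth[off : off + len(seq)] += 1
    if (depth == 0).any():
        raise InconsistentOffsets(f"{super_id}: zero-coverage column in layout")
    combined = weights * 64 + maxq
    winner = np.argmax(combined, axis=0)
    cons_codes = winner.astype(np.uint8)
    seq_arr = CODE_BASE[cons_codes]
    cons_seq = seq_arr.tobytes().decode("ascii")

    # each constituent must agree with the consensus at its placement
    for seq, _, off, _ in placed:
        codes = encode(seq)
        valid = codes < 4
        if valid.sum() == 0:
            continue
        agree = (codes[valid] == cons_codes[off + np.nonzero(valid)[0]]).mean()
        if agree < min_node_identity:
            raise InconsistentOffsets(
                f"{super_id}: constituent agrees at {agree:.3f} < {min_node_identity}"
            )

    w_sorted = np.sort(weights, axis=0)
    qv = np.clip(w_sorted[3] - w_sorted[2], 2, 60).astype(np.uint8)
    support: List[Support] = []
    read_depth = np.zeros(total, dtype=np.int32)
    for _, _, off, sup in placed:
        for rid, roff, o, rlen in sup:
            support.append((rid, off + roff, o, rlen))
    for _, roff, _, rlen in support:
        read_depth[max(0, roff) : roff + rlen] += 1
    support.sort(key=lambda s: (s[1], s[0]))
    return SuperRead(
        id=super_id, sequence=cons_seq, support=support, quals=qv,
        depth_profile=read_depth,
    )


def _trim_tips(sr: SuperRead, min_depth: int) -> Optional[SuperRead]:
    """Trim leading/trailing consensus columns supported by < min_depth reads."""
    if min_depth <= 1:
        return sr
    idx = np.nonzero(sr.depth_profile >= min_depth)[0]
    if idx.size == 0:
        return None
    lo, hi = int(idx[0]), int(idx[-1]) + 1
    if lo == 0 and hi == len(sr.sequence):
        return sr
    sr.sequence = sr.sequence[lo:hi]
    sr.quals = sr.quals[lo:hi]
    sr.depth_profile = sr.depth_profile[lo:hi]
    # support offsets may become negative for reads hanging off the trim
    sr.support = [(rid, off - lo, o, rlen) for rid, off, o, rlen in sr.support]
    return sr


def merge_unambiguous_paths(
    g: AssemblyGraph,
    name_prefix: str = "sr",
    min_node_identity: float = 0.9,
    min_tip_depth: int = 2,
) -> Tuple[List[SuperRead], AssemblyGraph]:
    """Collapse maximal branch-free paths into consensus super-reads.

    Interior path vertices have in- and out-degree <= 1; branching vertices
    terminate paths; isolated vertices become singleton super-reads.
    Contained sequences contribute their read support to their container's
    super-read.  Returns the super-reads and a simplified graph whose
    vertices are the super-reads and whose edges are the surviving
    between-path overlaps.
    """
    chains = linear_paths(g)
    chain_of: Dict[str, int] = {}
    offsets_in_chain: Dict[str, int] = {}
    for ci, chain in enumerate(chains):
        offs = chain_offsets(g, chain)
        for nid, off in zip(chain, offs):
            chain_of[nid] = ci
            offsets_in_chain[nid] = off

    # fold contained nodes onto the chain that carries their container
    extra_support: Dict[int, List[Support]] = {}
    for inner in sorted(g.contained):
        inner_node = g.nodes[inner]
        resolved = resolve_containment(g, inner, len(inner_node.seq))
        if resolved is None:
            continue
        container, c_off, c_flip = resolved
        if container not in chain_of:
            continue
        ci = chain_of[container]
        base = offsets_in_chain[container] + c_off
        sup = inner_node.support
        if c_flip:
            L = len(inner_node.seq)
            sup = [(rid, L - (off + rlen), o ^ 1, rlen) for rid, off, o, rlen in sup]
        extra_support.setdefault(ci, []).extend(
            (rid, base + off, o, rlen) for rid, off, o, rlen in sup
        )

    superreads: List[SuperRead] = []
    rejected: List[List[str]] = []
    for ci, chain in enumerate(chains):
        sid = f"{name_prefix}{ci}"
        offs = [offsets_in_chain[nid] for nid in chain]
        try:
            sr = consensus(
                [(g.nodes[nid], off, 0) for nid, off in zip(chain, offs)],
                super_id=sid,
                min_node_identity=min_node_identity,
            )
        except InconsistentOffsets:
            rejected.append(chain)
            continue
        sr.support.extend(extra_support.get(ci, ()))
        sr.support.sort(key=lambda s: (s[1], s[0]))
        if len(chain) > 1:
            sr = _trim_tips(sr, min_tip_depth)
            if sr is None:
                rejected.append(chain)
                continue
        superreads.append(sr)
    # rejected chains fall back to their unmerged constituents
    for chain in rejected:
        for nid in chain:
            n = g.nodes[nid]
            superreads.append(
                SuperRead(
                    id=f"{name_prefix}u_{nid}",
                    sequence=n.seq,
                    support=list(n.support),
                    quals=n.quals.astype(np.uint8),
                    depth_profile=np.ones(len(n.seq), dtype=np.int32),
                )
            )

    simplified = AssemblyGraph()
    sr_by_id = {}
    for sr in superreads:
        simplified.nodes[sr.id] = Node(
            id=sr.id, seq=sr.sequence, quals=sr.quals, support=list(sr.support)
        )
        simplified.flipped[sr.id] = False
        sr_by_id[sr.id] = sr
    chain_head = {chains[ci][0]: f"{name_prefix}{ci}" for ci in range(len(chains))}
    chain_tail = {chains[ci][-1]: f"{name_prefix}{ci}" for ci in range(len(chains))}
    for u, targets in g.out_edges.items():
        for v, e in targets.items():
            su, sv = chain_tail.get(u), chain_head.get(v)
            if su is None or sv is None or su == sv:
                continue
            if su not in simplified.nodes or sv not in simplified.nodes:
                continue
            off = offsets_in_chain[u] + e.offset
            simplified.add_edge(
                GEdge(u=su, v=sv, offset=off, ovlen=e.ovlen,
                      identity=e.identity, score=e.score)
            )
    return superreads, simplified


@dataclass
class LocalAssemblyResult:
    contigs: List[SuperRead]
    unplaced: List[str] = field(default_factory=list)
    n_iterations: int = 0


def assemble_cluster(
    cluster_seqs,
    params: LocalParams = LocalParams(),
    name_prefix: str = "cluster0",
) -> LocalAssemblyResult:
    """Iterate graph building and path merging to a fixpoint; emit contigs.

    Returns contigs of length >= ``min_contig_out`` with per-contig read
    support, plus the ids of input reads that ended up in no emitted
    contig's support.
    """
    nodes = _as_nodes(cluster_seqs)
    input_ids = set(nodes)
    if len(nodes) < 3:
        return LocalAssemblyResult(contigs=[], unplaced=sorted(input_ids))
    current: List[SuperRead] = [
        SuperRead(
            id=n.id, sequence=n.seq, support=list(n.support),
            quals=n.quals, depth_profile=np.ones(len(n.seq), dtype=np.int32),
        )
        for n in nodes.values()
    ]
    it = 0
    for it in range(1, params.max_iterations + 1):
        g = build_cluster_graph(
            [Node(id=s.id, seq=s.sequence, quals=s.quals, support=s.support) for s in current],
            params,
        )
        transitive_reduce(g)
        merged, _ = merge_unambiguous_paths(
            g,
            name_prefix=f"{name_prefix}_it{it}_",
            min_node_identity=params.consensus_min_node_identity,
            min_tip_depth=params.min_tip_depth,
        )
        if len(merged) >= len(current):
            break
        current = merged
    contigs: List[SuperRead] = []
    placed: set = set()
    n_out = 0
    for sr in sorted(current, key=lambda s: (-len(s.sequence), s.id)):
        if len(sr.sequence) < params.min_contig_out:
            continue
        sr.id = f"{name_prefix}_ctg{n_out}"
        n_out += 1
        contigs.append(sr)
        placed.update(rid for rid, _, _, _ in sr.support)
    unplaced = sorted(input_ids - placed)
    if not contigs:
        logger.info("%s: no contig >= %d bp", name_prefix, params.min_contig_out)
    return LocalAssemblyResult(contigs=contigs, unplaced=unplaced, n_iterations=it)
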