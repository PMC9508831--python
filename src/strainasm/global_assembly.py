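"""Master-graph contig extension across cluster boundaries.

All cluster contigs are collected into one global overlap graph whose
edges are dovetail overlaps of length > 100 bp at identity >= 0.99.
Transitive edges are removed, branches are identified by evaluating the
reads that match the contigs around each junction, and contigs are merged
only along unique (branch-free) paths — extension stops wherever the path
is not unique, so chimera formation is avoided by construction.  The
procedure is iterated until no further merge happens; the resulting
master contigs are the pipeline's final output.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .graph import (
    AssemblyGraph,
    GEdge,
    Node,
    build_graph,
    chain_offsets,
    linear_paths,
    transitive_reduce,
)
from .io_qc import SequencingRead
from .local_assembly import SuperRead
from .overlaps import (
    OPPOSITE,
    SAME,
    OverlapParams,
    QueryIndex,
    filter_overlaps,
    find_overlaps_detailed,
    map_to_targets,
    score_overlap,
)

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class GlobalParams:
    """Master-graph thresholds.

    Edges require an overlap strictly longer than ``min_ovlen_exclusive``
    bp at identity at least ``min_identity``.  An edge is read-supported
    when at least ``min_span_reads`` reads (or read pairs) align across the
    junction; junction mapping uses ``map_min_identity``.
    """

    min_ovlen_exclusive: int = 100
    min_identity: float = 0.99
    min_span_reads: int = 3
    map_min_identity: float = 0.98
    # a contig counts as contained (redundant) only when it matches its
    # container with at most this many mismatching columns; otherwise the
    # "containment" is a near-identical sibling strain and must be kept
    max_containment_mismatch: int = 0
    junction_flank: int = 15
    insert_max: int = 2000
    max_rounds: int = 8
    transitive_tol_bp: int = 3
    transitive_tol_frac: float = 0.02

    def overlap_params(self) -> OverlapParams:
        return OverlapParams(
            min_ovlen=self.min_ovlen_exclusive + 1,
            min_identity=self.min_identity,
        )


class MasterGraph(AssemblyGraph):
    """Overlap graph over cluster contigs, with per-vertex branch flags."""

    def __init__(self) -> None:
        super().__init__()
        self.branch_flags: Dict[str, str] = {}  # vertex -> "clean" | "branched"


@dataclass(slots=True)
class MasterContig:
    id: str
    sequence: str
    source_contigs: List[Tuple[str, int, bool]]  # (contig id, offset, flipped)
    source_clusters: Set[str]

    def __len__(self) -> int:
        return len(self.sequence)


def _cluster_of(contig_id: str) -> str:
    return contig_id.split("_ctg")[0] if "_ctg" in contig_id else contig_id


def _as_contig_nodes(contigs) -> Dict[str, Node]:
    nodes: Dict[str, Node] = {}
    if isinstance(contigs, Mapping):
        items: Iterable = contigs.items()
        for cid, seq in items:
            nodes[cid] = Node(
                id=cid, seq=seq, quals=np.full(len(seq), 40, np.uint8),
                support=[(cid, 0, 0, len(seq))],
            )
        return nodes
    for c in contigs:
        if isinstance(c, SuperRead):
            nodes[c.id] = Node(
                id=c.id, seq=c.sequence, quals=np.asarray(c.quals, np.uint8),
                support=list(c.support),
            )
        elif isinstance(c, Node):
            nodes[c.id] = c
        else:
            cid, seq = c
            nodes[cid] = Node(
                id=cid, seq=seq, quals=np.full(len(seq), 40, np.uint8),
                support=[(cid, 0, 0, len(seq))],
            )
    return nodes


def build_master_graph(
    contigs, reads=None, params: GlobalParams = GlobalParams()
) -> MasterGraph:
    """Global overlap graph over cluster contigs (o > 100 bp, i >= 0.99).

    Contained contigs are recorded on the graph and set aside from path
    extension.  ``reads`` is accepted for interface symmetry; read support
    is evaluated by :func:`detect_branches`.
    """
    nodes = _as_contig_nodes(contigs)
    op = params.overlap_params()
    seq_map = {nid: n.seq for nid, n in nodes.items()}
    dovetails, containments = find_overlaps_detailed(seq_map, op)
    scored = [
        s
        for s in filter_overlaps(
            (
                score_overlap(h, len(seq_map[h.id_a]), len(seq_map[h.id_b]), op)
                for h in dovetails
            ),
            op,
        )
        if s.o > params.min_ovlen_exclusive  # ">100 bp" is strict
    ]
    containments = [
        h
        for h in containments
        if h.aln_len - h.n_match <= params.max_containment_mismatch
    ]
    g = build_graph(nodes, scored, containments)
    mg = MasterGraph()
    mg.nodes = g.nodes
    mg.out_edges = g.out_edges
    mg.in_edges = g.in_edges
    mg.flipped = g.flipped
    mg.contained = g.contained
    mg.n_conflict_dropped = g.n_conflict_dropped
    mg.branch_flags = {nid: "clean" for nid in mg.nodes}
    return mg


def _junction_windows(
    mg: MasterGraph, read_len_max: int
) -> Dict[str, Tuple[str, str]]:
    """Merged-sequence windows around each edge's junction, keyed by a
    window id; values are (u, v).  Window coordinates are arranged so the
    junction (end of u-only sequence .. start of v-only sequence) sits at
    a known position encoded in the id."""
    windows: Dict[str, Tuple[str, str]] = {}
    seqs: Dict[str, str] = {}
    for u in sorted(mg.out_edges):
        for v, e in sorted(mg.out_edges[u].items()):
            useq = mg.nodes[u].seq
            vseq = mg.nodes[v].seq
            ov = len(useq) - e.offset
            if ov <= 0 or ov > len(vseq):
                continue
            merged = useq + vseq[ov:]
            w0 = max(0, e.offset - read_len_max)
            w1 = min(len(merged), len(useq) + read_len_max)
            wid = f"J|{u}|{v}|{e.offset - w0}|{len(useq) - w0}"
            windows[wid] = (u, v)
            seqs[wid] = merged[w0:w1]
    return windows, seqs


def detect_branches(
    mg: MasterGraph,
    reads: Optional[Iterable[SequencingRead]] = None,
    params: GlobalParams = GlobalParams(),
    read_index: Optional["QueryIndex"] = None,
) -> MasterGraph:
    """Evaluate read support across each junction; prune and flag (in place).

    An out-edge (u, v) is supported when at least ``min_span_reads`` reads
    align across the u/v junction (covering u-only and v-only sequence by
    at least ``junction_flank`` bp each) or read pairs straddle it in FR
    orientation within ``insert_max``.  Unsupported edges are pruned; a
    vertex with two or more supported edges on one side is flagged
    branched.  Without read data all edges count as supported.
    """
    if reads is None:
        reads = []
    read_list = list(reads)
    if not read_list or mg.n_edges() == 0:
        for nid in mg.nodes:
            outs = len(mg.outs(nid))
            ins = len(mg.ins(nid))
            mg.branch_flags[nid] = "branched" if (outs >= 2 or ins >= 2) else "clean"
        return mg

    read_seqs = {r.read_id: r.bases for r in read_list}
    if read_index is None:
        read_index = QueryIndex(read_seqs)
    mate_of = {r.read_id: r.mate_id for r in read_list}
    max_rl = max(len(r) for r in read_list)
    flank = params.junction_flank
    eps = 1e-9

    support: Dict[Tuple[str, str], int] = {}

    # single reads crossing the junction inside a merged window.  A read
    # only counts for an edge when it matches that junction strictly better
    # than every sibling junction (same u or same v): reads from identical
    # inter-strain regions are ambiguous and must not validate either path.
    windows, wseqs = _junction_windows(mg, max_rl)
    if wseqs:
        crossing: Dict[str, List[Tuple[Tuple[str, str], float]]] = {}
        for m in map_to_targets(
            read_index, wseqs, min_identity=params.map_min_identity
        ):
            _, u, v, jstart_s, jend_s = m.target_id.split("|")
            jstart, jend = int(jstart_s), int(jend_s)
            if m.t_start <= jstart - flank and m.t_end >= jend + flank:
                crossing.setdefault(m.query_id, []).append(((u, v), m.identity))
        for rid, hits in crossing.items():
            for (u, v), ident in hits:
                discriminating = all(
                    ident > o_ident + eps
                    for (ou, ov), o_ident in hits
                    if (ou, ov) != (u, v) and (ou == u or ov == v)
                )
                if discriminating:
                    support[(u, v)] = support.get((u, v), 0) + 1

    # read pairs straddling the junction, with the same discrimination
    # requirement: the v-side mate must fit v strictly better than any other
    # out-neighbor of u, and the u-side mate must fit u strictly better than
    # any other in-neighbor of v.
    contig_seqs = {nid: n.seq for nid, n in mg.nodes.items() if nid not in mg.contained}
    by_query: Dict[str, List] = {}
    by_target: Dict[str, List] = {}
    for m in map_to_targets(read_index, contig_seqs, min_identity=params.map_min_identity):
        by_query.setdefault(m.query_id, []).append(m)
        by_target.setdefault(m.target_id, []).append(m)

    def _best_on(rid: str, target: str) -> float:
        best = -1.0
        for m in by_query.get(rid, ()):
            if m.target_id == target and m.identity > best:
                best = m.identity
        return best

    for u in sorted(mg.out_edges):
        ulen = len(mg.nodes[u].seq)
        out_sibs = sorted(mg.out_edges[u])
        for v, e in sorted(mg.out_edges[u].items()):
            in_sibs = sorted(mg.in_edges.get(v, {}))
            n_pairs = 0
            for m1 in by_target.get(u, ()):
                # only forward-mapped reads near u's 3' end can straddle
                if m1.strand != SAME or m1.t_start < ulen - params.insert_max:
                    continue
                mid = mate_of.get(m1.query_id)
                if mid is None:
                    continue
                for m2 in by_query.get(mid, ()):
                    if m2.target_id != v or m2.strand != OPPOSITE:
                        continue
                    frag_start = m1.t_start
                    frag_end = e.offset + m2.t_end
                    if not (
                        frag_start < ulen - flank
                        and frag_end > ulen + flank
                        and 0 < frag_end - frag_start <= params.insert_max
                    ):
                        continue
                    if any(
                        _best_on(mid, v2) >= m2.identity - eps
                        for v2 in out_sibs
                        if v2 != v
                    ):
                        continue
                    if any(
                        _best_on(m1.query_id, u2) >= m1.identity - eps
                        for u2 in in_sibs
                        if u2 != u
                    ):
                        continue
                    n_pairs += 1
                    break
            if n_pairs:
                support[(u, v)] = support.get((u, v), 0) + n_pairs

    for u in sorted(mg.out_edges):
        for v in sorted(mg.out_edges[u]):
            if support.get((u, v), 0) < params.min_span_reads:
                mg.remove_edge(u, v)
    for nid in mg.nodes:
        mg.branch_flags[nid] = (
            "branched" if (len(mg.outs(nid)) >= 2 or len(mg.ins(nid)) >= 2) else "clean"
        )
    return mg


def _mean_depth(node: Node, start: int, end: int) -> float:
    depth = 0
    for _, off, _, rlen in node.support:
        lo, hi = max(start, off), min(end, off + rlen)
        if hi > lo:
            depth += hi - lo
    return depth / max(1, end - start)


def extend_unique_paths(mg: MasterGraph) -> Tuple[List[SuperRead], List[MasterContig]]:
    """Merge contigs along maximal branch-free paths of clean vertices.

    Within each overlap the bases of the deeper-supported contig are kept.
    Extension never crosses a branched vertex; contained contigs do not
    take part.  Returns the merged sequences (as :class:`SuperRead`, for
    further rounds) and their :class:`MasterContig` layout records.
    """
    # sever paths at branched vertices so chains never cross them
    g = AssemblyGraph()
    g.nodes = mg.nodes
    g.flipped = mg.flipped
    g.contained = mg.contained
    for u, targets in mg.out_edges.items():
        if mg.branch_flags.get(u) == "branched":
            continue
        for v, e in targets.items():
            if mg.branch_flags.get(v) == "branched":
                continue
            g.add_edge(e)

    chains = linear_paths(g)
    merged: List[SuperRead] = []
    records: List[MasterContig] = []
    for ci, chain in enumerate(chains):
        offs = chain_offsets(g, chain)
        pieces: List[str] = []
        support = []
        cursor = 0
        for idx, nid in enumerate(chain):
            node = g.nodes[nid]
            off = offs[idx]
            if idx == 0:
                pieces.append(node.seq)
                cursor = len(node.seq)
            else:
                ov = cursor - off
                if ov < 0:  # layout gap; should not happen for dovetails
                    raise ValueError(f"negative overlap in chain at {nid}")
                prev = g.nodes[chain[idx - 1]]
                prev_depth = _mean_depth(prev, len(prev.seq) - ov, len(prev.seq))
                cur_depth = _mean_depth(node, 0, ov)
                if cur_depth > prev_depth:
                    # prefer the deeper contig's bases inside the overlap
                    pieces = [_concat(pieces)[:off]]
                    pieces.append(node.seq)
                else:
                    pieces.append(node.seq[ov:])
                cursor = off + len(node.seq)
            support.extend(
                (rid, off + roff, o, rlen) for rid, roff, o, rlen in node.support
            )
        seq = _concat(pieces)
        support.sort(key=lambda s: (s[1], s[0]))
        sid = f"m{ci}"
        merged.append(
            SuperRead(
                id=sid, sequence=seq, support=support,
                quals=np.full(len(seq), 40, np.uint8),
                depth_profile=np.zeros(len(seq), np.int32),
            )
        )
        records.append(
            MasterContig(
                id=sid,
                sequence=seq,
                source_contigs=[
                    (nid, offs[i], bool(g.flipped.get(nid, False)))
                    for i, nid in enumerate(chain)
                ],
                source_clusters={_cluster_of(nid) for nid in chain},
            )
        )
    return merged, records


def _concat(pieces: List[str]) -> str:
    return pieces[0] if len(pieces) == 1 else "".join(pieces)


@dataclass
class GlobalAssemblyResult:
    master_contigs: List[MasterContig]
    n_rounds: int = 0
    n_contained_dropped: int = 0


def global_assemble(
    contigs,
    reads: Optional[Iterable[SequencingRead]] = None,
    params: GlobalParams = GlobalParams(),
) -> GlobalAssemblyResult:
    """Iterate build -> reduce -> branch detection -> unique-path extension.

    The loop stops when a pass makes no merge (or after ``max_rounds``).
    Every input cluster contig is accounted for: merged into a master
    contig, contained in one, or emitted as-is.
    """
    read_list = list(reads) if reads is not None else None
    read_index = (
        QueryIndex({r.read_id: r.bases for r in read_list}) if read_list else None
    )
    current = _as_contig_nodes(contigs)
    provenance: Dict[str, List[Tuple[str, int, bool]]] = {
        cid: [(cid, 0, False)] for cid in current
    }
    n_contained = 0
    rounds = 0
    for rounds in range(1, params.max_rounds + 1):
        if len(current) < 2:
            break
        mg = build_master_graph(list(current.values()), read_list, params)
        transitive_reduce(mg, params.transitive_tol_bp, params.transitive_tol_frac)
        detect_branches(mg, read_list, params, read_index=read_index)
        n_edges = mg.n_edges()
        merged, records = extend_unique_paths(mg)
        n_contained += len(mg.contained)
        made_progress = any(len(r.source_contigs) > 1 for r in records) or bool(
            mg.contained
        )
        new_provenance: Dict[str, List[Tuple[str, int, bool]]] = {}
        new_current: Dict[str, Node] = {}
        for sr, rec in zip(merged, records):
            nid = f"r{rounds}_{sr.id}"
            sr.id = nid
            sources: List[Tuple[str, int, bool]] = []
            for src, off, flip in rec.source_contigs:
                for orig, o_off, o_flip in provenance.get(src, [(src, 0, False)]):
                    sources.append((orig, off + o_off, flip ^ o_flip))
            new_provenance[nid] = sources
            new_current[nid] = Node(
                id=nid, seq=sr.sequence,
                quals=np.full(len(sr.sequence), 40, np.uint8),
                support=list(sr.support),
            )
        current = new_current
        provenance = new_provenance
        if not made_progress:
            break

    ordered = sorted(current.values(), key=lambda n: (-len(n.seq), n.id))
    out: List[MasterContig] = []
    for i, node in enumerate(ordered):
        sources = provenance.get(node.id, [(node.id, 0, False)])
        out.append(
            MasterContig(
                id=f"master_ctg{i}",
                sequence=node.seq,
                source_contigs=sorted(sources, key=lambda s: (s[1], s[0])),
                source_clusters={_cluster_of(s[0]) for s in sources},
            )
        )
    return GlobalAssemblyResult(
        master_contigs=out, n_rounds=rounds, n_contained_dropped=n_contained
    )


def write_assembly(
    master_contigs: Sequence[MasterContig], fasta_path: str | Path
) -> Path:
    """Write the final FASTA plus a provenance/report TSV alongside it."""
    fasta_path = Path(fasta_path)
    with open(fasta_path, "w") as out:
        for mc in master_contigs:
            out.write(
                f">{mc.id} length={len(mc.sequence)} "
                f"clusters={len(mc.source_clusters)}\n"
            )
            for i in range(0, len(mc.sequence), 80):
                out.write(mc.sequence[i : i + 80] + "\n")
    report = fasta_path.with_suffix(".report.tsv")
    with open(report, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["contig", "length", "n_sources", "sources"])
        for mc in master_contigs:
            w.writerow(
                [
                    mc.id,
                    len(mc.sequence),
                    len(mc.source_contigs),
                    ";".join(f"{s[0]}@{s[1]}{'-' if s[2] else '+'}" for s in mc.source_contigs),
                ]
            )
    return report
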