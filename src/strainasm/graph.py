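"""Oriented overlap-graph machinery shared by the local and global stages.

Sequences enter as unoriented strings with pairwise dovetail overlaps on
either strand.  Per connected component a consistent orientation is chosen
(union-find with parity, processing overlaps best-first; an overlap whose
orientation constraint conflicts with already-accepted ones is dropped).
After normalization every edge points from the sequence whose suffix is
consumed to the sequence whose prefix it matches, labelled with the layout
offset.  On this digraph the module provides transitive-edge removal with
a positional tolerance, containment folding, and maximal branch-free path
extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .dna import revcomp
from .overlaps import OPPOSITE, SAME, OverlapHit, ScoredOverlap

logger = logging.getLogger(__name__)

# (read_id, offset, orient, length): placement of a supporting read on the
# forward orientation of a node; orient 1 means the read's reverse
# complement is the one laid out.
Support = Tuple[str, int, int, int]


@dataclass(slots=True)
class Node:
    id: str
    seq: str
    quals: np.ndarray
    support: List[Support]

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(slots=True)
class GEdge:
    u: str
    v: str
    offset: int  # start of v relative to start of u in the layout (> 0)
    ovlen: int
    identity: float
    score: float


@dataclass
class AssemblyGraph:
    nodes: Dict[str, Node] = field(default_factory=dict)
    out_edges: Dict[str, Dict[str, GEdge]] = field(default_factory=dict)
    in_edges: Dict[str, Dict[str, GEdge]] = field(default_factory=dict)
    flipped: Dict[str, bool] = field(default_factory=dict)
    # inner id -> (container id, offset on container forward, relative flip)
    contained: Dict[str, Tuple[str, int, bool]] = field(default_factory=dict)
    n_conflict_dropped: int = 0

    def add_edge(self, e: GEdge) -> None:
        prev = self.out_edges.setdefault(e.u, {}).get(e.v)
        if prev is None or e.score > prev.score:
            self.out_edges[e.u][e.v] = e
            self.in_edges.setdefault(e.v, {})[e.u] = e

    def remove_edge(self, u: str, v: str) -> None:
        self.out_edges.get(u, {}).pop(v, None)
        self.in_edges.get(v, {}).pop(u, None)

    def outs(self, u: str) -> Dict[str, GEdge]:
        return self.out_edges.get(u, {})

    def ins(self, v: str) -> Dict[str, GEdge]:
        return self.in_edges.get(v, {})

    def n_edges(self) -> int:
        return sum(len(d) for d in self.out_edges.values())


class _ParityDSU:
    """Union-find tracking relative orientation (parity) to the root."""

    def __init__(self) -> None:
        self.parent: Dict[str, str] = {}
        self.parity: Dict[str, int] = {}

    def add(self, x: str) -> None:
        if x not in self.parent:
            self.parent[x] = x
            self.parity[x] = 0

    def find(self, x: str) -> Tuple[str, int]:
        self.add(x)
        path = []
        root, par = x, 0
        while self.parent[root] != root:
            path.append(root)
            par ^= self.parity[root]
            root = self.parent[root]
        # compress
        p = par
        for node in path:
            old = self.parity[node]
            self.parent[node] = root
            self.parity[node], p = p, p ^ old
        return root, par

    def union(self, a: str, b: str, rel: int) -> bool:
        """Constrain orient(a) xor orient(b) == rel; False on conflict."""
        ra, pa = self.find(a)
        rb, pb = self.find(b)
        if ra == rb:
            return (pa ^ pb) == rel
        self.parent[rb] = ra
        self.parity[rb] = pa ^ pb ^ rel
        return True


def _flip_interval(start: int, end: int, length: int) -> Tuple[int, int]:
    return length - end, length - start


def orient_components(
    node_ids: Iterable[str], scored: Sequence[ScoredOverlap]
) -> Tuple[Dict[str, bool], int, set]:
    """Choose a per-node orientation consistent with as many overlaps as
    possible, best-first; returns (flip map, n dropped, dropped pair set)."""
    dsu = _ParityDSU()
    for nid in node_ids:
        dsu.add(nid)
    dropped: set = set()
    n_dropped = 0
    order = sorted(
        scored, key=lambda s: (-s.D, -s.i, -s.o, s.hit.id_a, s.hit.id_b)
    )
    for s in order:
        rel = 0 if s.hit.strand == SAME else 1
        if not dsu.union(s.hit.id_a, s.hit.id_b, rel):
            dropped.add((s.hit.id_a, s.hit.id_b))
            n_dropped += 1
    flip = {nid: bool(dsu.find(nid)[1]) for nid in dsu.parent}
    return flip, n_dropped, dropped


def build_graph(
    nodes: Dict[str, Node],
    dovetails: Sequence[ScoredOverlap],
    containments: Sequence[OverlapHit] = (),
) -> AssemblyGraph:
    """Assemble the normalized layout digraph from scored dovetail overlaps.

    Orientation conflicts drop the lower-scoring overlap.  Containment hits
    are recorded (inner -> container placement) and the inner nodes carry
    no edges of their own.
    """
    flip, n_dropped, dropped_pairs = orient_components(nodes.keys(), dovetails)
    g = AssemblyGraph(n_conflict_dropped=n_dropped)

    # normalize node sequences once
    for nid in sorted(nodes):
        node = nodes[nid]
        if flip.get(nid, False):
            node = Node(
                id=nid,
                seq=revcomp(node.seq),
                quals=node.quals[::-1].copy(),
                support=[
                    (rid, len(node.seq) - (off + rlen), orient ^ 1, rlen)
                    for rid, off, orient, rlen in node.support
                ],
            )
        g.nodes[nid] = node
        g.flipped[nid] = flip.get(nid, False)

    contained_ids: set = set()
    for h in containments:
        kind = h.kind()
        if kind == "contains_b":
            inner, container = h.id_b, h.id_a
            c_start, c_end = h.a_start, h.a_end
            c_len, i_len = h.len_a, h.len_b
        elif kind == "contained_in_b":
            inner, container = h.id_a, h.id_b
            c_start, c_end = h.b_start, h.b_end
            c_len, i_len = h.len_b, h.len_a
        else:
            continue
        if inner in contained_ids or container in contained_ids:
            continue  # avoid chains/cycles of containment in one round
        rel_flip = (h.strand == OPPOSITE) ^ flip.get(inner, False) ^ flip.get(container, False)
        if flip.get(container, False):
            c_start, c_end = _flip_interval(c_start, c_end, c_len)
        g.contained[inner] = (container, c_start, bool(rel_flip))
        contained_ids.add(inner)

    for s in dovetails:
        h = s.hit
        if (h.id_a, h.id_b) in dropped_pairs:
            continue
        if h.id_a in contained_ids or h.id_b in contained_ids:
            continue
        fa, fb = flip.get(h.id_a, False), flip.get(h.id_b, False)
        a0, a1 = (h.a_start, h.a_end) if not fa else _flip_interval(h.a_start, h.a_end, h.len_a)
        b0, b1 = (h.b_start, h.b_end) if not fb else _flip_interval(h.b_start, h.b_end, h.len_b)
        diag = a0 - b0
        if diag > 0:
            u, v, offset = h.id_a, h.id_b, diag
        elif diag < 0:
            u, v, offset = h.id_b, h.id_a, -diag
        else:
            # identical layout start: effectively a containment/duplicate
            inner, container = (
                (h.id_a, h.id_b) if h.len_a <= h.len_b else (h.id_b, h.id_a)
            )
            if inner not in contained_ids and container not in contained_ids:
                g.contained[inner] = (container, 0, False)
                contained_ids.add(inner)
            continue
        g.add_edge(
            GEdge(u=u, v=v, offset=offset, ovlen=s.o, identity=s.i, score=s.D)
        )

    # containment-involved nodes must not keep edges
    for nid in contained_ids:
        for v in list(g.outs(nid)):
            g.remove_edge(nid, v)
        for u in list(g.ins(nid)):
            g.remove_edge(u, nid)
    return g


def transitive_reduce(
    g: AssemblyGraph, tol_bp: int = 3, tol_frac: float = 0.02
) -> AssemblyGraph:
    """Remove edges implied by a consistent two-step path (in place).

    An edge u->w is transitive when some v with edges u->v and v->w exists
    whose implied layout position of w agrees with the direct edge within
    ``tol_bp + tol_frac * offset`` base pairs.
    """
    for u in sorted(g.nodes):
        outs = g.outs(u)
        if len(outs) < 2:
            continue
        by_offset = sorted(outs.values(), key=lambda e: (e.offset, e.v))
        doomed: List[str] = []
        for i, ew in enumerate(by_offset):
            tol = tol_bp + tol_frac * ew.offset
            for ev in by_offset[:i]:
                if ev.v == ew.v:
                    continue
                mid = g.outs(ev.v).get(ew.v)
                if mid is None:
                    continue
                if abs(ev.offset + mid.offset - ew.offset) <= tol:
                    doomed.append(ew.v)
                    break
        for w in doomed:
            g.remove_edge(u, w)
    return g


def linear_paths(g: AssemblyGraph) -> List[List[str]]:
    """Maximal branch-free chains covering every (non-contained) vertex once.

    Interior chain vertices have in-degree 1 and out-degree 1; walking stops
    at any branch.  Pure cycles are broken at their lexicographically
    smallest vertex.  Isolated/branching vertices yield singleton chains.
    """
    visited: set = set()
    chains: List[List[str]] = []
    active = [nid for nid in sorted(g.nodes) if nid not in g.contained]

    def is_chain_start(nid: str) -> bool:
        ins = g.ins(nid)
        if len(ins) != 1:
            return True
        (pred,) = ins
        return len(g.outs(pred)) != 1

    for nid in active:
        if nid in visited or not is_chain_start(nid):
            continue
        chain = [nid]
        visited.add(nid)
        cur = nid
        while True:
            outs = g.outs(cur)
            if len(outs) != 1:
                break
            (nxt,) = outs
            if nxt in visited or len(g.ins(nxt)) != 1:
                break
            chain.append(nxt)
            visited.add(nxt)
            cur = nxt
        chains.append(chain)
    # anything left is inside a cycle
    for nid in active:
        if nid in visited:
            continue
        chain = [nid]
        visited.add(nid)
        cur = nid
        while True:
            outs = g.outs(cur)
            if len(outs) != 1:
                break
            (nxt,) = outs
            if nxt in visited:
                break
            chain.append(nxt)
            visited.add(nxt)
            cur = nxt
        logger.debug("cycle broken at %s (chain of %d)", nid, len(chain))
        chains.append(chain)
    return chains


def chain_offsets(g: AssemblyGraph, chain: Sequence[str]) -> List[int]:
    """Cumulative layout offsets of the chain's nodes (first node at 0)."""
    offsets = [0]
    for u, v in zip(chain, chain[1:]):
        offsets.append(offsets[-1] + g.outs(u)[v].offset)
    return offsets


def resolve_containment(
    g: AssemblyGraph, inner: str, inner_len: int
) -> Optional[Tuple[str, int, bool]]:
    """Follow containment links up to a node that still carries edges.

    Returns the (container id, offset, flip) placement of the original
    ``inner`` sequence on that container's forward orientation, or ``None``
    on a containment cycle.
    """
    seen = set()
    nid, off, fl = inner, 0, False
    while nid in g.contained:
        if nid in seen:
            return None
        seen.add(nid)
        container, c_off, c_flip = g.contained[nid]
        nid_len = len(g.nodes[nid].seq)
        if c_flip:
            off = c_off + (nid_len - (off + inner_len))
            fl = not fl
        else:
            off = c_off + off
        nid = container
    return nid, off, fl
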