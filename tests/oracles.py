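"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's seeding/graph machinery: overlaps
are found by scanning every offset of every pair, connected components by
transitive closure, and transitive reduction by checking all vertex
triples.
"""

from __future__ import annotations

from typing import Dict, List, Set, Tuple

from strainasm.dna import revcomp


def brute_force_dovetails(
    seqs: Dict[str, str], min_ovlen: int, min_identity: float
) -> Set[Tuple[str, str]]:
    """All unordered pairs with an exact-offset suffix-prefix overlap
    passing the thresholds, on either strand (substitution-only model)."""
    found: Set[Tuple[str, str]] = set()
    ids = sorted(seqs)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            sa = seqs[a]
            for sb in (seqs[b], revcomp(seqs[b])):
                la, lb = len(sa), len(sb)
                for diag in range(-(lb - 1), la):
                    a0, b0 = max(0, diag), max(0, -diag)
                    span = min(la - a0, lb - b0)
                    if span < min_ovlen:
                        continue
                    matches = sum(
                        1
                        for x, y in zip(sa[a0 : a0 + span], sb[b0 : b0 + span])
                        if x == y
                    )
                    ident = matches / span
                    if ident < min_identity:
                        continue
                    # dovetail: reaches an end of each sequence
                    a_l, a_r = a0 == 0, a0 + span == la
                    b_l, b_r = b0 == 0, b0 + span == lb
                    if (b_l and b_r) or (a_l and a_r):
                        continue  # containment
                    if (a_r and b_l) or (a_l and b_r):
                        found.add((a, b))
    return found


def connected_components(
    n_ids: List[str], edges: List[Tuple[str, str]]
) -> List[Set[str]]:
    """Components by repeated transitive closure (no union-find)."""
    comp: Dict[str, Set[str]] = {x: {x} for x in n_ids}
    for a, b in edges:
        if comp[a] is comp[b]:
            continue
        merged = comp[a] | comp[b]
        for x in merged:
            comp[x] = merged
    seen: List[Set[str]] = []
    for s in comp.values():
        if s not in seen:
            seen.append(s)
    return seen


def brute_force_transitive_edges(
    edges: Dict[Tuple[str, str], int], tol_bp: int = 3, tol_frac: float = 0.02
) -> Set[Tuple[str, str]]:
    """Edges (u, w) implied by a consistent pair u->v->w, checked over all
    triples (O(V * E^2))."""
    doomed: Set[Tuple[str, str]] = set()
    for (u, w), off_uw in edges.items():
        tol = tol_bp + tol_frac * off_uw
        for (u2, v), off_uv in edges.items():
            if u2 != u or v == w:
                continue
            off_vw = edges.get((v, w))
            if off_vw is None:
                continue
            if abs(off_uv + off_vw - off_uw) <= tol:
                doomed.add((u, w))
                break
    return doomed


def n50_brute(lengths: List[int]) -> int:
    """Largest L whose >=L contigs hold at least half the total (by
    direct enumeration over all candidate L)."""
    total = sum(lengths)
    if total == 0:
        return 0
    best = 0
    for L in sorted(set(lengths)):
        if sum(x for x in lengths if x >= L) * 2 >= total:
            best = L
    return best
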