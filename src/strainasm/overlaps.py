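"""All-vs-all suffix-prefix (dovetail) overlap detection and scoring.

Candidate pairs come from shared minimizers (:mod:`strainasm._minimizer`);
each candidate's dominant seed diagonal defines the implied overlap
segments, which are verified end-to-end with edlib.  A verified overlap is
scored as

    D = w_i * i + w_l * o / ((r1 + r2) / 2)

where ``i`` is the alignment identity (matches / alignment columns), ``o``
the overlap length, and ``r1``, ``r2`` the two sequence lengths.  With the
default weights (0.9 / 0.1) this balances overlap quality against overlap
length; D lies in [0, 1].  Overlaps shorter than ``min_ovlen`` or below
``min_identity`` are discarded by :func:`filter_overlaps`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Tuple

import edlib
import numpy as np

from ._minimizer import candidate_pairs, compute_minimizers
from .dna import revcomp

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

SAME = "same"
OPPOSITE = "opposite"


@dataclass(slots=True)
class OverlapParams:
    """Tuning knobs for overlap detection, scoring and filtering.

    min_ovlen / min_identity: overlaps of length < 30 bp or identity < 0.9
    are neglected (boundary values pass).  w_identity + w_length must sum
    to 1.  overhang_tol is the number of unaligned terminal bases tolerated
    when classifying a hit as dovetail; seed_k / window are the minimizer
    settings used for candidate detection.
    """

    min_ovlen: int = 30
    min_identity: float = 0.9
    w_identity: float = 0.9
    w_length: float = 0.1
    overhang_tol: int = 5
    seed_k: int = 15
    window: int = 5
    max_seed_occ: int = 120
    with_cigar: bool = False
    # optional fractional overlap floor: an overlap must additionally reach
    # min_ovlen_frac * min(len_a, len_b, frac_len_cap).  Short-read layout
    # graphs use this to reject micro-overlaps that are trivially shared
    # between near-identical strains; 0 disables it.
    min_ovlen_frac: float = 0.0
    frac_len_cap: int = 300
    # optional absolute cap on mismatching/indel columns per overlap;
    # None leaves the identity fraction as the only criterion.  With
    # error-corrected sequences a cap of 0 separates strains: a surviving
    # mismatch is more likely a linked variant than a sequencing error.
    max_mismatch: Optional[int] = None

    def effective_min_ovlen(self, len_a: int, len_b: int) -> int:
        frac = int(
            np.ceil(self.min_ovlen_frac * min(len_a, len_b, self.frac_len_cap))
        )
        return max(self.min_ovlen, frac)

    def allowed_mismatches(self, span: int) -> int:
        budget = int(span * (1.0 - self.min_identity))
        if self.max_mismatch is not None:
            budget = min(budget, self.max_mismatch)
        return budget

    def __post_init__(self) -> None:
        if abs(self.w_identity + self.w_length - 1.0) > 1e-9:
            raise ValueError("w_identity + w_length must equal 1")
        if self.min_ovlen < 1:
            raise ValueError("min_ovlen must be >= 1")
        if not 0.0 <= self.min_identity <= 1.0:
            raise ValueError("min_identity must lie in [0, 1]")


@dataclass(slots=True)
class OverlapHit:
    """One pairwise overlap; coordinates are 0-based half-open on the
    forward orientation of each sequence.

    For ``strand == "opposite"`` the CIGAR (when present) describes the
    alignment of A against the reverse complement of B.
    """

    id_a: str
    id_b: str
    strand: str  # "same" | "opposite"
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    n_match: int
    aln_len: int
    len_a: int
    len_b: int
    cigar: Optional[str] = None

    @property
    def identity(self) -> float:
        return self.n_match / self.aln_len

    def kind(self, overhang_tol: int = 5) -> str:
        """Classify the hit: 'dovetail', 'contains_b', 'contained_in_b'
        or 'internal', within ``overhang_tol`` bp of the sequence ends."""
        a_left = self.a_start <= overhang_tol
        a_right = self.a_end >= self.len_a - overhang_tol
        b_left = self.b_start <= overhang_tol
        b_right = self.b_end >= self.len_b - overhang_tol
        if b_left and b_right:
            return "contains_b"
        if a_left and a_right:
            return "contained_in_b"
        if (a_right and (b_left if self.strand == SAME else b_right)) or (
            a_left and (b_right if self.strand == SAME else b_left)
        ):
            return "dovetail"
        return "internal"


@dataclass(slots=True)
class ScoredOverlap:
    """An :class:`OverlapHit` together with the Eq.-(1)-style score."""

    hit: OverlapHit
    i: float
    o: int
    r1: int
    r2: int
    D: float

    @property
    def id_a(self) -> str:
        return self.hit.id_a

    @property
    def id_b(self) -> str:
        return self.hit.id_b


def parse_cigar(cigar: str) -> Tuple[int, int, int, int, int]:
    """Return (matches, mismatches, ins, dels, columns) for an extended CIGAR."""
    n_eq = n_x = n_i = n_d = 0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        if op == "=":
            n_eq += n
        elif op == "X":
            n_x += n
        elif op == "I":
            n_i += n
        elif op == "D":
            n_d += n
        else:  # plain M: cannot distinguish; counted as matches
            n_eq += n
    return n_eq, n_x, n_i, n_d, n_eq + n_x + n_i + n_d


def score_overlap(
    hit: OverlapHit, len_a: int, len_b: int, params: OverlapParams = OverlapParams()
) -> ScoredOverlap:
    """Score a hit: i = matches / alignment columns, o = longer overlap span."""
    if hit.aln_len == 0:
        raise ValueError(f"zero-length alignment for pair ({hit.id_a}, {hit.id_b})")
    if len_a <= 0 or len_b <= 0:
        raise ValueError("sequence lengths must be positive")
    i = hit.n_match / hit.aln_len
    o = max(hit.a_end - hit.a_start, hit.b_end - hit.b_start)
    d = params.w_identity * i + params.w_length * o / ((len_a + len_b) / 2.0)
    return ScoredOverlap(hit=hit, i=i, o=o, r1=len_a, r2=len_b, D=d)


def filter_overlaps(
    scored: Iterable[ScoredOverlap], params: OverlapParams = OverlapParams()
) -> Iterator[ScoredOverlap]:
    """Keep overlaps with o >= min_ovlen and i >= min_identity (inclusive).

    When ``min_ovlen_frac`` is set, the per-pair effective minimum overlap
    (see :meth:`OverlapParams.effective_min_ovlen`) applies instead.
    """
    for s in scored:
        if s.o < params.effective_min_ovlen(s.r1, s.r2) or s.i < params.min_identity:
            continue
        if (
            params.max_mismatch is not None
            and s.hit.aln_len - s.hit.n_match > params.max_mismatch
        ):
            continue
        yield s


def _as_items(seqs) -> list[Tuple[str, str]]:
    if isinstance(seqs, Mapping):
        items = list(seqs.items())
    else:
        items = list(seqs)
    items.sort(key=lambda kv: kv[0])  # canonical: lexicographically smaller id first
    ids = [k for k, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError("sequence ids must be unique")
    return items


def _verify_candidates(
    items: Sequence[Tuple[str, str]],
    rows: np.ndarray,
    params: OverlapParams,
) -> list[OverlapHit]:
    ids = [k for k, _ in items]
    seqs = [s for _, s in items]
    lens = [len(s) for s in seqs]
    rc_cache: dict[int, str] = {}
    tol = params.overhang_tol
    want_cigar = params.with_cigar
    task = "path" if want_cigar else "distance"
    best: dict[Tuple[int, int], OverlapHit] = {}

    a_col = rows[:, 0].tolist()
    b_col = rows[:, 1].tolist()
    st_col = rows[:, 2].tolist()
    dg_col = rows[:, 3].tolist()
    for a, b, st, diag in zip(a_col, b_col, st_col, dg_col):
        la, lb = lens[a], lens[b]
        a0 = diag if diag > 0 else 0
        b0 = -diag if diag < 0 else 0
        span = min(la - a0, lb - b0)
        if span < params.effective_min_ovlen(la, lb) - tol or span <= 0:
            continue
        if st == 0:
            sb_full = seqs[b]
        else:
            sb_full = rc_cache.get(b)
            if sb_full is None:
                sb_full = rc_cache[b] = revcomp(seqs[b])
        sa = seqs[a][a0 : a0 + span]
        sb = sb_full[b0 : b0 + span]
        max_ed = params.allowed_mismatches(span) + tol
        res = edlib.align(sa, sb, mode="NW", task=task, k=max_ed)
        ed = res["editDistance"]
        if ed < 0:
            continue
        if want_cigar:
            n_eq, n_x, n_i, n_d, cols = parse_cigar(res["cigar"])
            cigar = res["cigar"]
        else:
            n_eq, cols, cigar = span - ed, span, None
        if cols == 0 or n_eq / cols < params.min_identity - 0.05:
            # clearly sub-threshold; exact boundary semantics are applied
            # later by filter_overlaps
            continue
        a_start, a_end = a0, a0 + span
        if st == 0:
            b_start, b_end = b0, b0 + span
        else:
            b_start, b_end = lb - (b0 + span), lb - b0
        hit = OverlapHit(
            id_a=ids[a],
            id_b=ids[b],
            strand=SAME if st == 0 else OPPOSITE,
            a_start=a_start,
            a_end=a_end,
            b_start=b_start,
            b_end=b_end,
            n_match=n_eq,
            aln_len=cols,
            len_a=la,
            len_b=lb,
            cigar=cigar,
        )
        if hit.kind(tol) == "internal":
            continue
        prev = best.get((a, b))
        if prev is None or (hit.n_match, -hit.aln_len) > (prev.n_match, -prev.aln_len):
            best[(a, b)] = hit
    hits = list(best.values())
    hits.sort(key=lambda h: (h.id_a, h.id_b, h.a_start))
    return hits


def find_overlaps_detailed(
    seqs, params: OverlapParams = OverlapParams()
) -> Tuple[list[OverlapHit], list[OverlapHit]]:
    """All-vs-all overlaps, split into (dovetails, containments).

    Self-hits and duplicate (a, b)/(b, a) pairs are suppressed; per pair the
    best-supported relative orientation wins.  Hits below ``min_ovlen`` or
    clearly below ``min_identity`` are dropped here; the exact boundary
    semantics live in :func:`filter_overlaps`.
    """
    items = _as_items(seqs)
    if len(items) < 2:
        return [], []
    mz = compute_minimizers([s for _, s in items], k=params.seed_k, w=params.window)
    lens = np.array([len(s) for _, s in items], dtype=np.int64)
    rows = candidate_pairs(mz, lens, max_occ=params.max_seed_occ)
    hits = _verify_candidates(items, rows, params)
    dovetails = [h for h in hits if h.kind(params.overhang_tol) == "dovetail"]
    containments = [h for h in hits if h.kind(params.overhang_tol) in ("contains_b", "contained_in_b")]
    return dovetails, containments


def find_overlaps(seqs, params: OverlapParams = OverlapParams()) -> list[OverlapHit]:
    """All-vs-all dovetail overlaps among ``seqs`` (mapping id -> sequence).

    Deterministic output: hits sorted by (id_a, id_b, a_start), with
    ``id_a < id_b`` lexicographically.
    """
    return find_overlaps_detailed(seqs, params)[0]


def score_and_filter(
    seqs_by_id: Mapping[str, str],
    hits: Iterable[OverlapHit],
    params: OverlapParams = OverlapParams(),
) -> list[ScoredOverlap]:
    """Convenience: score hits against their sequence lengths and filter."""
    scored = (
        score_overlap(h, len(seqs_by_id[h.id_a]), len(seqs_by_id[h.id_b]), params)
        for h in hits
    )
    return list(filter_overlaps(scored, params))


@dataclass(slots=True)
class ReadMapping:
    """Placement of a query fully inside a target sequence."""

    query_id: str
    target_id: str
    strand: str  # orientation of the query relative to the target
    t_start: int
    t_end: int
    identity: float


class QueryIndex:
    """Precomputed minimizer table for a fixed query collection.

    Building the table once and reusing it across several
    :func:`map_to_targets` calls avoids rescanning a large read set when
    the target set changes (as it does between extension rounds).
    """

    def __init__(self, queries: Mapping[str, str], seed_k: int = 15, window: int = 5):
        self.items = sorted(queries.items())
        self.seed_k = seed_k
        self.window = window
        self.mz = compute_minimizers([s for _, s in self.items], k=seed_k, w=window)
        order = np.argsort(self.mz.hash, kind="stable")
        self.h_sorted = self.mz.hash[order]
        self.seq_sorted = self.mz.seq_idx[order].astype(np.int64)
        self.pos_sorted = self.mz.pos[order].astype(np.int64)
        self.sbit_sorted = self.mz.strand[order].astype(np.int64)


def map_to_targets(
    queries: Mapping[str, str] | QueryIndex,
    targets: Mapping[str, str],
    min_identity: float = 0.98,
    seed_k: int = 15,
    window: int = 5,
    max_posting: int = 2000,
) -> list[ReadMapping]:
    """Seed-and-extend mapping of short queries onto longer targets.

    Target minimizers are matched against the query minimizer table (only
    query-target pairs are ever enumerated), each candidate (query, target,
    strand) keeps its best-voted diagonal, and the placement is verified
    end-to-end with edlib (infix mode) at ``min_identity`` over the query
    length.  A query may map to several targets (e.g. identical regions
    shared between strains); all are reported.
    """
    qi = queries if isinstance(queries, QueryIndex) else QueryIndex(queries, seed_k, window)
    t_items = sorted(targets.items())
    if not qi.items or not t_items:
        return []
    k = qi.seed_k
    t_mz = compute_minimizers([s for _, s in t_items], k=k, w=qi.window)
    if t_mz.hash.size == 0 or qi.h_sorted.size == 0:
        return []
    from ._minimizer import _dedup_sum, _ranges

    lo = np.searchsorted(qi.h_sorted, t_mz.hash, side="left")
    hi = np.searchsorted(qi.h_sorted, t_mz.hash, side="right")
    counts = np.clip(hi - lo, 0, max_posting)
    if int(counts.sum()) == 0:
        return []
    q_lens = np.array([len(s) for _, s in qi.items], dtype=np.int64)

    # chunk over target minimizers to bound the pair expansion
    cum = np.cumsum(counts)
    bounds = [0]
    step = 4_000_000
    while bounds[-1] < len(counts):
        nxt = int(np.searchsorted(cum, (cum[bounds[-1] - 1] if bounds[-1] else 0) + step, side="right"))
        bounds.append(max(nxt, bounds[-1] + 1))
    chunk_rows, chunk_votes = [], []
    for b0, b1 in zip(bounds, bounds[1:]):
        sel = slice(b0, b1)
        c = counts[sel]
        if int(c.sum()) == 0:
            continue
        t_rep = np.repeat(np.arange(b0, b1), c)
        q_pos_in_sorted = np.repeat(lo[sel], c) + _ranges(c)
        q_seq = qi.seq_sorted[q_pos_in_sorted]
        q_pos = qi.pos_sorted[q_pos_in_sorted]
        q_sbit = qi.sbit_sorted[q_pos_in_sorted]
        t_seq = t_mz.seq_idx[t_rep].astype(np.int64)
        t_pos = t_mz.pos[t_rep].astype(np.int64)
        t_sbit = t_mz.strand[t_rep].astype(np.int64)
        st = q_sbit ^ t_sbit
        # same strand: placement of the query on the forward target is
        # t_pos - q_pos; opposite strand: the k-mer sits at lq - k - q_pos
        # on the reverse-complemented query
        diag = np.where(
            st == 0,
            t_pos - q_pos,
            t_pos - (q_lens[q_seq] - k - q_pos),
        )
        r, v = _dedup_sum(
            np.stack([q_seq, t_seq, st, diag], axis=1),
            np.ones(len(diag), dtype=np.int64),
        )
        chunk_rows.append(r)
        chunk_votes.append(v)
    rows, votes = _dedup_sum(np.concatenate(chunk_rows), np.concatenate(chunk_votes))
    key = np.lexsort((-np.abs(rows[:, 3]), votes, rows[:, 2], rows[:, 1], rows[:, 0]))
    rows, votes = rows[key], votes[key]
    grp = rows[:, :3]
    last = np.concatenate((np.any(grp[1:] != grp[:-1], axis=1), [True])) if len(rows) else np.empty(0, bool)
    rows = rows[last]

    out: list[ReadMapping] = []
    rc_cache: dict[int, str] = {}
    for qx, tx, strand_bit, d in rows.tolist():
        qseq = qi.items[qx][1]
        tseq = t_items[tx][1]
        lq, lt = len(qseq), len(tseq)
        # diag gives the start of the oriented query on the forward target
        if strand_bit == 0:
            q_oriented, t0 = qseq, d
        else:
            q_oriented = rc_cache.get(qx)
            if q_oriented is None:
                q_oriented = rc_cache[qx] = revcomp(qseq)
            t0 = d
        pad = 12
        w0 = max(0, int(t0) - pad)
        w1 = min(lt, int(t0) + lq + pad)
        if w1 - w0 < lq * 0.9:
            continue
        max_ed = int(lq * (1.0 - min_identity)) + 1
        res = edlib.align(q_oriented, tseq[w0:w1], mode="HW", task="locations", k=max_ed)
        ed = res["editDistance"]
        if ed < 0:
            continue
        identity = 1.0 - ed / lq
        if identity < min_identity:
            continue
        loc = res["locations"][0]
        out.append(
            ReadMapping(
                query_id=qi.items[qx][0],
                target_id=t_items[tx][0],
                strand=SAME if strand_bit == 0 else OPPOSITE,
                t_start=w0 + loc[0],
                t_end=w0 + loc[1] + 1,
                identity=identity,
            )
        )
    out.sort(key=lambda m: (m.query_id, m.target_id, m.t_start))
    return out


# --- PAF interoperability -------------------------------------------------

def write_paf(hits: Iterable[OverlapHit], path: str | Path) -> int:
    """Write hits as PAF records (12 mandatory columns + cg: tag if known).

    A maps to the query, B to the target; for '-' strand records the cg tag
    describes A against the reverse complement of B, with coordinates kept
    on the forward orientation as PAF requires.
    """
    n = 0
    with open(path, "w") as out:
        for h in hits:
            fields = [
                h.id_a, str(h.len_a), str(h.a_start), str(h.a_end),
                "+" if h.strand == SAME else "-",
                h.id_b, str(h.len_b), str(h.b_start), str(h.b_end),
                str(h.n_match), str(h.aln_len), "255",
            ]
            if h.cigar is not None:
                fields.append(f"cg:Z:{h.cigar}")
            out.write("\t".join(fields) + "\n")
            n += 1
    return n


def read_paf(path: str | Path, require_cigar: bool = False) -> list[OverlapHit]:
    """Parse PAF records (>= 12 mandatory columns) into :class:`OverlapHit`."""
    hits: list[OverlapHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(
                    f"{path}:{lineno}: PAF requires >= 12 columns, got {len(cols)}"
                )
            cigar = None
            for tag in cols[12:]:
                if tag.startswith("cg:Z:"):
                    cigar = tag[5:]
            if require_cigar and cigar is None:
                raise ValueError(f"{path}:{lineno}: missing cg: CIGAR tag")
            hits.append(
                OverlapHit(
                    id_a=cols[0],
                    len_a=int(cols[1]),
                    a_start=int(cols[2]),
                    a_end=int(cols[3]),
                    strand=SAME if cols[4] == "+" else OPPOSITE,
                    id_b=cols[5],
                    len_b=int(cols[6]),
                    b_start=int(cols[7]),
                    b_end=int(cols[8]),
                    n_match=int(cols[9]),
                    aln_len=int(cols[10]),
                    cigar=cigar,
                )
            )
    return hits
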