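"""Vectorized minimizer seeding for all-vs-all overlap candidate detection.

All sequences are concatenated (with invalid sentinel bases between them)
and canonical k-mer hashes are computed in a handful of whole-array numpy
passes.  Window minima select minimizers; candidate sequence pairs are then
enumerated from minimizers sharing a hash, each pair voting for a diagonal
(the implied relative offset of the two sequences).  The dominant diagonal
per (pair, relative strand) seeds the banded end-to-end verification done
by the overlap engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dna import encode

_MIX = np.uint64(0x9E3779B97F4A7C15)


def _hash_mix(x: np.ndarray) -> np.ndarray:
    """Cheap invertible 64-bit mix to decorrelate k-mer ranks."""
    with np.errstate(over="ignore"):
        x = x * _MIX
        x = x ^ (x >> np.uint64(31))
        x = x * np.uint64(0xBF58476D1CE4E5B9)
        x = x ^ (x >> np.uint64(29))
    return x


@dataclass(slots=True)
class Minimizers:
    """Columnar minimizer table over a sequence collection."""

    seq_idx: np.ndarray  # int32, index into the sequence list
    pos: np.ndarray  # int32, k-mer start on the forward sequence
    hash: np.ndarray  # uint64, canonical k-mer hash
    strand: np.ndarray  # uint8, 1 if the canonical k-mer is the reverse complement
    k: int


def compute_minimizers(seqs: Sequence[str], k: int = 15, w: int = 5) -> Minimizers:
    """Canonical (k, w)-minimizers of every sequence, in one numpy pass."""
    if not seqs:
        return Minimizers(
            np.empty(0, np.int32), np.empty(0, np.int32), np.empty(0, np.uint64),
            np.empty(0, np.uint8), k,
        )
    lens = np.fromiter((len(s) for s in seqs), count=len(seqs), dtype=np.int64)
    sep = np.full(1, 255, dtype=np.uint8)
    parts: list[np.ndarray] = []
    for s in seqs:
        parts.append(encode(s))
        parts.append(sep)
    cat = np.concatenate(parts)
    starts = np.concatenate(([0], np.cumsum(lens + 1)[:-1]))

    n_kmer = len(cat) - k + 1
    if n_kmer <= 0:
        return Minimizers(
            np.empty(0, np.int32), np.empty(0, np.int32), np.empty(0, np.uint64),
            np.empty(0, np.uint8), k,
        )
    del parts
    valid_base = cat < 4
    b = np.where(valid_base, cat, 0).astype(np.uint64)
    fwd = np.zeros(n_kmer, dtype=np.uint64)
    rev = np.zeros(n_kmer, dtype=np.uint64)
    two = np.uint64(2)
    for j in range(k):
        fwd = (fwd << two) | b[j : j + n_kmer]
        rev = rev | ((np.uint64(3) - b[j : j + n_kmer]) << np.uint64(2 * j))
    del b
    # k-mers touching a sentinel or N are invalid
    cs = np.concatenate(([0], np.cumsum(~valid_base)))
    kmer_valid = (cs[k:] - cs[:-k]) == 0
    del cs, valid_base

    strand = (rev < fwd).astype(np.uint8)
    np.minimum(fwd, rev, out=fwd)  # canonical k-mer, in place
    del rev
    h = _hash_mix(fwd)
    del fwd
    h[~kmer_valid] = np.uint64(0xFFFFFFFFFFFFFFFF)

    if n_kmer < w:
        win = h.reshape(1, -1)
    else:
        win = np.lib.stride_tricks.sliding_window_view(h, w)
    picks = np.arange(win.shape[0]) + np.argmin(win, axis=1)
    picks = np.unique(picks)
    picks = picks[kmer_valid[picks]]
    if picks.size == 0:
        return Minimizers(
            np.empty(0, np.int32), np.empty(0, np.int32), np.empty(0, np.uint64),
            np.empty(0, np.uint8), k,
        )
    seq_idx = np.searchsorted(starts, picks, side="right") - 1
    pos = picks - starts[seq_idx]
    # drop k-mers that run past their own sequence into the sentinel
    # (already invalid via the sentinel, but keep the guard explicit)
    keep = pos + k <= lens[seq_idx]
    return Minimizers(
        seq_idx[keep].astype(np.int32),
        pos[keep].astype(np.int32),
        h[picks[keep]],
        strand[picks[keep]],
        k,
    )


def _dedup_sum(rows: np.ndarray, counts: np.ndarray):
    """Sum counts of identical rows (rows: structured-free 2D int64 array)."""
    order = np.lexsort(rows.T[::-1])
    rows = rows[order]
    counts = counts[order]
    if len(rows) == 0:
        return rows, counts
    new = np.any(rows[1:] != rows[:-1], axis=1)
    starts = np.concatenate(([0], np.nonzero(new)[0] + 1))
    summed = np.add.reduceat(counts, starts)
    return rows[starts], summed


def candidate_pairs(
    mz: Minimizers,
    lens: np.ndarray,
    max_occ: int = 120,
    chunk: int = 4_000_000,
) -> np.ndarray:
    """Seed-voted overlap candidates from a minimizer table.

    Returns an int64 array with columns (a, b, strand, diag, votes) where
    ``a < b`` are sequence indices, ``strand`` is 0 for same-strand and 1
    for opposite, and ``diag`` is the implied offset of B (oriented per
    ``strand``) relative to A: position x on A pairs with x - diag on the
    oriented B.  Only the best-voted diagonal per (a, b, strand) is kept.
    Minimizers occurring more than ``max_occ`` times (repeats) are skipped.
    """
    if mz.hash.size == 0:
        return np.empty((0, 5), dtype=np.int64)
    k = mz.k
    order = np.argsort(mz.hash, kind="stable")
    h = mz.hash[order]
    sidx = mz.seq_idx[order].astype(np.int64)
    pos = mz.pos[order].astype(np.int64)
    sbit = mz.strand[order].astype(np.int64)

    new_group = np.concatenate(([True], h[1:] != h[:-1]))
    gstart = np.nonzero(new_group)[0]
    gcount = np.diff(np.concatenate((gstart, [len(h)])))
    ok = gcount <= max_occ
    gstart, gcount = gstart[ok], gcount[ok]

    # in-group index j for each element; element pairs with its j predecessors
    total = int(gcount.sum())
    if total == 0:
        return np.empty((0, 5), dtype=np.int64)
    elem = np.repeat(gstart, gcount) + _ranges(gcount)
    j = _ranges(gcount)

    vote_rows: list[np.ndarray] = []
    vote_counts: list[np.ndarray] = []
    n_accum = 0
    merge_threshold = 6_000_000

    def _compact() -> None:
        # cross-chunk duplicates are frequent (one pair shares many
        # minimizers); merging the accumulated tables keeps memory bounded
        nonlocal vote_rows, vote_counts, n_accum
        merged, counts = _dedup_sum(
            np.concatenate(vote_rows), np.concatenate(vote_counts)
        )
        vote_rows, vote_counts = [merged], [counts]
        n_accum = len(merged)

    # chunk over elements so the pair expansion stays within memory
    npairs = j
    cum = np.cumsum(npairs)
    lo = 0
    while lo < len(elem):
        hi = int(np.searchsorted(cum, (cum[lo - 1] if lo else 0) + chunk, side="right"))
        hi = max(hi, lo + 1)
        sel = slice(lo, hi)
        jj = npairs[sel]
        if jj.sum() == 0:
            lo = hi
            continue
        a_elem = np.repeat(elem[sel], jj)
        back = _ranges(jj) + 1
        b_elem = a_elem - back
        ia, ib = sidx[a_elem], sidx[b_elem]
        keep = ia != ib
        ia, ib = ia[keep], ib[keep]
        pa, pb = pos[a_elem][keep], pos[b_elem][keep]
        st = (sbit[a_elem][keep] ^ sbit[b_elem][keep])
        swap = ia > ib
        ia2 = np.where(swap, ib, ia)
        ib2 = np.where(swap, ia, ib)
        pa2 = np.where(swap, pb, pa)
        pb2 = np.where(swap, pa, pb)
        la, lb = lens[ia2], lens[ib2]
        # same strand: x on A <-> x - (pa - pb) on B
        # opposite:    minimizer sits at lb - k - pb on revcomp(B)
        diag = np.where(
            st == 0,
            pa2 - pb2,
            pa2 - (lb - k - pb2),
        )
        rows = np.stack([ia2, ib2, st, diag], axis=1)
        del ia, ib, ia2, ib2, pa, pb, pa2, pb2, st, diag, swap, la, lb, a_elem, b_elem, back
        rows, counts = _dedup_sum(rows, np.ones(len(rows), dtype=np.int64))
        vote_rows.append(rows)
        vote_counts.append(counts)
        n_accum += len(rows)
        if n_accum > merge_threshold:
            _compact()
        lo = hi

    if not vote_rows:
        return np.empty((0, 5), dtype=np.int64)
    _compact()
    rows, counts = vote_rows[0], vote_counts[0]
    # keep best-voted diagonal per (a, b, strand); ties -> smaller |diag|
    key = np.lexsort((-np.abs(rows[:, 3]), counts, rows[:, 2], rows[:, 1], rows[:, 0]))
    rows, counts = rows[key], counts[key]
    grp = rows[:, :3]
    last = np.concatenate((np.any(grp[1:] != grp[:-1], axis=1), [True]))
    rows, counts = rows[last], counts[last]
    return np.concatenate([rows, counts[:, None]], axis=1)


def _ranges(counts: np.ndarray) -> np.ndarray:
    """Concatenated [0..c) ranges for each count c (vectorized)."""
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    offsets = np.repeat(np.concatenate(([0], np.cumsum(counts)[:-1])), counts)
    return np.arange(total, dtype=np.int64) - offsets
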