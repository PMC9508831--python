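"""Assembly evaluation against truth strain genomes.

The reference is the collection of all strain genomes; a contig may align
to several strains (identical inter-strain regions are counted for each,
mirroring ambiguous-alignment handling in metagenome evaluation).  The
module reports genome fraction (overall and per strain), identity, N50,
NGA50, error rate (mismatch + indel), N rate, and a per-contig
misassembly classification: a contig is misassembled when two adjacent
alignment blocks leave a reference gap or overlap of more than 1 kbp,
switch strands, or switch strains.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import edlib
import numpy as np

from .dna import revcomp
from .overlaps import parse_cigar

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class EvalParams:
    """Evaluation settings; ``min_eval_len`` mirrors the usual 500 bp
    contig cutoff (exposed because 300-400 bp cutoffs are sometimes
    appropriate for fragmented strain assemblies)."""

    min_eval_len: int = 500
    min_block_len: int = 65
    min_block_identity: float = 0.95
    ambiguity_score: float = 0.9999
    seed_k: int = 21
    band: int = 100


@dataclass(slots=True)
class ContigAlignment:
    """One local alignment block of a contig against a strain genome.

    Intervals are 0-based half-open; ``contig_interval`` always refers to
    the forward orientation of the contig.
    """

    contig_id: str
    ref_strain_id: str
    c_start: int
    c_end: int
    r_start: int
    r_end: int
    strand: str  # '+' | '-'
    n_match: int
    n_mismatch: int
    n_indel_bases: int
    aligned_cols: int
    is_best: bool = False

    @property
    def identity(self) -> float:
        return self.n_match / self.aligned_cols


@dataclass
class AssemblyMetrics:
    """Summary metrics; percentages are in [0, 100]."""

    genome_fraction: float = 0.0
    genome_fraction_per_strain: Dict[str, float] = field(default_factory=dict)
    identity: float = 0.0
    total_len: int = 0
    n_contigs: int = 0
    n50: int = 0
    nga50: Optional[int] = None
    misassembled_contig_rate: float = 0.0
    mismatch_rate: float = 0.0
    indel_rate: float = 0.0
    error_rate: float = 0.0
    n_rate: float = 0.0

    def as_dict(self) -> Dict[str, object]:
        d = {
            "genome_fraction": round(self.genome_fraction, 3),
            "identity": round(self.identity, 3),
            "total_len": self.total_len,
            "n_contigs": self.n_contigs,
            "n50": self.n50,
            "nga50": self.nga50 if self.nga50 is not None else "-",
            "misassembled_contig_rate": round(self.misassembled_contig_rate, 3),
            "error_rate": round(self.error_rate, 4),
            "n_rate": round(self.n_rate, 4),
        }
        for sid, gf in sorted(self.genome_fraction_per_strain.items()):
            d[f"genome_fraction[{sid}]"] = round(gf, 3)
        return d


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    from .dna import encode

    codes = encode(seq)
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    valid = codes < 4
    b = np.where(valid, codes, 0).astype(np.int64)
    out = np.zeros(n, dtype=np.int64)
    for j in range(k):
        out = (out << 2) | b[j : j + n]
    cs = np.concatenate(([0], np.cumsum(~valid)))
    bad = (cs[k:] - cs[:-k]) > 0
    out[bad] = -1
    return out


def _index_truth(truth: Mapping[str, str], k: int) -> Dict[int, List[Tuple[int, int]]]:
    index: Dict[int, List[Tuple[int, int]]] = {}
    for si, sid in enumerate(sorted(truth)):
        codes = _kmer_codes(truth[sid], k)
        for pos, code in enumerate(codes.tolist()):
            if code >= 0:
                index.setdefault(code, []).append((si, pos))
    return index


def align_contigs_to_truth(
    contigs: Mapping[str, str],
    truth_genomes: Mapping[str, str],
    params: EvalParams = EvalParams(),
) -> List[ContigAlignment]:
    """Seed-and-verify local alignment of contigs to every strain genome.

    Exact k-mer matches are clustered per (strain, strand, diagonal band);
    each cluster is verified end-to-end with edlib and kept when at least
    ``min_block_len`` long at ``min_block_identity``.  All near-optimal
    placements are retained (``is_best`` marks, per contig region, blocks
    within ``ambiguity_score`` of the best score).
    """
    k = params.seed_k
    strain_ids = sorted(truth_genomes)
    index = _index_truth(truth_genomes, k)
    out: List[ContigAlignment] = []
    for cid in sorted(contigs):
        cseq = contigs[cid]
        lc = len(cseq)
        blocks: List[ContigAlignment] = []
        for strand in ("+", "-"):
            q = cseq if strand == "+" else revcomp(cseq)
            codes = _kmer_codes(q, k)
            # matches[(strain)] -> list of (qpos, rpos)
            per_strain: Dict[int, List[Tuple[int, int]]] = {}
            for qpos, code in enumerate(codes.tolist()):
                if code < 0:
                    continue
                for si, rpos in index.get(code, ()):
                    per_strain.setdefault(si, []).append((qpos, rpos))
            for si, matches in sorted(per_strain.items()):
                blocks.extend(
                    _verify_clusters(
                        cid, q, lc, strand, strain_ids[si],
                        truth_genomes[strain_ids[si]], matches, params,
                    )
                )
        _mark_best(blocks, params.ambiguity_score)
        out.extend(blocks)
    out.sort(key=lambda b: (b.contig_id, b.c_start, b.ref_strain_id, b.r_start))
    return out


def _verify_clusters(
    cid: str,
    q: str,
    lc: int,
    strand: str,
    strain_id: str,
    genome: str,
    matches: List[Tuple[int, int]],
    params: EvalParams,
) -> List[ContigAlignment]:
    k = params.seed_k
    matches.sort()
    clusters: List[List[Tuple[int, int]]] = []
    for qpos, rpos in matches:
        placedq = False
        for cl in clusters:
            pq, pr = cl[-1]
            if qpos - pq <= 1000 and abs((qpos - rpos) - (pq - pr)) <= params.band:
                cl.append((qpos, rpos))
                placedq = True
                break
        if not placedq:
            clusters.append([(qpos, rpos)])
    out: List[ContigAlignment] = []
    for cl in clusters:
        q0 = cl[0][0]
        q1 = cl[-1][0] + k
        r0 = min(r for _, r in cl)
        r1 = max(r for _, r in cl) + k
        # extend to the contig ends when close, padding the reference
        ext_left = min(q0, 30)
        ext_right = min(len(q) - q1, 30)
        if q0 <= 30:
            ext_left = q0
        if len(q) - q1 <= 30:
            ext_right = len(q) - q1
        q0e, q1e = q0 - ext_left, q1 + ext_right
        r0e = max(0, r0 - ext_left - 10)
        r1e = min(len(genome), r1 + ext_right + 10)
        if q1e - q0e < params.min_block_len:
            continue
        res = edlib.align(q[q0e:q1e], genome[r0e:r1e], mode="HW", task="path")
        if res["editDistance"] < 0:
            continue
        loc = res["locations"][0]
        n_eq, n_x, n_i, n_d, cols = parse_cigar(res["cigar"])
        if cols == 0 or n_eq / cols < params.min_block_identity:
            continue
        if q1e - q0e < params.min_block_len:
            continue
        if strand == "+":
            c_start, c_end = q0e, q1e
        else:
            c_start, c_end = lc - q1e, lc - q0e
        out.append(
            ContigAlignment(
                contig_id=cid,
                ref_strain_id=strain_id,
                c_start=c_start,
                c_end=c_end,
                r_start=r0e + loc[0],
                r_end=r0e + loc[1] + 1,
                strand=strand,
                n_match=n_eq,
                n_mismatch=n_x,
                n_indel_bases=n_i + n_d,
                aligned_cols=cols,
            )
        )
    return out


def _mark_best(blocks: List[ContigAlignment], ambiguity_score: float) -> None:
    """Mark, per contig region, the near-optimal blocks.

    Blocks whose contig intervals overlap by >= 80% of the shorter are
    alternative placements of the same region; within such a group every
    block scoring within ``ambiguity_score`` of the group's best is
    marked best.
    """
    for b in blocks:
        b.is_best = True
    for i, b1 in enumerate(blocks):
        for b2 in blocks[i + 1 :]:
            lo = max(b1.c_start, b2.c_start)
            hi = min(b1.c_end, b2.c_end)
            shorter = min(b1.c_end - b1.c_start, b2.c_end - b2.c_start)
            if hi - lo < 0.8 * shorter:
                continue
            if b1.n_match * ambiguity_score > b2.n_match:
                b2.is_best = False
            elif b2.n_match * ambiguity_score > b1.n_match:
                b1.is_best = False


def genome_fraction(
    alignments: Sequence[ContigAlignment], truth: Mapping[str, str]
) -> Tuple[float, Dict[str, float]]:
    """Percentage of truth bases covered by any alignment, overall and per
    strain (the central strain-awareness measure)."""
    per_strain: Dict[str, float] = {}
    covered_total = 0
    len_total = 0
    by_strain: Dict[str, List[Tuple[int, int]]] = {}
    for a in alignments:
        by_strain.setdefault(a.ref_strain_id, []).append((a.r_start, a.r_end))
    for sid in sorted(truth):
        glen = len(truth[sid])
        ivals = sorted(by_strain.get(sid, []))
        covered = 0
        cur_s, cur_e = None, None
        for s, e in ivals:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            covered += cur_e - cur_s
        per_strain[sid] = 100.0 * covered / glen if glen else 0.0
        covered_total += covered
        len_total += glen
    overall = 100.0 * covered_total / len_total if len_total else 0.0
    return overall, per_strain


def n50(lengths: Iterable[int]) -> int:
    """Largest L such that contigs of length >= L hold >= half the total."""
    ls = sorted(lengths, reverse=True)
    total = sum(ls)
    if total == 0:
        return 0
    acc = 0
    for L in ls:
        acc += L
        if acc * 2 >= total:
            return L
    return ls[-1]


def nga50(
    alignments: Sequence[ContigAlignment], truth: Mapping[str, str]
) -> Optional[int]:
    """NGA50 over aligned blocks against the total truth length.

    ``None`` (reported as '-') when the aligned blocks cover less than
    half of the truth.
    """
    truth_total = sum(len(g) for g in truth.values())
    if truth_total == 0:
        return None
    block_lens = sorted((a.r_end - a.r_start for a in alignments), reverse=True)
    if sum(block_lens) < 0.5 * truth_total:
        return None
    acc = 0
    for L in block_lens:
        acc += L
        if acc * 2 >= truth_total:
            return L
    return None


def classify_misassemblies(
    alignments: Sequence[ContigAlignment], max_gap: int = 1000
) -> Tuple[Dict[str, bool], float]:
    """Per-contig misassembly flags and the misassembled-contig rate (%).

    Adjacent best blocks (ordered by contig coordinate, ambiguity
    duplicates collapsed) trigger a misassembly when they (i) leave a
    reference gap or overlap larger than ``max_gap`` bp, (ii) lie on
    different strands, or (iii) align to different strains.  Single-block
    contigs are never misassembled.
    """
    by_contig: Dict[str, List[ContigAlignment]] = {}
    for a in alignments:
        by_contig.setdefault(a.contig_id, []).append(a)
    flags: Dict[str, bool] = {}
    for cid, blocks in by_contig.items():
        chain: List[ContigAlignment] = []
        for b in sorted(blocks, key=lambda x: (x.c_start, -x.n_match)):
            if not b.is_best:
                continue
            dup = False
            for c in chain:
                lo, hi = max(b.c_start, c.c_start), min(b.c_end, c.c_end)
                shorter = min(b.c_end - b.c_start, c.c_end - c.c_start)
                if hi - lo >= 0.8 * shorter:
                    dup = True  # alternative placement of the same region
                    break
            if not dup:
                chain.append(b)
        bad = False
        for b1, b2 in zip(chain, chain[1:]):
            if b1.strand != b2.strand or b1.ref_strain_id != b2.ref_strain_id:
                bad = True
                break
            gap = b2.r_start - b1.r_end if b1.strand == "+" else b1.r_start - b2.r_end
            if abs(gap) > max_gap:
                bad = True
                break
        flags[cid] = bad
    n_eval = len(flags)
    rate = 100.0 * sum(flags.values()) / n_eval if n_eval else 0.0
    return flags, rate


def error_and_n_rates(
    alignments: Sequence[ContigAlignment], contigs: Mapping[str, str]
) -> Tuple[float, float, float, float]:
    """(mismatch, indel, error, N) rates in percent.

    Mismatch and indel rates are per aligned column; the error rate is
    their sum.  The N rate is ambiguous bases over all evaluated contig
    bases.
    """
    cols = sum(a.aligned_cols for a in alignments)
    mism = sum(a.n_mismatch for a in alignments)
    indel = sum(a.n_indel_bases for a in alignments)
    mismatch_rate = 100.0 * mism / cols if cols else 0.0
    indel_rate = 100.0 * indel / cols if cols else 0.0
    total_bases = sum(len(s) for s in contigs.values())
    n_bases = sum(s.count("N") for s in contigs.values())
    n_rate = 100.0 * n_bases / total_bases if total_bases else 0.0
    return mismatch_rate, indel_rate, mismatch_rate + indel_rate, n_rate


def evaluate_assembly(
    contigs: Mapping[str, str],
    truth_genomes: Mapping[str, str],
    params: EvalParams = EvalParams(),
) -> AssemblyMetrics:
    """Full evaluation of an assembly against truth strain genomes."""
    kept = {
        cid: seq for cid, seq in contigs.items() if len(seq) >= params.min_eval_len
    }
    metrics = AssemblyMetrics()
    metrics.n_contigs = len(kept)
    metrics.total_len = sum(len(s) for s in kept.values())
    metrics.n50 = n50(len(s) for s in kept.values())
    if not kept:
        _, per = genome_fraction([], truth_genomes)
        metrics.genome_fraction_per_strain = per
        return metrics
    alignments = [
        a for a in align_contigs_to_truth(kept, truth_genomes, params) if a.is_best
    ]
    overall, per = genome_fraction(alignments, truth_genomes)
    metrics.genome_fraction = overall
    metrics.genome_fraction_per_strain = per
    metrics.nga50 = nga50(alignments, truth_genomes)
    _, metrics.misassembled_contig_rate = classify_misassemblies(alignments)
    (
        metrics.mismatch_rate,
        metrics.indel_rate,
        metrics.error_rate,
        metrics.n_rate,
    ) = error_and_n_rates(alignments, kept)
    cols = sum(a.aligned_cols for a in alignments)
    match = sum(a.n_match for a in alignments)
    metrics.identity = 100.0 * match / cols if cols else 0.0
    return metrics


def write_metrics(
    metrics: AssemblyMetrics,
    alignments: Sequence[ContigAlignment],
    out_prefix: str | Path,
) -> None:
    """Write a metrics TSV and a per-contig classification TSV."""
    out_prefix = Path(out_prefix)
    with open(out_prefix.with_suffix(".metrics.tsv"), "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for key, val in metrics.as_dict().items():
            w.writerow([key, val])
    flags, _ = classify_misassemblies(alignments)
    with open(out_prefix.with_suffix(".contigs.tsv"), "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["contig_id", "misassembled"])
        for cid in sorted(flags):
            w.writerow([cid, int(flags[cid])])
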