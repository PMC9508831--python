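"""FASTQ/FASTA input-output and pre-assembly read quality control.

Quality control follows the usual short-read preprocessing rules: terminal
bases below a Phred threshold are clipped from both read ends, exact adapter
matches are removed from the 3' end, reads that end up too short are
discarded, and within the self-overlapping part of a read pair a mismatched
low-quality base is corrected from its high-quality mate.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO

from .dna import revcomp

logger = logging.getLogger(__name__)

_COMPLEMENT_BASE = str.maketrans("ACGTN", "TGCAN")


class MalformedRecordError(ValueError):
    """A FASTQ record violates the format (e.g. base/quality length mismatch)."""


class MatePairError(ValueError):
    """Paired FASTQ files disagree in record count or read naming."""


@dataclass(slots=True)
class SequencingRead:
    """A single sequencing read with per-base Phred qualities.

    ``quals`` is stored as a uint8 numpy array of the same length as
    ``bases``.  ``mate_id`` links the read to its mate for paired-end data;
    ``mate_orientation`` is ``"FR"`` for standard forward-reverse libraries
    and ``"unknown"`` otherwise.
    """

    read_id: str
    bases: str
    quals: np.ndarray
    mate_id: Optional[str] = None
    mate_orientation: str = "unknown"

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.uint8)
        if len(self.quals) != len(self.bases):
            raise MalformedRecordError(
                f"record {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality values"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(slots=True)
class QCParams:
    """Quality-control parameters.

    end_trim_phred
        Terminal bases with Phred below this value are clipped from the 5'
        and 3' ends (single pass per end).
    min_len_keep
        Reads are kept only if strictly longer than this after trimming.
    min_len_strainaware
        Optional additional floor (e.g. 150 bp for pre-trimmed archives):
        reads shorter than this are discarded even if they pass
        ``min_len_keep``.  Too-short reads cannot link co-occurring variants
        and therefore do not help strain-aware assembly.
    adapters
        Optional adapter sequences clipped from the 3' end on an exact match.
    correction_margin
        Minimal Phred difference for mate-overlap base correction.
    """

    end_trim_phred: int = 20
    min_len_keep: int = 70
    min_len_strainaware: Optional[int] = None
    adapters: Tuple[str, ...] = ()
    correction_margin: int = 20

    def __post_init__(self) -> None:
        if self.end_trim_phred < 0:
            raise ValueError("end_trim_phred must be >= 0")
        if self.min_len_keep < 1:
            raise ValueError("min_len_keep must be >= 1")
        self.adapters = tuple(a.upper() for a in self.adapters)


@dataclass(slots=True)
class QCReport:
    """Bookkeeping for one QC run; counts reconcile exactly with outcomes."""

    n_input: int = 0
    n_kept: int = 0
    n_dropped_short: int = 0
    n_bases_trimmed: int = 0
    n_bases_corrected: int = 0

    def validate(self) -> None:
        if self.n_kept + self.n_dropped_short != self.n_input:
            raise AssertionError("QCReport counts do not reconcile")


def _open_maybe_gzip(path: Path) -> IO[str]:
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _id_stem(read_id: str) -> str:
    if len(read_id) > 2 and read_id[-2] == "/" and read_id[-1] in "12":
        return read_id[:-2]
    return read_id


def _records(path: Path) -> Iterator[SequencingRead]:
    with _open_maybe_gzip(path) as handle:
        try:
            for rec in SeqIO.parse(handle, "fastq"):
                yield SequencingRead(
                    read_id=rec.id,
                    bases=str(rec.seq).upper(),
                    quals=np.asarray(
                        rec.letter_annotations["phred_quality"], dtype=np.uint8
                    ),
                )
        except ValueError as exc:  # biopython names the offending record
            raise MalformedRecordError(str(exc)) from exc


def parse_fastq(
    path: str | Path, paired_with: str | Path | None = None
) -> Iterator[SequencingRead]:
    """Stream reads from a FASTQ file, transparently handling gzip.

    With ``paired_with`` the two files are read in lockstep and yielded
    interleaved (R1, R2, R1, R2, ...) with ``mate_id`` cross-populated.
    Unequal record counts or mismatching id stems raise :class:`MatePairError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if paired_with is None:
        yield from _records(path)
        return

    mate_path = Path(paired_with)
    if not mate_path.exists():
        raise FileNotFoundError(mate_path)
    it1, it2 = _records(path), _records(mate_path)
    _sentinel = object()
    n = 0
    while True:
        r1 = next(it1, _sentinel)
        r2 = next(it2, _sentinel)
        if r1 is _sentinel and r2 is _sentinel:
            return
        if (r1 is _sentinel) != (r2 is _sentinel):
            raise MatePairError(
                f"paired files {path.name} / {mate_path.name} have unequal "
                f"record counts (diverge after {n} pairs)"
            )
        assert isinstance(r1, SequencingRead) and isinstance(r2, SequencingRead)
        if _id_stem(r1.read_id) != _id_stem(r2.read_id):
            raise MatePairError(
                f"mate ids do not match at pair {n}: "
                f"{r1.read_id!r} vs {r2.read_id!r}"
            )
        if r1.read_id == r2.read_id:
            r1.read_id += "/1"
            r2.read_id += "/2"
        r1.mate_id, r1.mate_orientation = r2.read_id, "FR"
        r2.mate_id, r2.mate_orientation = r1.read_id, "FR"
        n += 1
        yield r1
        yield r2


def _clip_adapters(bases: str, quals: np.ndarray, adapters: Sequence[str]):
    """Remove the 3'-terminal segment starting at an exact adapter match.

    A full adapter occurrence anywhere cuts the read at its start; a
    3'-terminal fragment that is an adapter prefix of >= 8 bp is clipped too.
    """
    cut = len(bases)
    for ad in adapters:
        if not ad:
            continue
        pos = bases.find(ad)
        if pos != -1:
            cut = min(cut, pos)
        for frag in range(min(len(ad), len(bases)) - 1, 7, -1):
            if bases.endswith(ad[:frag]):
                cut = min(cut, len(bases) - frag)
                break
    return bases[:cut], quals[:cut]


def quality_trim(read: SequencingRead, params: QCParams) -> Optional[SequencingRead]:
    """Trim a read; return the trimmed read or ``None`` (= discard).

    Adapter clipping runs first, then a single pass from each end removes
    terminal bases with Phred below ``end_trim_phred`` (stopping at the
    first base meeting the threshold).  Reads are kept only when strictly
    longer than ``min_len_keep`` (and at least ``min_len_strainaware`` when
    that floor is set).
    """
    bases, quals = _clip_adapters(read.bases, read.quals, params.adapters)
    lo, hi = 0, len(bases)
    while lo < hi and quals[lo] < params.end_trim_phred:
        lo += 1
    while hi > lo and quals[hi - 1] < params.end_trim_phred:
        hi -= 1
    bases, quals = bases[lo:hi], quals[lo:hi]
    if len(bases) <= params.min_len_keep:
        return None
    if params.min_len_strainaware is not None and len(bases) < params.min_len_strainaware:
        return None
    if len(bases) == len(read.bases):
        return read
    return replace(read, bases=bases, quals=quals)


def _overlap_diagonal(r1: str, rc2: str, k: int = 11, min_votes: int = 3) -> Optional[int]:
    """Best offset of ``rc2`` relative to ``r1`` by exact k-mer diagonal votes."""
    if len(r1) < k or len(rc2) < k:
        return None
    index: dict[str, list[int]] = {}
    for i in range(len(r1) - k + 1):
        index.setdefault(r1[i : i + k], []).append(i)
    votes: dict[int, int] = {}
    for j in range(len(rc2) - k + 1):
        for i in index.get(rc2[j : j + k], ()):
            d = i - j
            votes[d] = votes.get(d, 0) + 1
    if not votes:
        return None
    diag, n = max(votes.items(), key=lambda kv: (kv[1], -abs(kv[0])))
    return diag if n >= min_votes else None


def pair_overlap_correct(
    r1: SequencingRead, r2: SequencingRead, params: QCParams = QCParams()
) -> Tuple[SequencingRead, SequencingRead, int]:
    """Correct mismatched bases in the self-overlap of a read pair.

    The reverse complement of R2 is aligned against R1 (exact k-mer diagonal
    voting; substitution-only comparison within the implied overlap).  At
    overlap positions where the bases disagree and one Phred exceeds the
    other by at least ``correction_margin``, the low-quality base and its
    quality are replaced by the high-quality ones.  Without a detectable
    overlap the pair is returned unchanged.
    """
    rc2 = revcomp(r2.bases)
    d = _overlap_diagonal(r1.bases, rc2)
    if d is None:
        return r1, r2, 0
    a0, b0 = max(0, d), max(0, -d)
    span = min(len(r1) - a0, len(rc2) - b0)
    if span < 10:
        return r1, r2, 0
    b1 = np.frombuffer(r1.bases.encode(), dtype=np.uint8)[a0 : a0 + span]
    b2 = np.frombuffer(rc2.encode(), dtype=np.uint8)[b0 : b0 + span]
    q1 = r1.quals[a0 : a0 + span]
    # rc2 position j maps to r2 forward position len(r2)-1-(b0+j)
    q2_rc = r2.quals[::-1][b0 : b0 + span]
    diff = b1 != b2
    if diff.sum() > 0.3 * span:  # spurious diagonal, not a real overlap
        return r1, r2, 0
    margin = params.correction_margin
    fix1 = diff & (q2_rc.astype(int) - q1.astype(int) >= margin)
    fix2 = diff & (q1.astype(int) - q2_rc.astype(int) >= margin)
    n_corrected = int(fix1.sum() + fix2.sum())
    if n_corrected == 0:
        return r1, r2, 0
    if fix1.any():
        new_bases = np.frombuffer(r1.bases.encode(), dtype=np.uint8).copy()
        new_quals = r1.quals.copy()
        idx = a0 + np.nonzero(fix1)[0]
        new_bases[idx] = b2[fix1]
        new_quals[idx] = q2_rc[fix1]
        r1 = replace(r1, bases=new_bases.tobytes().decode(), quals=new_quals)
    if fix2.any():
        new_bases = np.frombuffer(r2.bases.encode(), dtype=np.uint8).copy()
        new_quals = r2.quals.copy()
        j = np.nonzero(fix2)[0]
        fwd_idx = len(r2.bases) - 1 - (b0 + j)
        fixed = (
            b1[fix2]
            .tobytes()
            .decode()
            .translate(_COMPLEMENT_BASE)
            .encode()
        )
        new_bases[fwd_idx] = np.frombuffer(fixed, dtype=np.uint8)
        new_quals[fwd_idx] = q1[fix2]
        r2 = replace(r2, bases=new_bases.tobytes().decode(), quals=new_quals)
    return r1, r2, n_corrected


def run_qc(
    reads: Iterable[SequencingRead], params: QCParams = QCParams()
) -> Tuple[list[SequencingRead], QCReport]:
    """Apply mate-overlap correction and trimming to a read stream.

    Consecutive reads whose ``mate_id`` fields cross-reference each other
    are treated as pairs and corrected before trimming.  Returns the kept
    reads (file order preserved) and a :class:`QCReport`.
    """
    report = QCReport()
    kept: list[SequencingRead] = []
    pending: Optional[SequencingRead] = None

    def _emit(read: Optional[SequencingRead], raw_len: int) -> None:
        report.n_input += 1
        if read is None:
            report.n_dropped_short += 1
        else:
            report.n_kept += 1
            report.n_bases_trimmed += raw_len - len(read)
            kept.append(read)

    for read in reads:
        if pending is not None:
            if pending.mate_id == read.read_id and read.mate_id == pending.read_id:
                r1, r2, n_corr = pair_overlap_correct(pending, read, params)
                report.n_bases_corrected += n_corr
                _emit(quality_trim(r1, params), len(r1))
                _emit(quality_trim(r2, params), len(r2))
                pending = None
                continue
            _emit(quality_trim(pending, params), len(pending))
            pending = None
        if read.mate_id is not None:
            pending = read
        else:
            _emit(quality_trim(read, params), len(read))
    if pending is not None:
        _emit(quality_trim(pending, params), len(pending))
    report.validate()
    return kept, report


def write_fasta(records: Iterable[Tuple[str, str]], path: str | Path) -> int:
    """Write (id, sequence) records as 80-column-wrapped FASTA.

    Whitespace inside ids is replaced by ``_`` (and logged).  Returns the
    number of records written.
    """
    path = Path(path)
    n = 0
    with open(path, "w") as out:
        for rid, seq in records:
            clean = "_".join(rid.split())
            if clean != rid:
                logger.warning("FASTA id %r contains whitespace; written as %r", rid, clean)
            out.write(f">{clean}\n")
            for i in range(0, len(seq), 80):
                out.write(seq[i : i + 80] + "\n")
            n += 1
    return n


def write_fastq(reads: Iterable[SequencingRead], path: str | Path) -> int:
    """Write reads as Phred+33 FASTQ; returns the number of records."""
    n = 0
    with open(path, "w") as out:
        for read in reads:
            qual = (read.quals + 33).tobytes().decode("ascii")
            out.write(f"@{read.read_id}\n{read.bases}\n+\n{qual}\n")
            n += 1
    return n


def read_fasta(path: str | Path) -> list[Tuple[str, str]]:
    """Read a (possibly gzipped) FASTA file into (id, sequence) tuples."""
    with _open_maybe_gzip(Path(path)) as handle:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fasta")]
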