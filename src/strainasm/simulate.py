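"""Synthetic strain-community generator with full per-read ground truth.

Communities contain several species, each with sibling strains derived
from a common ancestor genome by placing substitutions at controlled
spacing until the requested average nucleotide identity (ANI) is reached.
Per-strain abundances follow a log-normal distribution (natural log, mean
0; only sigma is exposed since the scale cancels under normalization),
paired-end reads are drawn uniformly along each linear genome in FR
orientation, and sequencing errors are i.i.d. substitutions at a fixed
rate, with Phred values encoding that rate.  Every simulated read carries
one ground-truth record (strain, position, strand).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .dna import CODE_BASE, decode, encode, revcomp
from .io_qc import SequencingRead


@dataclass(slots=True)
class StrainSpec:
    """One strain genome with its derivation metadata."""

    species_id: str
    strain_id: str
    genome: str
    ani_to_sibling: float
    snp_positions: List[int]
    abundance: float


@dataclass(slots=True)
class CommunitySpec:
    """Parameters of a simulated strain community.

    ``mean_coverage`` is the average per-strain coverage; individual
    strain coverages scale with the normalized log-normal abundances
    (``lognormal_sigma = 0`` gives uniform coverage).  ``target_ani`` is
    the ANI between sibling strains of one species; SNP spacing is drawn
    within [min_snp_gap, max_snp_gap].
    """

    n_species: int = 4
    strains_per_species: int = 2
    genome_len: int = 100_000
    target_ani: float = 0.99
    min_snp_gap: int = 50
    max_snp_gap: int = 400
    mean_coverage: float = 20.0
    lognormal_sigma: float = 0.0
    read_len: int = 250
    insert_mean: float = 600.0
    insert_sd: float = 60.0
    subst_error: float = 0.003
    seed: int = 1

    def __post_init__(self) -> None:
        for rate in (self.subst_error,):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if not 0.0 < self.target_ani <= 1.0:
            raise ValueError("target_ani must lie in (0, 1]")


@dataclass
class GroundTruth:
    """Per-read provenance plus the truth genomes."""

    # read_id -> (strain_id, 0-based genome position, strand '+'/'-')
    reads: Dict[str, Tuple[str, int, str]] = field(default_factory=dict)
    genomes: Dict[str, str] = field(default_factory=dict)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["read_id", "strain_id", "position", "strand"])
            for rid in sorted(self.reads):
                strain, pos, strand = self.reads[rid]
                w.writerow([rid, strain, pos, strand])


def random_genome(length: int, rng: np.random.Generator) -> str:
    """I.i.d. uniform A/C/G/T ancestor genome."""
    return decode(rng.integers(0, 4, size=length).astype(np.uint8))


def _snp_positions(
    genome_len: int, n_snps: int, min_gap: int, max_gap: int, rng: np.random.Generator
) -> np.ndarray:
    """Place ``n_snps`` positions with consecutive gaps inside [min_gap, max_gap].

    The gap distribution is uniform on the widest interval centred on the
    mean gap the SNP count requires that still respects the requested
    bounds, so both the SNP count (hence ANI) and the spacing constraint
    hold exactly.
    """
    if n_snps == 0:
        return np.empty(0, dtype=np.int64)
    mean_gap = genome_len / (n_snps + 1)
    if mean_gap < min_gap or (n_snps - 1) * min_gap >= genome_len:
        need = (n_snps - 1) * min_gap
        raise ValueError(
            f"cannot place {n_snps} substitutions with min gap {min_gap} in "
            f"{genome_len} bp (needs >= {need} bp)"
        )
    if mean_gap > max_gap:
        raise ValueError(
            f"max gap {max_gap} too small for only {n_snps} substitutions in "
            f"{genome_len} bp"
        )
    half = 0.9 * min(mean_gap - min_gap, max_gap - mean_gap)
    for _ in range(100):
        gaps = rng.uniform(mean_gap - half, mean_gap + half, size=n_snps)
        pos = np.floor(np.cumsum(gaps)).astype(np.int64) - 1
        if pos[-1] < genome_len and pos[0] >= 0 and len(np.unique(pos)) == n_snps:
            d = np.diff(pos)
            if len(d) == 0 or (d.min() >= min_gap // 2 and d.max() <= max_gap):
                return pos
        half *= 0.95
    raise ValueError("could not satisfy SNP spacing constraints")


def mutate_genome(
    ancestor: str,
    target_ani: float,
    min_snp_gap: int,
    max_snp_gap: int,
    rng: np.random.Generator,
    species_id: str = "sp0",
    strain_id: str = "sp0_strain1",
) -> StrainSpec:
    """Derive a sibling strain by substitutions down to ``target_ani``.

    The number of substitutions is round((1 - ANI) * len); each substituted
    base is replaced by a different uniformly drawn base.  The realized ANI
    is recorded on the returned :class:`StrainSpec`.
    """
    n = int(round((1.0 - target_ani) * len(ancestor)))
    pos = _snp_positions(len(ancestor), n, min_snp_gap, max_snp_gap, rng)
    codes = encode(ancestor).copy()
    if n:
        shift = rng.integers(1, 4, size=n).astype(np.uint8)
        codes[pos] = (codes[pos] + shift) % 4
    genome = decode(codes)
    realized = 1.0 - n / len(ancestor)
    return StrainSpec(
        species_id=species_id,
        strain_id=strain_id,
        genome=genome,
        ani_to_sibling=realized,
        snp_positions=pos.tolist(),
        abundance=0.0,
    )


def sample_abundances(n: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Normalized log-normal abundance weights (LogNormal(0, sigma))."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return np.full(n, 1.0 / n)
    w = rng.lognormal(mean=0.0, sigma=sigma, size=n)
    return w / w.sum()


def make_strains(spec: CommunitySpec, rng: np.random.Generator) -> List[StrainSpec]:
    """Generate all strain genomes of a community (ancestor per species)."""
    strains: List[StrainSpec] = []
    weights = sample_abundances(
        spec.n_species * spec.strains_per_species, spec.lognormal_sigma, rng
    )
    wi = 0
    for s in range(spec.n_species):
        species_id = f"sp{s}"
        ancestor = random_genome(spec.genome_len, rng)
        first = StrainSpec(
            species_id=species_id,
            strain_id=f"{species_id}_strain0",
            genome=ancestor,
            ani_to_sibling=spec.target_ani,
            snp_positions=[],
            abundance=float(weights[wi]),
        )
        wi += 1
        strains.append(first)
        for t in range(1, spec.strains_per_species):
            st = mutate_genome(
                ancestor,
                spec.target_ani,
                spec.min_snp_gap,
                spec.max_snp_gap,
                rng,
                species_id=species_id,
                strain_id=f"{species_id}_strain{t}",
            )
            st.abundance = float(weights[wi])
            wi += 1
            strains.append(st)
    return strains


def _phred_for_error(rate: float) -> int:
    if rate <= 0:
        return 40
    return max(2, min(41, int(round(-10.0 * math.log10(rate)))))


def simulate_paired_reads(
    spec: CommunitySpec,
    strains: Sequence[StrainSpec],
    rng: np.random.Generator,
) -> Tuple[List[SequencingRead], GroundTruth]:
    """Uniform FR paired-end reads from each strain genome.

    Per strain, n_pairs = round(coverage * genome_len / (2 * read_len))
    with coverage = mean_coverage * n_strains * abundance.  Fragments are
    placed uniformly within the linear genome (reads never run over the
    ends); overlapping mates are allowed when the insert is short.
    Substitution errors are i.i.d. at ``subst_error`` and Phred values are
    set to match that rate.
    """
    reads: List[SequencingRead] = []
    truth = GroundTruth()
    rl = spec.read_len
    q = _phred_for_error(spec.subst_error)
    n_strains = len(strains)
    for st in strains:
        truth.genomes[st.strain_id] = st.genome
        glen = len(st.genome)
        coverage = spec.mean_coverage * n_strains * st.abundance
        n_pairs = int(round(coverage * glen / (2.0 * rl)))
        gcodes = encode(st.genome)
        frag_lens = np.clip(
            np.round(rng.normal(spec.insert_mean, spec.insert_sd, size=n_pairs)),
            rl,
            glen,
        ).astype(np.int64)
        starts = rng.integers(0, glen - frag_lens + 1)
        flip = rng.integers(0, 2, size=n_pairs)
        err = spec.subst_error
        for p in range(n_pairs):
            s, fl = int(starts[p]), int(frag_lens[p])
            fwd = gcodes[s : s + rl].copy()
            rev_src = gcodes[s + fl - rl : s + fl]
            rev = ((3 - rev_src) % 4)[::-1].copy()  # reverse complement
            if flip[p] == 0:
                r1_codes, r2_codes = fwd, rev
                pos1, str1 = s, "+"
                pos2, str2 = s + fl - rl, "-"
            else:
                r1_codes, r2_codes = rev, fwd
                pos1, str1 = s + fl - rl, "-"
                pos2, str2 = s, "+"
            for codes in (r1_codes, r2_codes):
                if err > 0:
                    nerr = rng.binomial(rl, err)
                    if nerr:
                        at = rng.choice(rl, size=nerr, replace=False)
                        codes[at] = (codes[at] + rng.integers(1, 4, size=nerr)) % 4
            rid1 = f"{st.strain_id}_p{p}/1"
            rid2 = f"{st.strain_id}_p{p}/2"
            quals = np.full(rl, q, dtype=np.uint8)
            r1 = SequencingRead(
                read_id=rid1, bases=CODE_BASE[r1_codes].tobytes().decode(),
                quals=quals.copy(), mate_id=rid2, mate_orientation="FR",
            )
            r2 = SequencingRead(
                read_id=rid2, bases=CODE_BASE[r2_codes].tobytes().decode(),
                quals=quals.copy(), mate_id=rid1, mate_orientation="FR",
            )
            reads.append(r1)
            reads.append(r2)
            truth.reads[rid1] = (st.strain_id, pos1, str1)
            truth.reads[rid2] = (st.strain_id, pos2, str2)
    return reads, truth


def simulate_community(
    spec: CommunitySpec,
) -> Tuple[List[SequencingRead], List[StrainSpec], GroundTruth]:
    """Generate strains and reads for a :class:`CommunitySpec` (seeded)."""
    rng = np.random.default_rng(spec.seed)
    strains = make_strains(spec, rng)
    reads, truth = simulate_paired_reads(spec, strains, rng)
    return reads, strains, truth


def strain_of_read(read_id: str, truth: GroundTruth) -> Optional[str]:
    rec = truth.reads.get(read_id)
    return rec[0] if rec else None
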