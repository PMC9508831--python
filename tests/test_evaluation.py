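"""Assembly evaluation: alignment, genome fraction, N50/NGA50,
misassembly classification and error rates."""

import numpy as np
import pytest

from strainasm.dna import revcomp
from strainasm.evaluation import (
    ContigAlignment,
    EvalParams,
    align_contigs_to_truth,
    classify_misassemblies,
    error_and_n_rates,
    evaluate_assembly,
    genome_fraction,
    n50,
    nga50,
)
from strainasm.simulate import random_genome

from .oracles import n50_brute


def _block(cid, strain, c0, c1, r0, r1, strand="+", mism=0, indel=0, best=True):
    cols = (c1 - c0) + indel
    return ContigAlignment(
        contig_id=cid, ref_strain_id=strain, c_start=c0, c_end=c1,
        r_start=r0, r_end=r1, strand=strand, n_match=cols - mism - indel,
        n_mismatch=mism, n_indel_bases=indel, aligned_cols=cols, is_best=best,
    )


class TestAlign:
    def test_exact_substring_single_alignment(self, rng):
        g = random_genome(3000, rng)
        blocks = align_contigs_to_truth({"c": g[500:1600]}, {"sA": g})
        assert len(blocks) == 1
        b = blocks[0]
        assert (b.r_start, b.r_end) == (500, 1600)
        assert b.identity == 1.0

    def test_shared_region_aligns_to_both_strains(self, rng):
        g = random_genome(2000, rng)
        other = random_genome(500, rng) + g[400:1500] + random_genome(500, rng)
        blocks = align_contigs_to_truth({"c": g[500:1400]}, {"sA": g, "sB": other})
        strains = {b.ref_strain_id for b in blocks}
        assert strains == {"sA", "sB"}
        assert all(b.is_best for b in blocks)

    def test_random_contig_no_alignment(self, rng):
        g = random_genome(2000, rng)
        junk = random_genome(800, rng)
        assert align_contigs_to_truth({"c": junk}, {"sA": g}) == []

    def test_reverse_complement_contig_found(self, rng):
        g = random_genome(2000, rng)
        blocks = align_contigs_to_truth({"c": revcomp(g[300:1200])}, {"sA": g})
        assert len(blocks) == 1
        assert blocks[0].strand == "-"
        assert (blocks[0].r_start, blocks[0].r_end) == (300, 1200)

    def test_wrong_strain_placement_not_best(self, rng):
        g = random_genome(2000, rng)
        sib = list(g)
        for p in range(50, 2000, 100):
            sib[p] = "A" if g[p] != "A" else "G"
        sib = "".join(sib)
        blocks = align_contigs_to_truth({"c": g[200:1800]}, {"sA": g, "sB": sib})
        best = [b for b in blocks if b.is_best]
        assert {b.ref_strain_id for b in best} == {"sA"}


class TestGenomeFraction:
    def test_single_interval(self):
        truth = {"s": "A" * 1000}
        overall, per = genome_fraction([_block("c", "s", 0, 930, 0, 930)], truth)
        assert overall == pytest.approx(93.0)
        assert per["s"] == pytest.approx(93.0)

    def test_union_of_overlapping_intervals(self):
        truth = {"s": "A" * 1000}
        blocks = [
            _block("c1", "s", 0, 600, 0, 600),
            _block("c2", "s", 0, 600, 400, 1000),
        ]
        overall, _ = genome_fraction(blocks, truth)
        assert overall == pytest.approx(100.0)

    def test_no_alignments(self):
        overall, per = genome_fraction([], {"s": "A" * 100})
        assert overall == 0.0 and per["s"] == 0.0

    def test_monotone_under_added_contigs(self, rng):
        truth = {"s": "A" * 1000}
        blocks = []
        prev = 0.0
        for _ in range(20):
            r0 = int(rng.integers(0, 900))
            r1 = r0 + int(rng.integers(50, 100))
            blocks.append(_block(f"c{len(blocks)}", "s", 0, r1 - r0, r0, r1))
            cur, _ = genome_fraction(blocks, truth)
            assert cur >= prev
            prev = cur


class TestN50:
    def test_simple_case(self):
        assert n50([30, 10, 10]) == 30

    def test_matches_brute_force_on_random_sets(self, rng):
        for _ in range(50):
            lens = rng.integers(1, 500, size=int(rng.integers(1, 40))).tolist()
            assert n50(lens) == n50_brute(lens)

    def test_empty(self):
        assert n50([]) == 0

    def test_nga50_single_block(self):
        truth = {"s": "A" * 1000}
        assert nga50([_block("c", "s", 0, 600, 0, 600)], truth) == 600

    def test_nga50_undefined_below_half(self):
        truth = {"s": "A" * 1000}
        assert nga50([_block("c", "s", 0, 400, 0, 400)], truth) is None


class TestMisassembly:
    def test_large_reference_gap_triggers(self):
        blocks = [
            _block("c", "s", 0, 500, 0, 500),
            _block("c", "s", 500, 1000, 3000, 3500),
        ]
        flags, rate = classify_misassemblies(blocks)
        assert flags["c"] and rate == 100.0

    def test_strand_switch_triggers(self):
        blocks = [
            _block("c", "s", 0, 500, 0, 500, strand="+"),
            _block("c", "s", 500, 1000, 600, 1100, strand="-"),
        ]
        flags, _ = classify_misassemblies(blocks)
        assert flags["c"]

    def test_strain_switch_triggers(self):
        blocks = [
            _block("c", "sA", 0, 500, 0, 500),
            _block("c", "sB", 500, 1000, 500, 1000),
        ]
        flags, _ = classify_misassemblies(blocks)
        assert flags["c"]

    def test_single_block_clean(self):
        flags, rate = classify_misassemblies([_block("c", "s", 0, 900, 0, 900)])
        assert not flags["c"] and rate == 0.0

    def test_small_gap_tolerated(self):
        blocks = [
            _block("c", "s", 0, 500, 0, 500),
            _block("c", "s", 500, 1000, 900, 1400),  # gap 400 <= 1000
        ]
        flags, _ = classify_misassemblies(blocks)
        assert not flags["c"]

    def test_ambiguity_duplicates_not_adjacent_pairs(self):
        # same contig region placed on two strains: alternative placements,
        # not a split contig
        blocks = [
            _block("c", "sA", 0, 900, 0, 900),
            _block("c", "sB", 0, 900, 100, 1000),
        ]
        flags, _ = classify_misassemblies(blocks)
        assert not flags["c"]


class TestRates:
    def test_perfect_contigs(self):
        blocks = [_block("c", "s", 0, 1000, 0, 1000)]
        mism, indel, err, nrate = error_and_n_rates(blocks, {"c": "A" * 1000})
        assert (mism, indel, err, nrate) == (0.0, 0.0, 0.0, 0.0)

    def test_one_mismatch_in_1000(self):
        blocks = [_block("c", "s", 0, 1000, 0, 1000, mism=1)]
        mism, _, err, _ = error_and_n_rates(blocks, {"c": "A" * 1000})
        assert mism == pytest.approx(0.1)
        assert err == pytest.approx(0.1)

    def test_n_rate(self):
        contig = "A" * 495 + "N" * 5
        _, _, _, nrate = error_and_n_rates([], {"c": contig})
        assert nrate == pytest.approx(1.0)

    def test_error_is_sum_of_mismatch_and_indel(self):
        blocks = [_block("c", "s", 0, 1000, 0, 1000, mism=3, indel=2)]
        mism, indel, err, _ = error_and_n_rates(blocks, {"c": "A" * 1000})
        assert err == pytest.approx(mism + indel)


class TestEvaluateAssembly:
    def test_truth_as_assembly_scores_perfectly(self, rng):
        truth = {
            "sA": random_genome(3000, rng),
            "sB": random_genome(2500, rng),
        }
        m = evaluate_assembly(dict(truth), truth)
        assert m.genome_fraction == pytest.approx(100.0)
        assert m.identity == pytest.approx(100.0)
        assert m.error_rate == 0.0
        assert m.misassembled_contig_rate == 0.0
        assert m.n_rate == 0.0
        assert m.nga50 == m.n50

    def test_invariant_under_reverse_complement(self, rng):
        truth = {"sA": random_genome(4000, rng)}
        contigs = {"c1": truth["sA"][:2200], "c2": truth["sA"][1800:]}
        rc = {cid: revcomp(s) for cid, s in contigs.items()}
        m1 = evaluate_assembly(contigs, truth)
        m2 = evaluate_assembly(rc, truth)
        assert m1.genome_fraction == pytest.approx(m2.genome_fraction)
        assert m1.nga50 == m2.nga50
        assert m1.error_rate == pytest.approx(m2.error_rate)

    def test_short_contigs_excluded(self, rng):
        truth = {"sA": random_genome(2000, rng)}
        m = evaluate_assembly({"tiny": truth["sA"][:400]}, truth)
        assert m.n_contigs == 0 and m.genome_fraction == 0.0
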