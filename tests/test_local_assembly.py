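"""Within-cluster overlap-graph assembly: graph building, path merging,
consensus, and strain separation."""

import edlib
import numpy as np
import pytest

from strainasm.dna import revcomp
from strainasm.graph import linear_paths, transitive_reduce
from strainasm.io_qc import SequencingRead
from strainasm.local_assembly import (
    InconsistentOffsets,
    LocalParams,
    assemble_cluster,
    build_cluster_graph,
    consensus,
    merge_unambiguous_paths,
    polish_reads,
)
from strainasm.overlaps import OverlapParams, find_overlaps, score_overlap, filter_overlaps
from strainasm.simulate import CommunitySpec, simulate_community


def _read(rid, bases, q=30):
    return SequencingRead(rid, bases, np.full(len(bases), q, np.uint8))


def _tile(genome, read_len, step, prefix="t"):
    reads = []
    i = 0
    for start in range(0, len(genome) - read_len + 1, step):
        reads.append((f"{prefix}{i:03d}", genome[start : start + read_len]))
        i += 1
    return reads


class TestBuildClusterGraph:
    def test_tiling_gives_path_graph(self, make_seq):
        genome = make_seq(600)
        tiles = _tile(genome, 200, 100)  # consecutive overlap 100 = 0.5 * 200
        g = build_cluster_graph(
            tiles, LocalParams(local_min_ovlen_frac=0.5)
        )
        # 5 tiles -> path of 4 edges after transitive reduction
        transitive_reduce(g)
        assert len(g.nodes) == 5
        assert g.n_edges() == 4
        chains = linear_paths(g)
        assert len(chains) == 1 and len(chains[0]) == 5

    def test_snp_in_every_overlap_separates_haplotypes(self, make_seq):
        """Reads <= 100 bp whose every overlap spans a variant: one mismatch
        in a <= 99 bp overlap is below identity 0.99, so the two haplotypes
        form disjoint components."""
        hap_a = make_seq(400)
        # one substitution every 60 bp
        hap_b = list(hap_a)
        for pos in range(30, 400, 60):
            hap_b[pos] = "A" if hap_a[pos] != "A" else "G"
        hap_b = "".join(hap_b)
        reads = [(f"a{i}", s) for i, (_, s) in enumerate(_tile(hap_a, 100, 40))]
        reads += [(f"b{i}", s) for i, (_, s) in enumerate(_tile(hap_b, 100, 40))]
        g = build_cluster_graph(reads, LocalParams())
        for (u, targets) in g.out_edges.items():
            for v in targets:
                assert u[0] == v[0], f"cross-haplotype edge {u}->{v}"

    def test_non_overlapping_reads_edgeless(self, make_seq):
        g = build_cluster_graph(
            [("r1", make_seq(100)), ("r2", make_seq(100)), ("r3", make_seq(100))],
            LocalParams(),
        )
        assert g.n_edges() == 0


class TestMergePaths:
    def _graph(self, make_seq, branch=False):
        genome = make_seq(500)
        tiles = [("a", genome[0:200]), ("b", genome[100:300]), ("c", genome[200:400])]
        if branch:
            # d overlaps a exactly like b does -> out-branch at a
            alt = genome[100:280] + make_seq(120)
            tiles.append(("d", alt))
        return build_cluster_graph(tiles, LocalParams(local_min_ovlen_frac=0.5))

    def test_branchless_path_collapses(self, make_seq):
        g = self._graph(make_seq)
        srs, _ = merge_unambiguous_paths(g, min_tip_depth=1)
        assert len(srs) == 1
        assert {rid for rid, *_ in srs[0].support} == {"a", "b", "c"}

    def test_out_branch_blocks_merge(self, make_seq):
        g = self._graph(make_seq, branch=True)
        srs, _ = merge_unambiguous_paths(g, min_tip_depth=1)
        supports = [sorted(rid for rid, *_ in sr.support) for sr in srs]
        # a is not merged across its branch: no super-read contains both
        # b and d, and none contains a together with only one branch tip
        assert all(not ({"b", "d"} <= set(s)) for s in supports)
        assert len(srs) >= 2

    def test_empty_graph(self):
        from strainasm.graph import AssemblyGraph

        srs, simplified = merge_unambiguous_paths(AssemblyGraph())
        assert srs == [] and len(simplified.nodes) == 0


class TestConsensus:
    def test_identical_reads(self):
        r = _read("x", "ACGTACGTAC")
        sr = consensus([(r, 0, 0), (_read("y", "ACGTACGTAC"), 0, 0), (_read("z", "ACGTACGTAC"), 0, 0)])
        assert sr.sequence == "ACGTACGTAC"
        assert sr.depth_profile.tolist() == [3] * 10

    def test_quality_weighted_majority(self):
        base = "ACGTACGTACGTACGTACGT"
        off = base[:10] + "G" + base[11:]  # one disagreeing column, Q10
        reads = [
            (_read("a", base, q=40), 0, 0),
            (_read("b", base, q=40), 0, 0),
            (_read("c", off, q=10), 0, 0),
        ]
        sr = consensus(reads)
        assert sr.sequence == base

    def test_single_read_identity(self):
        r = _read("solo", "ACGTACGT")
        assert consensus([(r, 0, 0)]).sequence == "ACGTACGT"

    def test_orientation_flip(self):
        r = _read("f", "AACCGGTT")
        sr = consensus([(r, 0, 1)])
        assert sr.sequence == revcomp("AACCGGTT")

    def test_zero_coverage_column_rejected(self):
        with pytest.raises(InconsistentOffsets):
            consensus([(_read("a", "ACGT"), 0, 0), (_read("b", "ACGT"), 10, 0)])

    def test_disagreeing_placement_rejected(self, make_seq):
        s = make_seq(60)
        with pytest.raises(InconsistentOffsets):
            consensus(
                [(_read("a", s), 0, 0)] * 3 + [(_read("b", make_seq(60)), 0, 0)] * 1,
                min_node_identity=0.9,
            )


class TestAssembleCluster:
    def test_single_haplotype_exact_reconstruction(self):
        spec = CommunitySpec(
            n_species=1, strains_per_species=1, genome_len=2000,
            mean_coverage=20, read_len=250, subst_error=0.0, seed=3,
        )
        reads, strains, _ = simulate_community(spec)
        res = assemble_cluster(reads, LocalParams(), name_prefix="c0")
        assert len(res.contigs) == 1
        assert res.contigs[0].sequence in strains[0].genome

    def test_two_haplotypes_split_and_pure(self):
        """Two strains, SNPs spaced well below read length: one contig per
        haplotype, each containing its own variant pattern."""
        spec = CommunitySpec(
            n_species=1, strains_per_species=2, genome_len=3000,
            target_ani=0.987, min_snp_gap=50, max_snp_gap=100,
            mean_coverage=20, read_len=250, subst_error=0.0, seed=7,
        )
        reads, strains, truth = simulate_community(spec)
        res = assemble_cluster(reads, LocalParams(), name_prefix="c0")
        big = [c for c in res.contigs if len(c.sequence) >= 1000]
        assert len(big) == 2
        matched = set()
        for c in big:
            hits = [
                min(
                    edlib.align(c.sequence, st.genome, mode="HW", task="distance")["editDistance"],
                    edlib.align(revcomp(c.sequence), st.genome, mode="HW", task="distance")["editDistance"],
                )
                for st in strains
            ]
            assert min(hits) == 0, "contig must match one haplotype exactly"
            matched.add(int(np.argmin(hits)))
        assert matched == {0, 1}

    def test_tiny_cluster_skipped(self, make_seq):
        res = assemble_cluster(
            [("a", make_seq(250)), ("b", make_seq(250))], LocalParams()
        )
        assert res.contigs == [] and sorted(res.unplaced) == ["a", "b"]

    def test_read_conservation(self):
        spec = CommunitySpec(
            n_species=1, strains_per_species=1, genome_len=1500,
            mean_coverage=15, read_len=250, subst_error=0.0, seed=9,
        )
        reads, _, _ = simulate_community(spec)
        res = assemble_cluster(reads, LocalParams(), name_prefix="c0")
        placed = {rid for c in res.contigs for rid, *_ in c.support}
        assert placed | set(res.unplaced) == {r.read_id for r in reads}

    def test_consensus_corrects_errors(self):
        """At 0.5% substitution error and 15x coverage the consensus contig
        matches its haplotype at >= 99.9% identity."""
        spec = CommunitySpec(
            n_species=1, strains_per_species=1, genome_len=3000,
            mean_coverage=15, read_len=250, subst_error=0.005, seed=13,
        )
        reads, strains, _ = simulate_community(spec)
        store = {r.read_id: r for r in reads}
        seqs = {r.read_id: r.bases for r in reads}
        op = OverlapParams()
        scored = list(
            filter_overlaps(
                (
                    score_overlap(h, len(seqs[h.id_a]), len(seqs[h.id_b]), op)
                    for h in find_overlaps(seqs, op)
                ),
                op,
            )
        )
        polish_reads(store, scored)
        res = assemble_cluster(reads, LocalParams(), name_prefix="c0")
        assert res.contigs
        total_cols = total_ed = 0
        for c in res.contigs:
            ed = min(
                edlib.align(c.sequence, strains[0].genome, mode="HW", task="distance")["editDistance"],
                edlib.align(revcomp(c.sequence), strains[0].genome, mode="HW", task="distance")["editDistance"],
            )
            total_ed += ed
            total_cols += len(c.sequence)
        assert 1 - total_ed / total_cols >= 0.999


class TestPolish:
    def test_errors_corrected_variants_kept(self):
        spec = CommunitySpec(
            n_species=1, strains_per_species=2, genome_len=4000,
            target_ani=0.99, min_snp_gap=50, max_snp_gap=200,
            mean_coverage=20, read_len=250, subst_error=0.004, seed=21,
        )
        reads, strains, truth = simulate_community(spec)
        store = {r.read_id: r for r in reads}
        seqs = {r.read_id: r.bases for r in reads}
        op = OverlapParams()
        scored = list(
            filter_overlaps(
                (
                    score_overlap(h, len(seqs[h.id_a]), len(seqs[h.id_b]), op)
                    for h in find_overlaps(seqs, op)
                ),
                op,
            )
        )

        def mismatches():
            tot = 0
            for r in reads:
                sid, pos, strand = truth.reads[r.read_id]
                seg = truth.genomes[sid][pos : pos + len(r.bases)]
                s = r.bases if strand == "+" else revcomp(r.bases)
                tot += sum(1 for x, y in zip(s, seg) if x != y)
            return tot

        before = mismatches()
        n = polish_reads(store, scored)
        after = mismatches()
        assert n > 0
        assert after < 0.05 * before  # errors removed, variants untouched
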