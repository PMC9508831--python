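"""Master-graph construction, transitive reduction, branch detection and
unique-path extension."""

import numpy as np
import pytest

from strainasm.dna import revcomp
from strainasm.graph import AssemblyGraph, GEdge, Node, transitive_reduce
from strainasm.global_assembly import (
    GlobalParams,
    build_master_graph,
    detect_branches,
    extend_unique_paths,
    global_assemble,
    write_assembly,
)
from strainasm.io_qc import SequencingRead, read_fasta

from .oracles import brute_force_transitive_edges


def _mutate(seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = "A" if seq[p] != "A" else "G"
    return "".join(out)


class TestBuildMasterGraph:
    def test_qualifying_overlap_makes_edge(self, make_seq):
        g = make_seq(1000)
        a, b = g[:600], g[450:1000]  # overlap 150, identity 1.0
        mg = build_master_graph({"a": a, "b": b})
        assert mg.n_edges() == 1
        (e,) = [e for d in mg.out_edges.values() for e in d.values()]
        assert e.ovlen == 150

    def test_exactly_100_bp_rejected(self, make_seq):
        g = make_seq(1000)
        a, b = g[:600], g[500:1000]  # overlap exactly 100: ">100 bp" strict
        mg = build_master_graph({"a": a, "b": b})
        assert mg.n_edges() == 0

    def test_101_bp_accepted(self, make_seq):
        g = make_seq(1000)
        mg = build_master_graph({"a": g[:600], "b": g[499:1000]})
        assert mg.n_edges() == 1

    def test_low_identity_rejected(self, make_seq):
        g = make_seq(1000)
        a = g[:600]
        b_seq = g[450:1000]
        # 3 substitutions inside the 150 bp overlap: identity 147/150 = 0.98
        b = _mutate(b_seq, [10, 60, 110])
        mg = build_master_graph({"a": a, "b": b})
        assert mg.n_edges() == 0

    def test_sibling_strain_not_swallowed_as_containment(self, make_seq):
        """A near-identical (99%) sibling must not be recorded as a
        contained duplicate."""
        g = make_seq(800)
        sib = _mutate(g, list(range(40, 800, 80)))[50:750]
        mg = build_master_graph({"long": g, "sib": sib})
        assert "sib" not in mg.contained

    def test_true_duplicate_contained(self, make_seq):
        g = make_seq(800)
        mg = build_master_graph({"long": g, "dup": g[100:700]})
        assert "dup" in mg.contained


class TestTransitiveReduce:
    def _graph(self, edges):
        g = AssemblyGraph()
        ids = {x for e in edges for x in e[:2]}
        for nid in ids:
            g.nodes[nid] = Node(nid, "A" * 10, np.full(10, 30, np.uint8), [])
        for u, v, off in edges:
            g.add_edge(GEdge(u=u, v=v, offset=off, ovlen=100, identity=1.0, score=1.0))
        return g

    def test_triangle_reduced(self):
        g = self._graph([("a", "b", 100), ("b", "c", 120), ("a", "c", 220)])
        transitive_reduce(g)
        assert g.n_edges() == 2
        assert "c" not in g.outs("a")

    def test_plain_path_unchanged(self):
        g = self._graph([("a", "b", 100), ("b", "c", 120)])
        transitive_reduce(g)
        assert g.n_edges() == 2

    def test_inconsistent_layout_kept(self):
        # direct edge disagrees with the two-step path by 50 bp
        g = self._graph([("a", "b", 100), ("b", "c", 120), ("a", "c", 270)])
        transitive_reduce(g)
        assert "c" in g.outs("a")

    def test_matches_brute_force_on_random_layouts(self, rng):
        """Reduction agrees with an all-triples oracle on 100 random
        DAG-like layouts of up to 30 vertices."""
        for trial in range(100):
            n = int(rng.integers(3, 31))
            ids = [f"v{i:02d}" for i in range(n)]
            offsets = np.sort(rng.integers(0, 2000, size=n))
            edges = {}
            for i in range(n):
                for j in range(i + 1, n):
                    gap = int(offsets[j] - offsets[i])
                    if 0 < gap and rng.random() < 0.4:
                        edges[(ids[i], ids[j])] = gap
            g = self._graph([(u, v, off) for (u, v), off in edges.items()])
            expected_removed = brute_force_transitive_edges(edges)
            transitive_reduce(g)
            got_removed = {
                (u, v)
                for (u, v) in edges
                if v not in g.outs(u)
            }
            assert got_removed == expected_removed, f"trial {trial}"


def _paired_reads_over(seq, n, rng, insert=400, rl=120, prefix="p"):
    reads = []
    for k in range(n):
        start = int(rng.integers(0, max(1, len(seq) - insert)))
        frag = seq[start : start + insert]
        r1 = SequencingRead(f"{prefix}{k}/1", frag[:rl], np.full(rl, 30, np.uint8))
        r2 = SequencingRead(
            f"{prefix}{k}/2", revcomp(frag[-rl:]), np.full(rl, 30, np.uint8)
        )
        r1.mate_id, r2.mate_id = r2.read_id, r1.read_id
        reads += [r1, r2]
    return reads


class TestDetectBranches:
    def _fork(self, make_seq):
        """u with two possible successors v, w sharing their prefix with u's
        suffix; only the u-v junction is covered by reads."""
        u_part = make_seq(600)
        shared = make_seq(150)
        v_tail = make_seq(500)
        w_tail = make_seq(500)
        u = u_part + shared
        v = shared + v_tail
        w = shared + w_tail
        return u, v, w, u_part + shared + v_tail

    def test_unsupported_edge_pruned(self, make_seq, rng):
        u, v, w, true_path = self._fork(make_seq)
        mg = build_master_graph({"u": u, "v": v, "w": w})
        assert len(mg.outs("u")) == 2
        reads = _paired_reads_over(true_path, 60, rng)
        detect_branches(mg, reads, GlobalParams())
        assert list(mg.outs("u")) == ["v"]
        assert mg.branch_flags["u"] == "clean"

    def test_both_supported_flags_branched(self, make_seq, rng):
        u, v, w, _ = self._fork(make_seq)
        mg = build_master_graph({"u": u, "v": v, "w": w})
        reads = _paired_reads_over(u + v[150:], 60, rng, prefix="pv")
        reads += _paired_reads_over(u + w[150:], 60, rng, prefix="pw")
        detect_branches(mg, reads, GlobalParams())
        assert set(mg.outs("u")) == {"v", "w"}
        assert mg.branch_flags["u"] == "branched"

    def test_linear_supported_graph_all_clean(self, make_seq, rng):
        g = make_seq(1500)
        mg = build_master_graph({"a": g[:700], "b": g[500:1100], "c": g[900:1500]})
        reads = _paired_reads_over(g, 80, rng)
        detect_branches(mg, reads, GlobalParams())
        assert all(f == "clean" for f in mg.branch_flags.values())
        assert mg.n_edges() == 2

    def test_without_reads_degrees_decide(self, make_seq):
        u, v, w, _ = self._fork(make_seq)
        mg = build_master_graph({"u": u, "v": v, "w": w})
        detect_branches(mg, None, GlobalParams())
        assert mg.branch_flags["u"] == "branched"


class TestExtend:
    def test_clean_path_merges_with_layout_arithmetic(self, make_seq):
        g = make_seq(2000)
        a, b, c = g[:800], g[650:1400], g[1200:2000]  # overlaps 150, 200
        mg = build_master_graph({"a": a, "b": b, "c": c})
        detect_branches(mg, None, GlobalParams())
        merged, records = extend_unique_paths(mg)
        assert len(merged) == 1
        assert len(merged[0].sequence) == 800 + 750 + 800 - 150 - 200
        assert merged[0].sequence == g

    def test_branch_stops_extension(self, make_seq, rng):
        u_part, shared = make_seq(600), make_seq(150)
        u = u_part + shared
        v = shared + make_seq(500)
        w = shared + make_seq(500)
        mg = build_master_graph({"u": u, "v": v, "w": w})
        reads = _paired_reads_over(u + v[150:], 60, rng, prefix="pv")
        reads += _paired_reads_over(u + w[150:], 60, rng, prefix="pw")
        detect_branches(mg, reads, GlobalParams())
        merged, _ = extend_unique_paths(mg)
        assert len(merged) == 3  # branched vertex blocks all merging

    def test_single_contig_passthrough(self, make_seq):
        mg = build_master_graph({"only": make_seq(700)})
        detect_branches(mg, None, GlobalParams())
        merged, records = extend_unique_paths(mg)
        assert len(merged) == 1 and merged[0].sequence == mg.nodes["only"].seq


class TestGlobalAssemble:
    def test_every_contig_accounted_for(self, make_seq, rng):
        g = make_seq(2400)
        contigs = {
            "cluster0_ctg0": g[:900],
            "cluster1_ctg0": g[700:1600],
            "cluster2_ctg0": g[1400:2400],
            "cluster0_ctg1": g[300:800],  # contained duplicate
        }
        reads = _paired_reads_over(g, 120, rng)
        res = global_assemble(contigs, reads, GlobalParams())
        assert res.master_contigs
        accounted = set()
        for mc in res.master_contigs:
            accounted |= {s[0] for s in mc.source_contigs}
        assert ("cluster0_ctg0" in accounted and "cluster2_ctg0" in accounted)
        total = sum(len(m.sequence) for m in res.master_contigs)
        assert total >= 2300  # nothing substantial lost

    def test_write_assembly_round_trip(self, make_seq, tmp_path):
        res = global_assemble({"cluster0_ctg0": make_seq(700)}, None, GlobalParams())
        fasta = tmp_path / "out.fasta"
        report = write_assembly(res.master_contigs, fasta)
        back = read_fasta(fasta)
        assert [seq for _, seq in back] == [m.sequence for m in res.master_contigs]
        lines = report.read_text().splitlines()
        assert lines[0].startswith("contig\t")
        assert len(lines) == 1 + len(res.master_contigs)

    def test_empty_assembly(self, tmp_path):
        fasta = tmp_path / "empty.fasta"
        report = write_assembly([], fasta)
        assert read_fasta(fasta) == []
        assert len(report.read_text().splitlines()) == 1
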