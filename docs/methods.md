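# Methods

`strainasm` assembles short-read metagenomes at strain resolution with an
overlap-graph (OLC) workflow, following a divide-and-conquer design:
reads are first partitioned into small species-coherent clusters, each
cluster is assembled locally into strain-aware, error-corrected contigs,
and the cluster contigs are finally extended across cluster boundaries on
a master overlap graph. De Bruijn graph assemblers cut reads into k-mers
and thereby lose the linkage between co-occurring variants; full-length
read overlaps preserve it, which is what makes strain separation
possible.

## Overlap detection and scoring

All-vs-all suffix–prefix (dovetail) overlaps are found by canonical
minimizer seeding (k = 15, window 5 by default) followed by banded
end-to-end verification with edlib. Each candidate pair votes for a
diagonal (the implied relative offset); the dominant diagonal defines the
overlap segments, which are aligned exactly. A hit is dovetail when the
alignment reaches an end of each sequence within a 5 bp overhang
tolerance; containments are recorded separately (a contained sequence
cannot extend a layout). Per pair only the best-supported relative
orientation is kept, and output is deterministically ordered.

An overlap with identity *i* (matching columns / alignment columns),
length *o*, between sequences of lengths *r₁*, *r₂*, is scored

    D = 0.9·i + 0.1·o / ((r₁ + r₂)/2)

so that D ∈ [0, 1] balances overlap quality against overlap length.
Overlaps shorter than 30 bp or below identity 0.9 are discarded
(boundary values pass). These are the clustering-stage settings; the
assembly stages are stricter (below).

## Read clustering

Retained overlaps are sorted best-first (descending D; ties by identity,
length, then ids) and processed in one pass over a path-compressed
union-find: each overlap merges the clusters of its two reads unless the
union would exceed the cluster-size cap (default 3000 reads). Sorting
dominates the cost (O(n log n + n)). The cap is what makes the
best-first order meaningful — uncapped single linkage would simply
return the connected components of the overlap graph. Clusters below
3 reads are routed to an unclustered pool and reported.

## Read polishing

Before local assembly, reads are error-corrected from the overlap pileup
already computed for clustering: every partner's bases are stacked onto
the read along the overlap, and a base is replaced only when the winning
alternative holds ≥ 80 % of the column's votes (≥ 3 votes absolute).
Because the permissive 0.9 identity cut admits overlaps between sibling
strains, true strain variants sit near 50/50 in the pileup and are never
touched, while isolated sequencing errors are outvoted. Measured on
simulated data this removes > 95 % of substitution errors and leaves the
mismatch count of reads against their own strain essentially unchanged.
Only substitution-style (equal-span) overlaps contribute; the step is a
no-op for indel-dominated data.

## Local (within-cluster) assembly

Each cluster is assembled by iterating three steps until no merge
happens (at most 20 iterations, with the vertex count strictly
decreasing on every productive iteration):

1. **Graph building.** Dovetail overlaps among the current sequences are
   recomputed at the local thresholds. Orientations are normalized per
   component by union-find with parity, processing overlaps best-first;
   an overlap whose orientation constraint conflicts is dropped.
   Transitive edges are removed (Myers-style, with a positional
   tolerance of 3 bp + 2 %).
2. **Branch-free path merging.** Maximal paths whose interior vertices
   have in- and out-degree ≤ 1 are collapsed; branching vertices
   terminate paths; contained sequences contribute their read support to
   their container.
3. **Consensus.** Reads on a path are stacked at their layout offsets
   and a per-column, Phred-weighted majority is called (ties toward the
   base carried by the highest-quality single read, then alphabetical).
   A placement that agrees with the consensus below 0.9, or a
   zero-coverage column, rejects the whole path and its reads stay
   unmerged. Consensus tips supported by fewer than 2 reads are trimmed
   (a once-covered base cannot be error-checked).

Two numerical choices make this strain-separating in practice, and both
were driven by measurements on simulated two-strain data:

* **Fractional minimum overlap.** A layout edge must span at least
  0.6 × min(len, 300 bp) in addition to the absolute 30 bp floor. With a
  30 bp floor alone, every variant-free gap between strain-distinguishing
  SNPs admits a cross-strain micro-overlap, and branch-stopping then
  fragments contigs to roughly the SNP spacing. Requiring a substantial
  fraction of the read length is standard practice in short-read OLC
  layout.
* **Zero-mismatch edges.** After polishing, local edges (and
  containments) tolerate 0 mismatching columns. At 99 % strain identity
  an identity threshold of 0.99 alone still admits overlaps spanning one
  or two variants (e.g. 2 mismatches in a 250 bp overlap), and transitive
  reduction then braids the two strains into a single chain that
  consensus collapses into one sequence. With error-corrected reads, a
  surviving disagreement is evidence of a linked variant, not of a
  sequencing error, so it must break the edge. Same-strain connectivity
  is preserved because polishing leaves same-strain overlaps essentially
  perfect.

Contigs shorter than 300 bp are not emitted; every input read is either
in some contig's support or reported unplaced.

## Global (master-graph) assembly

Cluster contigs are collected into one overlap graph; an edge requires
an overlap strictly longer than 100 bp at identity at least 0.99. A
contig is set aside as contained only when it matches its container with
zero mismatches — at 99 % sibling-strain identity, the 0.99 cut alone
would classify one strain's contig as a redundant copy of its sibling
and delete it. After transitive reduction, branches are detected from
the reads:

* a read supports an edge (u, v) when it aligns across the junction
  (covering ≥ 15 bp of u-only and of v-only sequence) at identity
  ≥ 0.98;
* a read pair supports the edge when the forward mate maps near u's 3'
  end, the reverse mate maps on v, and the implied fragment crosses the
  junction within a 2 kb insert bound;
* in both cases the support is **discriminating**: it counts only if the
  read (or each mate) fits that junction strictly better than every
  sibling junction sharing u or v. Reads from regions where the strains
  are identical are ambiguous and validate no branch.

Edges with fewer than 3 discriminating supporters are pruned; a vertex
with ≥ 2 supported edges on one side is flagged branched. Contigs are
merged along maximal paths of clean vertices only — extension stops at
every branch, which is what prevents chimeras — with overlap
disagreements resolved toward the deeper-supported contig. The loop
(build → reduce → detect branches → extend) repeats until a pass makes
no merge (≤ 8 rounds). Cycles on a merge path are broken at the
lowest-scoring edge. Without read data, branch flags fall back to vertex
degrees.

## Quality control

Reads are preprocessed by the usual short-read rules: terminal bases
with Phred < 20 are clipped in a single pass from each end, exact
adapter matches are removed from the 3' end, and only reads strictly
longer than 70 bp are kept. An optional stricter floor (e.g. 150 bp)
exists for pre-trimmed archives, since reads too short to link
co-occurring variants cannot contribute to strain-aware assembly. In the
self-overlapping part of a pair, a mismatched base whose mate's Phred is
at least 20 higher is replaced by the mate's base and quality. The QC
report reconciles exactly (kept + dropped = input).

## Synthetic strain communities

The simulator generates, per species, an i.i.d.-uniform ancestor genome
and derives sibling strains by placing substitutions until the requested
ANI is met: the substitution count is round((1−ANI)·len) and gaps
between substitutions are drawn uniformly on the widest interval centred
on the required mean gap that stays inside the configured
[min_gap, max_gap]. (When the ANI and the gap bounds are jointly
infeasible — e.g. 1 % divergence forces a ~100 bp mean gap regardless of
a 400 bp upper bound — the ANI wins, since it is the strain-identity
knob; the realized gaps still respect both bounds.) Abundances follow
LogNormal(0, σ) normalized to 1 (σ = 0 gives uniform coverage; only σ is
exposed because the scale cancels). Paired-end FR reads are placed
uniformly within the linear genomes (never across ends), with Gaussian
insert lengths and i.i.d. substitution errors at a configurable rate;
Phred values encode that rate. Every read carries one ground-truth
record (strain, position, strand).

Defaults encode the reference study conditions used by the acceptance
run: 4 species × 2 strains, 100 kb genomes, sibling ANI 99 % with SNP
gaps in [50, 400] bp, uniform 20× per-strain coverage, 2 × 250 bp reads
with a 600 ± 60 bp insert, and 0.3 % substitution error. 100 kb genomes
(rather than full bacterial chromosomes) keep a complete run on one CPU
in minutes while preserving the quantity that matters — thousands of
inter-strain SNPs at realistic spacing. What this generator does **not**
emulate: repeats and mobile elements, GC/coverage bias, indel errors
(togglable in principle but off by default so identity arithmetic stays
exact), and uneven within-genome coverage. Passing tests therefore
demonstrate the method's strain-separation logic, not robustness to
repeat-rich real genomes.

## Evaluation

Contigs (≥ 500 bp by default; the cutoff is exposed) are aligned to
every strain genome by exact k-mer seeding (k = 21, both strands),
diagonal-band clustering, and edlib verification; blocks ≥ 65 bp at
identity ≥ 0.95 are retained. Per contig region, blocks within 0.9999 of
the best score are marked near-best; all metrics use near-best blocks,
so a contig from a region where two strains are identical counts for
both strains, while a clearly sub-optimal wrong-strain placement counts
for neither. Genome fraction is the percentage of truth bases covered by
any block (per strain and overall — the central strain-awareness
measure). N50 follows the standard definition; NGA50 is computed over
aligned block lengths against the total truth length and is undefined
(reported "-") when blocks cover less than half of it. A contig is
misassembled when two adjacent blocks (ordered by contig coordinate,
alternative placements of the same region collapsed) leave a reference
gap or overlap > 1 kb, switch strands, or switch strains. The error rate
is the sum of mismatch and indel rates per aligned column; the N rate is
ambiguous bases over contig bases. This is a self-contained
re-implementation of the stated criteria, not a QUAST wrapper; small
numeric drift against QUAST's alignment engine is expected.

## Determinism and parallelism

All randomness flows from one seed. Every stage orders its output
deterministically (sorted ids, explicit tie-breaks), clusters are
assembled independently and merged in cluster-id order, so the final
FASTA is byte-identical across thread counts and repeated runs. Stage
outputs are written under the work directory with a configuration-hash
marker and are reused on resume.

## Problem sizes

The default test and acceptance configuration (64 000 reads, 800 kb of
truth sequence) runs the full pipeline in about 6 minutes and ~2 GB of
memory on one CPU; the unit-test communities are 10–100× smaller and run
in seconds.

## Known limitations

* Strains below the coverage needed for discriminating junction support
  (< ~10×) fragment at every shared region longer than the insert size.
* Shared regions longer than the insert size cannot be phased and
  legitimately terminate contigs.
* The zero-mismatch local edge rule assumes substitution-dominated
  errors and effective polishing; indel-rich data (e.g. uncorrected
  long reads) would need a relaxed budget.
* Containment folding attaches contained reads to a single container;
  for reads from regions shared between strains the attachment is
  arbitrary among equally good containers.
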