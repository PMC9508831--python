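# strainasm

Strain-aware assembly of short-read metagenomes on overlap graphs.

Conspecific bacterial strains can differ by small numbers of linked
variants yet behave very differently (virulence, resistance, metabolic
capacity). De Bruijn graph metagenome assemblers cut reads into k-mers
and lose the linkage between co-occurring variants, so they typically
collapse strains into one species consensus. `strainasm` keeps reads
intact and assembles on overlap graphs in three stages:

1. **Clustering.** All-vs-all suffix–prefix read overlaps are scored by

       D = 0.9·i + 0.1·o / ((r₁+r₂)/2)

   where *i* is the overlap identity, *o* its length, and *r₁*, *r₂* the
   read lengths (overlaps with o < 30 bp or i < 0.9 are neglected).
   Reads are merged into small species-coherent clusters by one-pass,
   best-first single-linkage with a cluster-size cap.
2. **Local assembly.** Each cluster is assembled on an iterated overlap
   graph: pileup-polished reads, mismatch-free dovetail edges,
   transitive reduction, branch-free path merging, quality-weighted
   consensus — producing strain-aware, error-corrected cluster contigs.
3. **Global assembly.** Cluster contigs form a master overlap graph
   (edges: overlap > 100 bp, identity ≥ 0.99). After transitive-edge
   removal, junctions are validated by reads and read pairs that
   discriminate between sibling branches; contigs are merged only along
   unique (branch-free) paths, iterating until nothing changes. The
   resulting master contigs are the final output.

The package also ships a synthetic strain-community simulator
(multi-species, controlled strain ANI, log-normal abundances, paired-end
reads with substitution errors, full per-read ground truth) and a
self-contained evaluator (genome fraction per strain, N50/NGA50, error
and N rates, misassembly classification), so the whole method is
testable without external data. See `docs/methods.md` for the model,
parameter rationale and limitations.

Intended users: developers of strain-resolved metagenomics methods and
bioinformaticians who want a transparent, dependency-light OLC baseline
on simulated or small real datasets.

## Worked example

Simulate two species with two strains each (20 kb genomes, 99 % strain
ANI, 20× per strain, 2×250 bp reads, 0.3 % substitution error), run the
pipeline, and score the result against the truth genomes:

```python
import json, tempfile
from strainasm.simulate import CommunitySpec, simulate_community
from strainasm.pipeline import PipelineConfig, run_pipeline
from strainasm.evaluation import EvalParams, evaluate_assembly
from strainasm.io_qc import read_fasta

spec = CommunitySpec(n_species=2, strains_per_species=2, genome_len=20_000, seed=11)
reads, strains, truth = simulate_community(spec)
with tempfile.TemporaryDirectory() as td:
    summary = run_pipeline(PipelineConfig(workdir=td, seed=11), reads=reads)
    contigs = dict(read_fasta(summary.final_fasta))

metrics = evaluate_assembly(contigs, truth.genomes, EvalParams())
print(f"{len(reads)} reads -> {len(contigs)} master contigs")
print(json.dumps(metrics.as_dict(), indent=2))
```

Output:

```
6400 reads -> 25 master contigs
{
  "genome_fraction": 99.161,
  "identity": 99.999,
  "total_len": 82492,
  "n_contigs": 24,
  "n50": 4719,
  "nga50": 5259,
  "misassembled_contig_rate": 0.0,
  "error_rate": 0.0012,
  "n_rate": 0.0,
  "genome_fraction[sp0_strain0]": 99.38,
  "genome_fraction[sp0_strain1]": 98.2,
  "genome_fraction[sp1_strain0]": 99.46,
  "genome_fraction[sp1_strain1]": 99.605
}
```

Genome fraction near 100 % **per strain** is the point: all four strain
genomes are reconstructed separately (a strain-unaware assembler would
cover only ~50 % of this concatenated reference, one consensus per
species), with zero misassembled contigs and an error rate of ~1 in
10⁵ columns. `total_len` ≈ the 80 kb of truth sequence confirms both
haplotypes are present rather than one collapsed copy.

## Command line

The same stages are available as a CLI for shell use:

```bash
strainasm simulate --seed 1 --out sim/
strainasm run --reads sim/reads_1.fastq --reads2 sim/reads_2.fastq --out work/
strainasm evaluate work/master_contigs.fasta sim/truth_genomes.fasta
```

plus `qc`, `overlap` (PAF out), `cluster`, `local-assemble` and
`global-assemble` subcommands for running stages individually.

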