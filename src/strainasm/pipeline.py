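"""End-to-end pipeline: QC -> overlaps -> clustering -> local -> global.

One :class:`PipelineConfig` carries every stage parameter; a run writes
its artifacts under a work directory and can resume, skipping stages whose
marker files match the current configuration hash.  Cluster-level
parallelism is available (clusters are independent); results are merged
in cluster-id order so the output is identical regardless of thread
count.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, fields
from multiprocessing import get_context
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .clustering import (
    DEFAULT_MAX_CLUSTER,
    DEFAULT_MIN_CLUSTER,
    emit_cluster_reads,
    single_linkage_cluster,
    sort_by_score,
)
from .evaluation import EvalParams
from .global_assembly import GlobalParams, global_assemble, write_assembly
from .io_qc import (
    QCParams,
    SequencingRead,
    parse_fastq,
    run_qc,
    write_fasta,
    write_fastq,
)
from .local_assembly import LocalParams, SuperRead, assemble_cluster, polish_reads
from .overlaps import OverlapParams, filter_overlaps, find_overlaps, score_overlap

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline parameters in one (de)serializable record."""

    qc: QCParams = field(default_factory=QCParams)
    overlap: OverlapParams = field(default_factory=OverlapParams)
    local: LocalParams = field(default_factory=LocalParams)
    glob: GlobalParams = field(default_factory=GlobalParams)
    eval: EvalParams = field(default_factory=EvalParams)
    max_cluster_size: int = DEFAULT_MAX_CLUSTER
    min_cluster_size: int = DEFAULT_MIN_CLUSTER
    seed: int = 1
    threads: int = 1
    workdir: str = "strainasm_work"

    def to_flat(self) -> Dict[str, object]:
        flat: Dict[str, object] = {}
        for f in fields(self):
            val = getattr(self, f.name)
            if dataclasses.is_dataclass(val):
                for sf in fields(val):
                    sval = getattr(val, sf.name)
                    if isinstance(sval, tuple):
                        sval = ",".join(sval)
                    flat[f"{f.name}.{sf.name}"] = sval
            else:
                flat[f.name] = val
        return flat

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: v for k, v in self.to_flat().items() if k not in ("threads", "workdir")},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for key, val in sorted(self.to_flat().items()):
                fh.write(f"{key}={val}\n")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        cfg = cls()
        known = cfg.to_flat()
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value")
                key, _, raw = line.partition("=")
                key = key.strip()
                raw = raw.strip()
                if key not in known:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                target: object = cfg
                *parents, leaf = key.split(".")
                for p in parents:
                    target = getattr(target, p)
                current = getattr(target, leaf)
                if isinstance(current, bool):
                    val: object = raw.lower() in ("1", "true", "yes")
                elif isinstance(current, int):
                    val = int(raw)
                elif isinstance(current, float):
                    val = float(raw)
                elif isinstance(current, tuple):
                    val = tuple(x for x in raw.split(",") if x)
                elif current is None:
                    val = None if raw in ("", "None") else int(raw)
                else:
                    val = raw
                setattr(target, leaf, val)
        return cfg


@dataclass
class PipelineSummary:
    n_reads_in: int = 0
    n_reads_qc: int = 0
    n_overlaps: int = 0
    n_clusters: int = 0
    n_cluster_contigs: int = 0
    n_master_contigs: int = 0
    final_fasta: Optional[Path] = None
    stage_seconds: Dict[str, float] = field(default_factory=dict)


def _stage_done(workdir: Path, stage: str, cfg_hash: str) -> bool:
    marker = workdir / f"{stage}.done.json"
    if not marker.exists():
        return False
    try:
        data = json.loads(marker.read_text())
    except json.JSONDecodeError as exc:
        raise RuntimeError(f"stage {stage}: corrupt marker file {marker}") from exc
    return data.get("config_hash") == cfg_hash


def _mark_done(workdir: Path, stage: str, cfg_hash: str, **extra) -> None:
    (workdir / f"{stage}.done.json").write_text(
        json.dumps({"config_hash": cfg_hash, **extra}, sort_keys=True)
    )


def _assemble_one(args: Tuple[int, List[SequencingRead], LocalParams]):
    cid, reads, params = args
    return cid, assemble_cluster(reads, params, name_prefix=f"cluster{cid}")


def run_pipeline(
    config: PipelineConfig,
    reads: Optional[Sequence[SequencingRead]] = None,
    reads1: Optional[str | Path] = None,
    reads2: Optional[str | Path] = None,
) -> PipelineSummary:
    """Run (or resume) the full assembly pipeline.

    Input is either an in-memory read list or FASTQ path(s).  Stage
    outputs land under ``config.workdir``; a stage is skipped on resume
    when its marker matches the configuration hash and its artifacts are
    present.
    """
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    config.save(workdir / "config.txt")
    summary = PipelineSummary()

    # --- stage 1: quality control ---------------------------------------
    t0 = time.perf_counter()
    qc_fastq = workdir / "qc_reads.fastq"
    if _stage_done(workdir, "qc", cfg_hash) and qc_fastq.exists():
        kept = list(parse_fastq(qc_fastq))
        id_map: Dict[str, Optional[str]] = json.loads(
            (workdir / "qc_mates.json").read_text()
        )
        for r in kept:
            r.mate_id = id_map.get(r.read_id)
        logger.info("qc: resumed (%d reads)", len(kept))
    else:
        if reads is None:
            if reads1 is None:
                raise ValueError("either reads or reads1 must be provided")
            reads = list(parse_fastq(reads1, paired_with=reads2))
        summary.n_reads_in = len(reads)
        kept, report = run_qc(reads, config.qc)
        write_fastq(kept, qc_fastq)
        (workdir / "qc_mates.json").write_text(
            json.dumps({r.read_id: r.mate_id for r in kept})
        )
        (workdir / "qc_report.json").write_text(json.dumps(dataclasses.asdict(report)))
        _mark_done(workdir, "qc", cfg_hash, n_kept=len(kept))
        logger.info(
            "qc: %d/%d reads kept, %d bases trimmed, %d corrected",
            report.n_kept, report.n_input, report.n_bases_trimmed,
            report.n_bases_corrected,
        )
    summary.n_reads_qc = len(kept)
    summary.stage_seconds["qc"] = time.perf_counter() - t0

    # --- stage 2+3: overlaps and clustering -----------------------------
    t0 = time.perf_counter()
    clusters_dir = workdir / "clusters"
    read_store = {r.read_id: r for r in kept}
    if _stage_done(workdir, "cluster", cfg_hash) and (clusters_dir / "manifest.tsv").exists():
        logger.info("cluster: resumed")
    else:
        seq_map = {r.read_id: r.bases for r in kept}
        hits = find_overlaps(seq_map, config.overlap)
        scored = list(
            filter_overlaps(
                (
                    score_overlap(
                        h, len(seq_map[h.id_a]), len(seq_map[h.id_b]), config.overlap
                    )
                    for h in hits
                ),
                config.overlap,
            )
        )
        summary.n_overlaps = len(scored)
        n_polished = polish_reads(read_store, scored)
        logger.info("polish: %d bases corrected from overlap pileups", n_polished)
        ordered = sort_by_score(scored)
        clusters = single_linkage_cluster(
            ordered, config.max_cluster_size, all_read_ids=seq_map.keys()
        )
        emit_cluster_reads(clusters, read_store, clusters_dir, config.min_cluster_size)
        _mark_done(
            workdir, "cluster", cfg_hash,
            n_overlaps=len(scored), n_clusters=len(clusters.clusters),
        )
        logger.info(
            "cluster: %d retained overlaps -> %d clusters (%d singletons)",
            len(scored), len(clusters.clusters), clusters.n_singletons,
        )
        # the overlap lists are by far the largest in-memory structures;
        # release them before the assembly stages
        del hits, scored, ordered, clusters
        import gc

        gc.collect()
    summary.stage_seconds["cluster"] = time.perf_counter() - t0

    # --- stage 4: local assembly ----------------------------------------
    t0 = time.perf_counter()
    local_fasta = workdir / "cluster_contigs.fasta"
    support_tsv = workdir / "cluster_support.tsv"
    if _stage_done(workdir, "local", cfg_hash) and local_fasta.exists():
        from .io_qc import read_fasta

        cluster_contigs = [
            SuperRead(
                id=cid, sequence=seq, support=[],
                quals=None, depth_profile=None,  # type: ignore[arg-type]
            )
            for cid, seq in read_fasta(local_fasta)
        ]
        import numpy as np

        for sr in cluster_contigs:
            sr.quals = np.full(len(sr.sequence), 40, np.uint8)
            sr.depth_profile = np.ones(len(sr.sequence), np.int32)
        logger.info("local: resumed (%d contigs)", len(cluster_contigs))
    else:
        manifest = (clusters_dir / "manifest.tsv").read_text().splitlines()[1:]
        cluster_ids = [int(line.split("\t")[0]) for line in manifest if line]
        jobs = []
        for cid in cluster_ids:
            creads = list(parse_fastq(clusters_dir / f"cluster_{cid}.fastq"))
            jobs.append((cid, creads, config.local))
        results = {}
        if config.threads > 1 and len(jobs) > 1:
            ctx = get_context("fork")
            with ctx.Pool(config.threads) as pool:
                for cid, res in pool.imap_unordered(_assemble_one, jobs):
                    results[cid] = res
        else:
            for job in jobs:
                cid, res = _assemble_one(job)
                results[cid] = res
        cluster_contigs = []
        unplaced_total = 0
        for cid in sorted(results):  # merge order fixed by cluster id
            cluster_contigs.extend(results[cid].contigs)
            unplaced_total += len(results[cid].unplaced)
        write_fasta(((c.id, c.sequence) for c in cluster_contigs), local_fasta)
        with open(support_tsv, "w") as fh:
            fh.write("contig_id\tread_id\toffset\torientation\n")
            for c in cluster_contigs:
                for rid, off, orient, _ in c.support:
                    fh.write(f"{c.id}\t{rid}\t{off}\t{'-' if orient else '+'}\n")
        _mark_done(workdir, "local", cfg_hash, n_contigs=len(cluster_contigs))
        logger.info(
            "local: %d cluster contigs from %d clusters (%d reads unplaced)",
            len(cluster_contigs), len(cluster_ids), unplaced_total,
        )
    summary.n_cluster_contigs = len(cluster_contigs)
    summary.n_clusters = len(
        {c.id.split("_ctg")[0] for c in cluster_contigs}
    )
    summary.stage_seconds["local"] = time.perf_counter() - t0

    # --- stage 5: global assembly ---------------------------------------
    t0 = time.perf_counter()
    final_fasta = workdir / "master_contigs.fasta"
    if _stage_done(workdir, "global", cfg_hash) and final_fasta.exists():
        logger.info("global: resumed")
    else:
        result = global_assemble(cluster_contigs, kept, config.glob)
        write_assembly(result.master_contigs, final_fasta)
        _mark_done(
            workdir, "global", cfg_hash,
            n_master=len(result.master_contigs), n_rounds=result.n_rounds,
        )
        logger.info(
            "global: %d master contigs after %d rounds",
            len(result.master_contigs), result.n_rounds,
        )
        summary.n_master_contigs = len(result.master_contigs)
    if summary.n_master_contigs == 0:
        summary.n_master_contigs = sum(
            1 for line in open(final_fasta) if line.startswith(">")
        )
    summary.final_fasta = final_fasta
    summary.stage_seconds["global"] = time.perf_counter() - t0
    logger.info(
        "pipeline done: %s (%s)",
        final_fasta,
        ", ".join(f"{k}={v:.1f}s" for k, v in summary.stage_seconds.items()),
    )
    return summary
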