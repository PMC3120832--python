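"""Pipeline orchestration, flow accounting and the printed-ratio arithmetic.

``run_pipeline`` executes the whole chain on simulated data — genome +
planted truth, library simulation, demultiplexing/filters, genome alignment
and partition, feature/SNP/fusion discovery, and differential expression —
writing every stage output plus a manifest under a run directory, and
returning all stage results in memory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from . import dge as dge_mod
from . import features, fusions as fus_mod, snps as snp_mod
from .align import Aligner, PartitionResult, ReadClass, partition_reads, single_hit_set
from .config import PipelineConfig, SimConfig
from .demux import FlowAccounting, Read, run_demux
from .genome import ToyGenome
from .psl import write_psl
from .simulate import (
    EventPlan,
    GroundTruth,
    ReadLogEntry,
    SimRead,
    generate_contaminants,
    generate_genome,
    plant_events,
    simulate_library,
    write_fastq,
)


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100 * numerator / denominator with half-up rounding."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if decimals not in (0, 1, 2):
        raise ValueError("decimals must be 0, 1 or 2")
    q = Decimal(1).scaleb(-decimals)
    val = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(q, rounding=ROUND_HALF_UP)
    return float(val)


def extrapolate_validated(candidates: int, validated: int, tested: int) -> int:
    """Project a validation rate over a candidate set (floor)."""
    if tested <= 0:
        raise ValueError("tested must be positive")
    if not 0 <= validated <= tested:
        raise ValueError("validated must be within tested")
    return candidates * validated // tested


@dataclass
class RunConfig:
    seed: int = 1
    outdir: str | None = None
    sim: SimConfig = field(default_factory=SimConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    plan: EventPlan = field(default_factory=EventPlan)


@dataclass
class RunResult:
    config: RunConfig
    genome: ToyGenome
    truth: GroundTruth
    contaminants: dict[str, str]
    reads: list[SimRead]
    read_log: dict[str, ReadLogEntry]
    lenient: dict[str, str | None]
    strict: dict[str, str | None]
    accounting: FlowAccounting
    partition: PartitionResult
    single_hit: dict
    assignments: dict[str, str]
    novel_genes: list
    splice_events: list
    coverage: features.CoverageSummary
    snp_candidates: list
    snp_rejects: list
    fusion_candidates: list  # merged, with artifact flags and support
    expression: pd.DataFrame
    as_category_counts: dict
    enrichment_p: dict
    outdir: Path | None


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Execute every stage on one simulated run; idempotent for a fixed seed."""
    sim = replace(cfg.sim, seed=cfg.seed)
    pcfg = cfg.pipeline

    base = generate_genome(sim)
    genome, truth = plant_events(base, cfg.plan, seed=sim.seed, size_window=sim.size_window)
    contaminants = generate_contaminants(sim)

    reads: list[SimRead] = []
    read_log: dict[str, ReadLogEntry] = {}
    for sample in sim.barcodes:
        res = simulate_library(genome, truth, sample, sim, contaminants)
        reads.extend(res.reads)
        read_log.update(res.log)

    dreads = [Read(r.read_id, r.sequence, r.qualities) for r in reads]
    lenient, strict, acct = run_demux(dreads, sim.barcodes, sim.adapter, contaminants, pcfg)
    retained = [rd for rd in dreads if lenient[rd.read_id] is not None]
    inserts = {rd.read_id: rd.insert for rd in retained}

    aligner = Aligner(
        genome.chromosomes,
        min_match=pcfg.min_match_floor,
        max_intron=pcfg.max_intron,
    )
    records_by_read = {rid: aligner.align(rid, seq) for rid, seq in inserts.items()}
    part = partition_reads(records_by_read, pcfg)
    counts = part.counts()
    acct.add("genome_alignment", len(retained),
             counts["COMPLETE"] + counts["PARTIAL"])
    shs = single_hit_set(part)
    acct.add("single_hit", counts["COMPLETE"], len(shs))

    assignments = features.map_to_genes(shs, genome.genes)
    intergenic = {rid: shs[rid] for rid, a in assignments.items() if a == "intergenic"}
    novel = features.detect_novel_genes(intergenic, genome.genes, genome, pcfg)
    events = features.classify_splice_events(shs, assignments, genome, pcfg, strict)

    txdb = {
        f"{g.gene_id}.1": (g.gene_id, genome.transcript(g.gene_id))
        for g in genome.genes
    }
    complete_ids = set(part.read_ids(ReadClass.COMPLETE))
    tx_align = features.align_to_transcripts(
        [(rid, seq) for rid, seq in inserts.items()], txdb, pcfg
    )
    cov_records = {
        rid: recs[0] for rid, recs in tx_align.items() if rid in complete_ids
    }
    coverage = features.coverage_summary(cov_records, txdb)

    pile = snp_mod.pileup(shs, inserts, genome, strict, pcfg)
    cands, rejects = snp_mod.call_candidates(pile, genome, genome.genes, pcfg)
    cands = snp_mod.annotate_candidates(cands, truth.known_snp_list(), genome.genes, genome)

    partial_recs = {rid: part.records[rid] for rid in part.read_ids(ReadClass.PARTIAL)}
    raw = fus_mod.find_candidates(partial_recs, inserts, genome, pcfg)
    raw = fus_mod.filter_artifacts(raw, genome.genes, genome.pseudogene_pairs, genome, pcfg)
    merged = fus_mod.merge_candidates(raw)
    for cand in merged:
        fus_mod.support_depth(cand, inserts, strict, pcfg)

    gene_counts = dge_mod.count_genes(tx_align, strict, txdb)
    expression = dge_mod.expression_table(gene_counts, pcfg)

    cat_counts: dict[str, tuple[int, int]] = {}
    for cat in features.CATEGORIES:
        e1 = sum(len(e.support.get("HB4a", [])) for e in events if e.category == cat)
        e2 = sum(len(e.support.get("C5.2", [])) for e in events if e.category == cat)
        cat_counts[cat] = (e1, e2)
    lib_totals = (
        sum(1 for v in strict.values() if v == "HB4a"),
        sum(1 for v in strict.values() if v == "C5.2"),
    )
    enrichment = (
        dge_mod.as_enrichment(cat_counts, lib_totals) if all(lib_totals) else {}
    )

    outdir = None
    if cfg.outdir is not None:
        outdir = Path(cfg.outdir)
        _write_outputs(
            outdir, cfg, genome, truth, reads, lenient, strict, acct, part,
            records_by_read, novel, events, cands, merged, expression,
        )

    return RunResult(
        config=cfg, genome=genome, truth=truth, contaminants=contaminants,
        reads=reads, read_log=read_log, lenient=lenient, strict=strict,
        accounting=acct, partition=part, single_hit=shs, assignments=assignments,
        novel_genes=novel, splice_events=events, coverage=coverage,
        snp_candidates=cands, snp_rejects=rejects, fusion_candidates=merged,
        expression=expression, as_category_counts=cat_counts,
        enrichment_p=enrichment, outdir=outdir,
    )


def _write_outputs(
    outdir: Path, cfg, genome, truth, reads, lenient, strict, acct, part,
    records_by_read, novel, events, snp_cands, fusion_cands, expression,
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    genome.write_fasta(outdir / "genome.fa")
    genome.write_gff3(outdir / "annotation.gff3")
    genome.write_bed(outdir / "annotation.bed")
    truth.to_json(outdir / "truth.json")

    by_sample: dict[str, list] = {}
    for r in reads:
        by_sample.setdefault(lenient.get(r.read_id) or "undefined", []).append(r)
    for sample, rs in by_sample.items():
        write_fastq(rs, outdir / f"{sample.replace('.', '')}.fastq")

    pd.DataFrame(acct.as_rows()).to_csv(outdir / "accounting.tsv", sep="\t", index=False)

    all_records = [r for recs in records_by_read.values() for r in recs]
    write_psl(all_records, outdir / "alignments.psl")
    pd.Series(part.counts()).rename("reads").to_csv(outdir / "partition.tsv", sep="\t")

    with open(outdir / "splice_events.tsv", "w") as fh:
        fh.write("gene\tcategory\tchrom\tstart\tend\tsites\tsupport_total\tsupport\n")
        for e in events:
            supp = ",".join(f"{k}:{len(v)}" for k, v in sorted(e.support.items()))
            fh.write(
                f"{e.gene_id}\t{e.category}\t{e.chrom}\t{e.coords[0]}\t{e.coords[1]}\t"
                f"{e.sites}\t{e.n_support}\t{supp}\n"
            )
    with open(outdir / "novel_genes.tsv", "w") as fh:
        fh.write("chrom\tintervals\texons\tsplice_status\tstrand\tdistance\treads\n")
        for n in novel:
            ivs = ";".join(f"{a}-{b}" for a, b in n.intervals)
            fh.write(
                f"{n.chrom}\t{ivs}\t{n.exon_count}\t{n.splice_status}\t"
                f"{n.strand_guess}\t{n.distance_to_gene}\t{len(n.read_ids)}\n"
            )
    snp_mod.write_candidates_tsv(snp_cands, outdir / "snp_candidates.tsv")
    fus_mod.write_candidates_tsv(fusion_cands, outdir / "fusion_candidates.tsv")
    expression.to_csv(outdir / "expression.tsv", sep="\t")

    manifest = {
        "seed": cfg.seed,
        "n_reads": len(reads),
        "stages": acct.as_rows(),
        "partition": part.counts(),
        "n_splice_events": len(events),
        "n_novel_gene_candidates": len(novel),
        "n_snp_candidates": len(snp_cands),
        "n_fusion_candidates": len(fusion_cands),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
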