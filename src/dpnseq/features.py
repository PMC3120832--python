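"""Mapping completely-aligned reads onto gene models: novel-gene discovery,
alternative-splicing event classification, and transcript coverage summaries.

Splice events are read-level observations against the annotation: alignment
gaps longer than 50 nt with conserved (GT..AG) splice sites are treated as
true introns; an unannotated exon inside an annotated intron is an exon
inclusion (sub-classified by how many flanking constitutive exons the read
shows), an absent annotated exon between two others is an exon skipping, a
junction sharing exactly one boundary with the annotation is an alternative
donor/acceptor, and a read running through an annotated intron without a gap
is an intron retention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from .align import AlignmentRecord
from .config import PipelineConfig
from .genome import GeneModel, ToyGenome
from .util import merge_intervals, overlap

CATEGORIES = (
    "intron_retention",
    "alt_donor",
    "alt_acceptor",
    "exon_skipping",
    "exon_inclusion_one_flank",
    "exon_inclusion_both_flanks",
)


@dataclass
class SpliceEvent:
    gene_id: str
    category: str
    chrom: str
    coords: tuple[int, int]
    sites: str  # junction dinucleotides, e.g. "GT..AG"
    support: dict[str, list[str]] = field(default_factory=dict)  # sample -> read ids

    @property
    def key(self) -> tuple:
        return (self.gene_id, self.category, self.coords)

    @property
    def n_support(self) -> int:
        return sum(len(v) for v in self.support.values())

    def add(self, sample: str | None, read_id: str) -> None:
        self.support.setdefault(sample or "undefined", []).append(read_id)


@dataclass
class NovelGeneCandidate:
    chrom: str
    intervals: tuple[tuple[int, int], ...]
    splice_status: str  # 'canonical' | 'non_canonical' | 'NA'
    strand_guess: str  # '+', '-', or '.'
    distance_to_gene: int
    read_ids: list[str]

    @property
    def exon_count(self) -> int:
        return len(self.intervals)


@dataclass
class CoverageSummary:
    transcripts_detected: int
    genes_detected: int
    total_nt: int
    covered_nt: int
    histogram: np.ndarray  # relative midpoint position, bins 0..100

    @property
    def basepair_representation(self) -> float:
        return self.covered_nt / self.total_nt if self.total_nt else 0.0


# ------------------------------------------------------------------ mapping
def _exon_tree(genes: list[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        t = trees.setdefault(g.chrom, IntervalTree())
        for a, b in g.exons:
            t[a:b] = g.gene_id
    return trees


def map_to_genes(
    records: dict[str, AlignmentRecord], genes: list[GeneModel]
) -> dict[str, str]:
    """Per-read assignment: a gene id, 'intergenic', or 'ambiguous' (blocks
    overlapping exons of two or more genes; excluded from counting)."""
    trees = _exon_tree(genes)
    out: dict[str, str] = {}
    for rid, rec in records.items():
        tree = trees.get(rec.chrom)
        hits: set[str] = set()
        if tree is not None:
            for a, b in rec.target_intervals():
                hits |= {iv.data for iv in tree.overlap(a, b)}
        if len(hits) == 1:
            out[rid] = hits.pop()
        elif len(hits) > 1:
            out[rid] = "ambiguous"
        else:
            out[rid] = "intergenic"
    return out


# --------------------------------------------------------------- novel genes
def detect_novel_genes(
    records: dict[str, AlignmentRecord],
    genes: list[GeneModel],
    genome: ToyGenome,
    config: PipelineConfig,
) -> list[NovelGeneCandidate]:
    """Cluster intergenic reads (single-linkage on read spans) into putative
    novel transcription units and check their splice sites."""
    spans: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        spans.setdefault(g.chrom, []).append(g.span)
    # reads overlapping any annotated gene span (e.g. intron-only) are not
    # novel-gene evidence
    clean = {}
    for rid, rec in records.items():
        t0, t1 = rec.tstart, rec.tend
        if any(overlap((t0, t1), s) for s in spans.get(rec.chrom, [])):
            continue
        clean[rid] = rec

    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for rid, rec in clean.items():
        by_chrom.setdefault(rec.chrom, []).append((rec.tstart, rec.tend, rid))

    out: list[NovelGeneCandidate] = []
    for chrom, rows in sorted(by_chrom.items()):
        rows.sort()
        clusters: list[list[tuple[int, int, str]]] = [[rows[0]]]
        for row in rows[1:]:
            if row[0] <= max(r[1] for r in clusters[-1]) + config.novel_cluster_gap:
                clusters[-1].append(row)
            else:
                clusters.append([row])
        seq = genome.chromosomes[chrom].upper()
        for cl in clusters:
            ids = [r[2] for r in cl]
            blocks = []
            for _, _, rid in cl:
                blocks.extend(clean[rid].target_intervals())
            exons = merge_intervals(blocks)
            gaps = [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]
            gaps = [g for g in gaps if g[1] - g[0] > config.min_intron_gap]
            if not gaps:
                exons = merge_intervals(blocks, gap=config.min_intron_gap)
                status, strand = "NA", "."
            else:
                plus = all(seq[s : s + 2] == "GT" and seq[e - 2 : e] == "AG" for s, e in gaps)
                minus = all(seq[s : s + 2] == "CT" and seq[e - 2 : e] == "AC" for s, e in gaps)
                if plus:
                    status, strand = "canonical", "+"
                elif minus:
                    status, strand = "canonical", "-"
                else:
                    status, strand = "non_canonical", "."
            span = (exons[0][0], exons[-1][1])
            dists = [
                0 if overlap(span, s) else max(s[0] - span[1], span[0] - s[1])
                for s in spans.get(chrom, [])
            ]
            dist = min(dists) if dists else 10**9
            out.append(NovelGeneCandidate(chrom, tuple(exons), status, strand, dist, ids))
    return out


# ------------------------------------------------------------ splice events
def _canonical(seq: str, gap: tuple[int, int], allow_gc: bool) -> str | None:
    don, acc = seq[gap[0] : gap[0] + 2], seq[gap[1] - 2 : gap[1]]
    if (don, acc) == ("GT", "AG") or (allow_gc and (don, acc) == ("GC", "AG")):
        return f"{don}..{acc}"
    if (don, acc) == ("CT", "AC") or (allow_gc and (don, acc) == ("CT", "GC")):
        return f"{don}..{acc}"
    return None


def classify_splice_events(
    records: dict[str, AlignmentRecord],
    assignments: dict[str, str],
    genome: ToyGenome,
    config: PipelineConfig,
    read_sample: dict[str, str | None] | None = None,
) -> list[SpliceEvent]:
    """Classify unannotated splicing observations of gene-assigned reads.

    Events are keyed by (gene, category, coordinates) so multi-read support
    accumulates; per-sample support follows the strict-mode demultiplexing.
    """
    read_sample = read_sample or {}
    genes = {g.gene_id: g for g in genome.genes}
    events: dict[tuple, SpliceEvent] = {}

    def emit(gene: GeneModel, category: str, coords: tuple[int, int], sites: str, rid: str):
        key = (gene.gene_id, category, coords)
        ev = events.get(key)
        if ev is None:
            ev = SpliceEvent(gene.gene_id, category, gene.chrom, coords, sites)
            events[key] = ev
        ev.add(read_sample.get(rid), rid)

    for rid, rec in sorted(records.items()):
        gid = assignments.get(rid)
        if gid in (None, "intergenic", "ambiguous"):
            continue
        gene = genes[gid]
        seq = genome.chromosomes[gene.chrom].upper()
        introns = gene.introns()
        intron_set = set(introns)
        blocks = rec.target_intervals()
        gaps = rec.target_gaps()
        valid = [
            (g[1] - g[0] > config.min_intron_gap)
            and _canonical(seq, g, config.allow_gc_donor) is not None
            for g in gaps
        ]
        consumed: set[int] = set()

        # exon inclusion: an unannotated block inside an annotated intron
        for bi, blk in enumerate(blocks):
            intr_i = next(
                (i for i, iv in enumerate(introns) if iv[0] <= blk[0] and blk[1] <= iv[1]), None
            )
            if intr_i is None:
                continue
            left_gap = bi - 1 if bi > 0 else None
            right_gap = bi if bi < len(gaps) else None
            lg = left_gap is not None and valid[left_gap]
            rg = right_gap is not None and valid[right_gap]
            if not (lg or rg):
                continue  # no junction evidence; retention logic handles blocks
            up_ex, down_ex = gene.exons[intr_i], gene.exons[intr_i + 1]
            has_up = any(overlap(b, up_ex) >= config.min_anchor for b in blocks)
            has_down = any(overlap(b, down_ex) >= config.min_anchor for b in blocks)
            if not (has_up or has_down):
                continue
            both = has_up and has_down and lg and rg
            cat = "exon_inclusion_both_flanks" if both else "exon_inclusion_one_flank"
            sites = _canonical(seq, gaps[left_gap], config.allow_gc_donor) if lg else ""
            emit(gene, cat, blk, sites or "", rid)
            if lg:
                consumed.add(left_gap)
            if rg:
                consumed.add(right_gap)

        # gap-based events
        for gi, gap in enumerate(gaps):
            if gi in consumed or not valid[gi]:
                continue
            if gap in intron_set:
                continue  # annotated junction, not an event
            gs, ge = gap
            start_match = any(s == gs for s, e in introns)
            end_match = any(e == ge for s, e in introns)
            sites = _canonical(seq, gap, config.allow_gc_donor) or ""
            if start_match and end_match:
                if any(gs <= a and b <= ge for a, b in gene.exons):
                    emit(gene, "exon_skipping", gap, sites, rid)
                continue
            if start_match != end_match:
                if start_match:
                    cat = "alt_acceptor" if gene.strand == "+" else "alt_donor"
                else:
                    cat = "alt_donor" if gene.strand == "+" else "alt_acceptor"
                emit(gene, cat, gap, sites, rid)
            # neither boundary annotated: a fully novel intron; not classified

        # intron retention: a block continuing through an annotated intron
        for bi, blk in enumerate(blocks):
            for ii, intr in enumerate(introns):
                ov = overlap(blk, intr)
                if ov < config.retention_min_overlap:
                    continue
                if intr[0] <= blk[0] and blk[1] <= intr[1]:
                    continue  # fully intronic block (inclusion geometry)
                up_ex, down_ex = gene.exons[ii], gene.exons[ii + 1]
                anchored = (
                    overlap(blk, up_ex) >= config.min_anchor
                    or overlap(blk, down_ex) >= config.min_anchor
                )
                if not anchored:
                    continue
                spans_whole = blk[0] < intr[0] and blk[1] > intr[1]
                ends_inside = blk[0] < intr[0] and blk[1] <= intr[1] and bi == len(blocks) - 1
                starts_inside = blk[0] >= intr[0] and blk[1] > intr[1] and bi == 0
                if spans_whole or ends_inside or starts_inside:
                    emit(gene, "intron_retention", intr, "", rid)
    return sorted(events.values(), key=lambda e: e.key)


# ------------------------------------------------------------------ coverage
def coverage_summary(
    tx_records: dict[str, AlignmentRecord],
    txdb: dict[str, tuple[str, str]],
) -> CoverageSummary:
    """Covered-base union and relative-position profile over a transcript DB.

    ``tx_records`` maps read id -> its best transcript-space alignment;
    ``txdb`` maps transcript id -> (gene id, sequence).
    """
    covered: dict[str, list[tuple[int, int]]] = {}
    hist = np.zeros(101, dtype=int)
    for rid, rec in tx_records.items():
        covered.setdefault(rec.chrom, []).extend(rec.target_intervals())
        mid = (rec.tstart + rec.tend) / 2.0
        pos = int(round(100.0 * mid / rec.tsize))
        hist[min(max(pos, 0), 100)] += 1
    total_nt = sum(len(seq) for _, seq in txdb.values())
    covered_nt = 0
    for tx, ivs in covered.items():
        covered_nt += sum(b - a for a, b in merge_intervals(ivs))
    genes = {txdb[tx][0] for tx in covered}
    return CoverageSummary(
        transcripts_detected=len(covered),
        genes_detected=len(genes),
        total_nt=total_nt,
        covered_nt=covered_nt,
        histogram=hist,
    )


def align_to_transcripts(
    reads: list[tuple[str, str]],
    txdb: dict[str, tuple[str, str]],
    config: PipelineConfig,
    aligner=None,
):
    """Best transcript-space alignments passing the transcript-DB thresholds.

    Returns read id -> list of passing records (best first).
    """
    from .align import Aligner

    if aligner is None:
        aligner = Aligner({tx: seq for tx, (_, seq) in txdb.items()}, max_intron=0)
    out: dict[str, list[AlignmentRecord]] = {}
    for rid, seq in reads:
        recs = [
            r
            for r in aligner.align(rid, seq)
            if r.evalue(aligner.db_len) <= config.txdb_max_evalue
            and r.identity >= config.txdb_min_identity
            and r.coverage >= config.txdb_min_coverage
        ]
        if recs:
            out[rid] = recs
    return out
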