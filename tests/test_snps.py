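"""Pileup construction, SNP candidate filters, and annotation."""

import numpy as np
import pytest

from dpnseq.align import AlignmentRecord
from dpnseq.config import PipelineConfig
from dpnseq.genome import GeneModel, ToyGenome
from dpnseq.snps import annotate_candidates, call_candidates, pileup

CFG = PipelineConfig()


def _flat_genome(n=600, seed=2):
    rng = np.random.default_rng(seed)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
    # keep homopolymers short so the run filter stays quiet by default
    seq = seq.replace("AAAA", "AACA").replace("TTTT", "TTCT")
    gene = GeneModel("G1", "chr1", "+", ((0, n),), cds=(30, 30 + ((n - 60) // 3) * 3))
    return ToyGenome({"chr1": seq}, [gene])


def _reads_at(genome, start, length, n_ref, n_alt, alt_pos=None, alt_base=None,
              lib_split=None):
    """n_ref reference reads plus n_alt reads carrying alt_base at alt_pos."""
    seq = genome.chromosomes["chr1"]
    records, read_seqs, libs = {}, {}, {}
    libsplit = lib_split or (lambda i: "HB4a" if i % 2 == 0 else "C5.2")
    i = 0
    for _ in range(n_ref):
        rid = f"ref{i}"
        read_seqs[rid] = seq[start : start + length]
        records[rid] = AlignmentRecord(rid, length, "chr1", len(seq), "+",
                                       ((0, start, length),), length, 0)
        libs[rid] = libsplit(i)
        i += 1
    for _ in range(n_alt):
        rid = f"alt{i}"
        s = list(seq[start : start + length])
        s[alt_pos - start] = alt_base
        read_seqs[rid] = "".join(s)
        records[rid] = AlignmentRecord(rid, length, "chr1", len(seq), "+",
                                       ((0, start, length),), length - 1, 1)
        libs[rid] = libsplit(i)
        i += 1
    return records, read_seqs, libs


def test_identical_reads_give_clean_pileup():
    genome = _flat_genome()
    records, seqs, libs = _reads_at(genome, 100, 200, n_ref=3, n_alt=0)
    pile = pileup(records, seqs, genome, libs, CFG)
    depths = [pile.depth[lib]["chr1"][150] for lib in pile.libraries]
    assert sum(depths) == 3
    assert pile.mismatches == {}


def test_clean_het_snp_called_with_expected_ratio():
    genome = _flat_genome()
    pos, alt = 200, "A" if genome.chromosomes["chr1"][200] != "A" else "C"
    records, seqs, libs = _reads_at(genome, 100, 200, n_ref=10, n_alt=10,
                                    alt_pos=pos, alt_base=alt)
    pile = pileup(records, seqs, genome, libs, CFG)
    cands, rejects = call_candidates(pile, genome, genome.genes, CFG)
    assert len(cands) == 1 and rejects == []
    c = cands[0]
    assert (c.pos, c.alt) == (pos, alt)
    assert c.total_depth == 20 and c.total_alt == 10
    assert all(z == "het" for z in c.zygosity.values())


def test_end_margin_masks_read_edge_bases():
    """Bases within 5 nt of an alignment end never enter the pileup."""
    genome = _flat_genome()
    alt = "A" if genome.chromosomes["chr1"][102] != "A" else "C"
    records, seqs, libs = _reads_at(genome, 100, 200, n_ref=0, n_alt=6,
                                    alt_pos=102, alt_base=alt)
    pile = pileup(records, seqs, genome, libs, CFG)
    assert ("chr1", 102) not in pile.mismatches


def test_two_mismatches_in_window_both_rejected():
    genome = _flat_genome()
    seq = genome.chromosomes["chr1"]
    p1, p2 = 200, 230
    a1 = "A" if seq[p1] != "A" else "C"
    a2 = "A" if seq[p2] != "A" else "C"
    records, seqs, libs = {}, {}, {}
    for j, (p, a) in enumerate(((p1, a1), (p2, a2))):
        r, s, l = _reads_at(genome, 100, 200, n_ref=4, n_alt=8, alt_pos=p, alt_base=a)
        for rid in list(r):
            records[f"{j}_{rid}"] = AlignmentRecord(
                f"{j}_{rid}", r[rid].qsize, "chr1", r[rid].tsize, "+",
                r[rid].blocks, r[rid].matches, r[rid].mismatches)
            seqs[f"{j}_{rid}"] = s[rid]
            libs[f"{j}_{rid}"] = l[rid]
    pile = pileup(records, seqs, genome, libs, CFG)
    cands, rejects = call_candidates(pile, genome, genome.genes, CFG)
    assert cands == []
    assert {(p, reason) for _, p, reason in rejects} == {(p1, "window"), (p2, "window")}


def test_homopolymer_site_rejected():
    genome = _flat_genome()
    seq = list(genome.chromosomes["chr1"])
    seq[200:205] = "AAAAA"
    genome.chromosomes["chr1"] = "".join(seq)
    records, seqs, libs = _reads_at(genome, 100, 200, n_ref=4, n_alt=8,
                                    alt_pos=202, alt_base="G")
    pile = pileup(records, seqs, genome, libs, CFG)
    cands, rejects = call_candidates(pile, genome, genome.genes, CFG)
    assert cands == []
    assert rejects[0][2] == "homopolymer"


def test_single_library_site_rejected():
    genome = _flat_genome()
    alt = "A" if genome.chromosomes["chr1"][200] != "A" else "C"
    records, seqs, libs = _reads_at(genome, 100, 200, n_ref=8, n_alt=8,
                                    alt_pos=200, alt_base=alt,
                                    lib_split=lambda i: "HB4a" if i < 8 else "C5.2")
    # alt reads all in C5.2 (indices 8..15): present_in_both fails
    pile = pileup(records, seqs, genome, libs, CFG)
    cands, rejects = call_candidates(pile, genome, genome.genes, CFG)
    assert cands == []
    assert rejects[0][2] == "single_library"


def test_triallelic_site_rejected():
    genome = _flat_genome()
    ref = genome.chromosomes["chr1"][200]
    alts = [b for b in "ACGT" if b != ref][:2]
    records, seqs, libs = {}, {}, {}
    for j, a in enumerate(alts):
        r, s, l = _reads_at(genome, 100, 200, n_ref=3, n_alt=6, alt_pos=200, alt_base=a)
        for rid in r:
            records[f"{j}{rid}"] = AlignmentRecord(
                f"{j}{rid}", 200, "chr1", r[rid].tsize, "+", r[rid].blocks,
                r[rid].matches, r[rid].mismatches)
            seqs[f"{j}{rid}"] = s[rid]
            libs[f"{j}{rid}"] = l[rid]
    pile = pileup(records, seqs, genome, libs, CFG)
    cands, rejects = call_candidates(pile, genome, genome.genes, CFG)
    assert cands == []
    assert rejects[0][2] == "triallelic"


def test_annotation_known_region_consequence():
    genome = _flat_genome()
    gene = genome.genes[0]
    cs, ce = gene.cds
    tx = genome.chromosomes["chr1"]
    # third codon position of codon 10: often synonymous; craft explicitly
    pos = cs + 29  # codon 10, position 3
    from Bio.Seq import Seq

    codon = tx[cs + 27 : cs + 30]
    syn_alt = None
    for b in "ACGT":
        if b == tx[pos]:
            continue
        if str(Seq(codon[:2] + b).translate()) == str(Seq(codon).translate()):
            syn_alt = b
            break
    records, seqs, libs = _reads_at(genome, max(0, pos - 60), 150, n_ref=6, n_alt=6,
                                    alt_pos=pos, alt_base=syn_alt or "A")
    pile = pileup(records, seqs, genome, libs, CFG)
    cands, _ = call_candidates(pile, genome, genome.genes, CFG)
    assert len(cands) == 1
    known = [("chr1", pos, tx[pos], cands[0].alt)]
    annotate_candidates(cands, known, genome.genes, genome)
    c = cands[0]
    assert c.known is True
    assert c.region == "CDS"
    if syn_alt is not None:
        assert c.consequence == "synonymous"


def test_call_set_invariant_to_read_order():
    genome = _flat_genome()
    alt = "A" if genome.chromosomes["chr1"][200] != "A" else "C"
    records, seqs, libs = _reads_at(genome, 100, 200, n_ref=6, n_alt=6,
                                    alt_pos=200, alt_base=alt)
    fwd = pileup(records, seqs, genome, libs, CFG)
    rev = pileup(dict(reversed(list(records.items()))), seqs, genome, libs, CFG)
    c1, _ = call_candidates(fwd, genome, genome.genes, CFG)
    c2, _ = call_candidates(rev, genome, genome.genes, CFG)
    assert [(c.pos, c.alt, c.depth, c.alt_count) for c in c1] == [
        (c.pos, c.alt, c.depth, c.alt_count) for c in c2
    ]


def test_emitted_candidates_reassert_all_filters(full_run):
    """Every emitted candidate passes every individual filter when re-checked
    independently of the caller."""
    from dpnseq.util import homopolymer_run

    cfg = full_run.config.pipeline
    for c in full_run.snp_candidates:
        assert c.alt != c.ref
        assert all(c.alt_count[lib] <= c.depth[lib] for lib in c.depth)
        assert all(c.depth[lib] >= cfg.snp_min_depth for lib in c.depth)
        assert c.present_in_both
        assert c.alt_ratio >= cfg.snp_min_alt_ratio
        assert c.boundary_dist >= cfg.snp_min_boundary_dist
        assert c.end_dist >= cfg.snp_end_margin
        assert c.window_mismatches == 0
        assert homopolymer_run(full_run.genome.chromosomes[c.chrom], c.pos) < cfg.homopolymer_min_run
        assert not full_run.genome.chromosomes[c.chrom][c.pos].islower()
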