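"""Fusion candidate discovery, junction character, and artifact flags."""

import numpy as np
import pytest

from dpnseq.align import Aligner, AlignmentRecord
from dpnseq.config import PipelineConfig
from dpnseq.fusions import (
    FusionCandidate,
    Segment,
    filter_artifacts,
    find_candidates,
    junction_character,
    merge_candidates,
)
from dpnseq.genome import GeneModel, ToyGenome
from dpnseq.util import revcomp

CFG = PipelineConfig()


def _rs(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _chimera_genome(mh=0, nt="", seed=21):
    """Two chromosomes and a chimeric read with a controlled junction."""
    rng = np.random.default_rng(seed)
    a = _rs(rng, 1500)
    b = _rs(rng, 1500)
    pa, pb = 700, 600
    if mh:
        b = b[:pb] + a[pa : pa + mh] + b[pb + mh :]
    # force divergence at the junction boundaries
    ops = {"A": "C", "C": "A", "G": "T", "T": "G"}
    if not nt:
        if a[pa + mh] == b[pb + mh]:
            b = b[: pb + mh] + ops[b[pb + mh]] + b[pb + mh + 1 :]
        if a[pa - 1] == b[pb - 1]:
            b = b[: pb - 1] + ops[b[pb - 1]] + b[pb:]
    else:
        if nt[0] == a[pa]:
            a = a[:pa] + ops[a[pa]] + a[pa + 1 :]
        if nt[-1] == b[pb - 1]:
            b = b[: pb - 1] + ops[b[pb - 1]] + b[pb:]
    read = a[pa - 100 : pa] + nt + b[pb : pb + 100]
    genome = ToyGenome(
        {"chrA": a, "chrB": b},
        [
            GeneModel("GA", "chrA", "+", ((pa - 200, pa + 200),)),
            GeneModel("GB", "chrB", "+", ((pb - 200, pb + 200),)),
        ],
    )
    return genome, read, (pa, pb)


def _oracle_mh_nt(read, genome, cand):
    """Brute force: try every junction placement; the number of valid
    placements minus one is the microhomology length; if no placement is
    valid the uncovered middle is the non-templated insert."""
    a, b = sorted((cand.seg_a, cand.seg_b), key=lambda s: s.read_lo)
    ta = genome.chromosomes[a.record.chrom].upper()
    tb = genome.chromosomes[b.record.chrom].upper()

    def a_ok(j):  # read[:j] consistent with the A continuation
        return all(
            a.record.frame_base(ta, p) == read[p] for p in range(a.read_lo, j)
        )

    def b_ok(j):
        return all(
            b.record.frame_base(tb, p) == read[p] for p in range(j, b.read_hi)
        )

    valid = [j for j in range(a.read_lo, b.read_hi + 1) if a_ok(j) and b_ok(j)]
    if valid:
        return (len(valid) - 1, 0)
    lo = max(j for j in range(a.read_lo, b.read_hi + 1) if a_ok(j))
    hi = min(j for j in range(a.read_lo, b.read_hi + 1) if b_ok(j))
    return (0, hi - lo)


@pytest.mark.parametrize("mh,nt", [(0, ""), (10, ""), (4, ""), (0, "CA")])
def test_junction_character_matches_plant_and_oracle(mh, nt):
    genome, read, _ = _chimera_genome(mh, nt)
    aligner = Aligner(genome.chromosomes)
    recs = aligner.align("r", read)
    cands = find_candidates({"r": recs}, {"r": read}, genome, CFG)
    assert len(cands) == 1
    cand = cands[0]
    assert (cand.mh_len, cand.nt_len) == (mh, len(nt))
    if nt:
        assert cand.nt_seq == nt
    assert _oracle_mh_nt(read.upper(), genome, cand) == (mh, len(nt))
    # exactly one of mh>0 / nt>0, or both zero
    assert not (cand.mh_len > 0 and cand.nt_len > 0)


def test_junction_character_symmetric_in_segment_order():
    genome, read, _ = _chimera_genome(mh=6)
    recs = Aligner(genome.chromosomes).align("r", read)
    cand = find_candidates({"r": recs}, {"r": read}, genome, CFG)[0]
    swapped = FusionCandidate(["r"], cand.sequence, cand.seg_b, cand.seg_a)
    junction_character(swapped, genome)
    assert (swapped.mh_len, swapped.nt_len, swapped.nt_seq) == (
        cand.mh_len, cand.nt_len, cand.nt_seq,
    )


def test_single_segment_read_is_not_a_candidate():
    rng = np.random.default_rng(33)
    g = _rs(rng, 2000)
    genome = ToyGenome({"chrA": g}, [GeneModel("GA", "chrA", "+", ((0, 2000),))])
    read = g[300:500]
    recs = Aligner(genome.chromosomes).align("r", read)
    assert find_candidates({"r": recs}, {"r": read}, genome, CFG) == []


def test_nonunique_segment_rejected():
    """A segment matching two genomic loci disqualifies the read."""
    rng = np.random.default_rng(34)
    core = _rs(rng, 120)
    a = _rs(rng, 400) + core + _rs(rng, 400) + core + _rs(rng, 400)  # duplicated
    b = _rs(rng, 1000)
    genome = ToyGenome(
        {"chrA": a, "chrB": b},
        [GeneModel("GA", "chrA", "+", ((0, len(a)),)),
         GeneModel("GB", "chrB", "+", ((0, 1000),))],
    )
    read = core[:100] + b[500:600]
    recs = Aligner(genome.chromosomes).align("r", read)
    assert find_candidates({"r": recs}, {"r": read}, genome, CFG) == []


def test_artifact_flags():
    genome, read, (pa, pb) = _chimera_genome(mh=0, seed=40)
    recs = Aligner(genome.chromosomes).align("r", read)
    cand = find_candidates({"r": recs}, {"r": read}, genome, CFG)[0]

    # clean junction: no flags
    filter_artifacts([cand], genome.genes, [], genome, CFG)
    assert cand.artifact is False and cand.artifact_reasons == []

    # a GATC spanning the junction fires the DpnII-artifact flag
    j = cand.junction_lo
    gatc_read = read[: j - 2] + "GATC" + read[j + 2 :]
    cand2 = FusionCandidate(["r"], gatc_read, cand.seg_a, cand.seg_b)
    cand2.junction_lo = cand2.junction_hi = j
    filter_artifacts([cand2], genome.genes, [], genome, CFG)
    assert "dpnii_junction" in cand2.artifact_reasons

    # same-gene chimera
    both_in_a = [
        GeneModel("GA", "chrA", "+", ((0, 1500),)),
        GeneModel("GB", "chrB", "+", ((0, 1500),)),
    ]
    cand3 = FusionCandidate(["r"], read, cand.seg_a, cand.seg_b)
    cand3.junction_lo, cand3.junction_hi = cand.junction_lo, cand.junction_hi
    seg_b_on_a = Segment(
        AlignmentRecord("r", cand.seg_b.record.qsize, "chrA", 1500, "+",
                        cand.seg_b.record.blocks, cand.seg_b.record.matches, 0),
        cand.seg_b.read_lo, cand.seg_b.read_hi,
    )
    cand3.seg_b = seg_b_on_a
    filter_artifacts([cand3], both_in_a, [], genome, CFG)
    assert "same_gene" in cand3.artifact_reasons

    # gene/pseudogene pair
    cand4 = FusionCandidate(["r"], read, cand.seg_a, cand.seg_b)
    cand4.junction_lo, cand4.junction_hi = cand.junction_lo, cand.junction_hi
    filter_artifacts([cand4], genome.genes, [("GA", "GB")], genome, CFG)
    assert "pseudogene_pair" in cand4.artifact_reasons

    # intronic segment
    exonless = [
        GeneModel("GA", "chrA", "+", ((0, 50),)),
        GeneModel("GB", "chrB", "+", ((pb - 200, pb + 200),)),
    ]
    cand5 = FusionCandidate(["r"], read, cand.seg_a, cand.seg_b)
    cand5.junction_lo, cand5.junction_hi = cand.junction_lo, cand.junction_hi
    filter_artifacts([cand5], exonless, [], genome, CFG)
    assert "non_exonic" in cand5.artifact_reasons


def test_merge_accumulates_read_support():
    genome, read, _ = _chimera_genome(mh=3, seed=55)
    al = Aligner(genome.chromosomes)
    recs = {f"r{i}": al.align(f"r{i}", read) for i in range(5)}
    seqs = {f"r{i}": read for i in range(5)}
    cands = find_candidates(recs, seqs, genome, CFG)
    merged = merge_candidates(cands)
    assert len(merged) == 1
    assert sorted(merged[0].read_ids) == [f"r{i}" for i in range(5)]
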