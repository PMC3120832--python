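"""Gene-fusion candidate discovery from partially-aligning reads.

A raw candidate is a read whose sequence splits into two perfectly-matching
segments (>=20 nt, 100% segment identity, each unique in the genome) that
jointly cover >=90% of the read. Candidates are then flagged — never
deleted — as library-construction artifacts (DpnII GATC at the junction),
same-gene chimeras, gene/pseudogene chimeras, or non-exonic alignments.
Junction character distinguishes microhomology (junction bases consistent
with both genomic continuations, a FoSTeS signature) from short
non-templated insertions (bases matching neither side).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from .align import AlignmentRecord
from .config import PipelineConfig
from .genome import GeneModel, ToyGenome
from .util import gatc_positions, overlap, revcomp


@dataclass
class Segment:
    record: AlignmentRecord
    read_lo: int  # perfect core, read orientation, half-open
    read_hi: int

    @property
    def length(self) -> int:
        return self.read_hi - self.read_lo


@dataclass
class FusionCandidate:
    read_ids: list[str]
    sequence: str  # representative read (insert)
    seg_a: Segment
    seg_b: Segment
    gene_a: str | None = None
    gene_b: str | None = None
    mh_len: int = 0
    nt_len: int = 0
    nt_seq: str = ""
    junction_lo: int = 0  # junction placement range on the read [lo, hi]
    junction_hi: int = 0
    artifact: bool = False
    artifact_reasons: list[str] = field(default_factory=list)
    support: dict[str, int] = field(default_factory=dict)

    @property
    def chrom_a(self) -> str:
        return self.seg_a.record.chrom

    @property
    def chrom_b(self) -> str:
        return self.seg_b.record.chrom

    @property
    def cls(self) -> str:
        return "intra" if self.chrom_a == self.chrom_b else "inter"

    @property
    def support_total(self) -> int:
        return sum(self.support.values())

    @property
    def key(self) -> tuple:
        ra, rb = self.seg_a.record, self.seg_b.record
        return (ra.chrom, ra.tstart // 10, rb.chrom, rb.tstart // 10)


def _perfect_core(rec: AlignmentRecord, read: str, genome: ToyGenome) -> tuple[int, int] | None:
    """Longest contiguous mismatch-free run of the record, in read coords."""
    tseq = genome.chromosomes[rec.chrom].upper()
    aln_q = read.upper() if rec.strand == "+" else revcomp(read).upper()
    flags: list[bool] = []
    qpos: list[int] = []
    for q0, t0, ln in rec.blocks:
        for i in range(ln):
            flags.append(aln_q[q0 + i] == tseq[t0 + i])
            qpos.append(q0 + i)
    best = cur = 0
    best_span = None
    cur_start = 0
    for i, ok in enumerate(flags):
        if ok:
            cur += 1
            if cur > best:
                best = cur
                best_span = (i - cur + 1, i + 1)
        else:
            cur = 0
    if best_span is None:
        return None
    qa, qb = qpos[best_span[0]], qpos[best_span[1] - 1] + 1
    if rec.strand == "+":
        return (qa, qb)
    return (rec.qsize - qb, rec.qsize - qa)


def find_candidates(
    partial_records: dict[str, list[AlignmentRecord]],
    read_seqs: dict[str, str],
    genome: ToyGenome,
    config: PipelineConfig,
) -> list[FusionCandidate]:
    """Per-read raw chimera candidates from the PARTIAL subset."""
    out: list[FusionCandidate] = []
    for rid in sorted(partial_records):
        recs = partial_records[rid]
        read = read_seqs[rid]
        n = len(read)
        segs: list[Segment] = []
        for rec in recs:
            core = _perfect_core(rec, read, genome)
            if core is None or core[1] - core[0] < config.fusion_min_segment:
                continue
            segs.append(Segment(rec, core[0], core[1]))
        # each region of the read may have only one match in the genome
        unique: list[Segment] = []
        for s in segs:
            competing = False
            for r2 in recs:
                if r2 is s.record:
                    continue
                if r2.chrom == s.record.chrom and overlap(
                    (r2.tstart, r2.tend), (s.record.tstart, s.record.tend)
                ):
                    continue  # same locus
                iv = r2.read_interval()
                if overlap(iv, (s.read_lo, s.read_hi)) >= 0.5 * s.length and r2.identity >= 0.95:
                    competing = True
                    break
            if not competing:
                unique.append(s)
        unique.sort(key=lambda s: (s.read_lo, s.read_hi))
        best_pair = None
        best_cover = 0
        for i in range(len(unique)):
            for j in range(len(unique)):
                if i == j:
                    continue
                a, b = unique[i], unique[j]
                if a.read_lo > b.read_lo or a.read_hi >= b.read_hi:
                    continue
                if a.record.chrom == b.record.chrom and overlap(
                    (a.record.tstart, a.record.tend), (b.record.tstart, b.record.tend)
                ):
                    continue
                union = (b.read_hi - a.read_lo) - max(0, b.read_lo - a.read_hi)
                if union / n < config.fusion_min_joint_coverage:
                    continue
                if overlap((a.read_lo, a.read_hi), (b.read_lo, b.read_hi)) > a.length / 2:
                    continue
                if union > best_cover:
                    best_cover = union
                    best_pair = (a, b)
        if best_pair is None:
            continue
        a, b = best_pair
        cand = FusionCandidate([rid], read, a, b)
        junction_character(cand, genome)
        out.append(cand)
    return out


def junction_character(cand: FusionCandidate, genome: ToyGenome) -> tuple[int, int, str]:
    """Microhomology / non-templated lengths at the junction.

    mh_len is the length of the maximal read substring consistent with both
    genomic continuations; nt bases align to neither side. Exactly one of
    mh_len>0 or nt_len>0 (or both zero) holds by construction, and the result
    is symmetric in the segment order.
    """
    read = cand.sequence.upper()
    n = len(read)
    # order-insensitive: A is always the upstream (read-orientation) segment
    a, b = sorted((cand.seg_a, cand.seg_b), key=lambda s: (s.read_lo, s.read_hi))
    tseq_a = genome.chromosomes[a.record.chrom].upper()
    tseq_b = genome.chromosomes[b.record.chrom].upper()
    eA = a.read_hi
    while eA < n:
        base = a.record.frame_base(tseq_a, eA)
        if base is None or base != read[eA]:
            break
        eA += 1
    sB = b.read_lo
    while sB > 0:
        base = b.record.frame_base(tseq_b, sB - 1)
        if base is None or base != read[sB - 1]:
            break
        sB -= 1
    if sB <= eA:
        cand.mh_len, cand.nt_len, cand.nt_seq = eA - sB, 0, ""
        cand.junction_lo, cand.junction_hi = sB, eA
    else:
        cand.mh_len, cand.nt_len, cand.nt_seq = 0, sB - eA, read[eA:sB]
        cand.junction_lo, cand.junction_hi = eA, sB
    return cand.mh_len, cand.nt_len, cand.nt_seq


def filter_artifacts(
    cands: list[FusionCandidate],
    genes: list[GeneModel],
    pseudogene_pairs: list[tuple[str, str]],
    genome: ToyGenome,
    config: PipelineConfig,
) -> list[FusionCandidate]:
    """Flag (never delete) artifacts: DpnII GATC at the junction, same-gene
    chimeras, gene/pseudogene pairs, and segments outside annotated exons."""
    pairs = {frozenset(p) for p in pseudogene_pairs}
    for cand in cands:
        reasons = []
        margin = config.fusion_gatc_margin
        jlo, jhi = cand.junction_lo - margin, cand.junction_hi + margin
        if any(p < jhi and p + 4 > jlo for p in gatc_positions(cand.sequence)):
            reasons.append("dpnii_junction")

        def seg_gene(seg: Segment) -> str | None:
            hits = {}
            for g in genes:
                if g.chrom != seg.record.chrom:
                    continue
                ov = sum(
                    overlap(iv, ex)
                    for iv in seg.record.target_intervals()
                    for ex in g.exons
                )
                if ov:
                    hits[g.gene_id] = ov
            if not hits:
                return None
            return max(hits, key=hits.get)

        cand.gene_a = seg_gene(cand.seg_a)
        cand.gene_b = seg_gene(cand.seg_b)
        if cand.gene_a is None or cand.gene_b is None:
            reasons.append("non_exonic")
        elif cand.gene_a == cand.gene_b:
            reasons.append("same_gene")
        elif frozenset((cand.gene_a, cand.gene_b)) in pairs:
            reasons.append("pseudogene_pair")
        cand.artifact = bool(reasons)
        cand.artifact_reasons = reasons
    return cands


def merge_candidates(cands: list[FusionCandidate]) -> list[FusionCandidate]:
    """Merge per-read candidates reporting the same junction loci.

    A merged junction keeps only the artifact reasons shown by *every*
    contributing read: a single clean junction-spanning read (no ligation
    GATC) demonstrates the junction exists without the artifact signature,
    so it rescues the event. Junction-level reasons (same gene, pseudogene
    pair, non-exonic) are identical across reads and survive unchanged.
    """
    merged: dict[tuple, FusionCandidate] = {}
    for cand in cands:
        ra, rb = cand.seg_a.record, cand.seg_b.record
        hit = None
        for key, m in merged.items():
            ma, mb = m.seg_a.record, m.seg_b.record
            if (
                ra.chrom == ma.chrom
                and rb.chrom == mb.chrom
                and overlap((ra.tstart, ra.tend), (ma.tstart, ma.tend))
                and overlap((rb.tstart, rb.tend), (mb.tstart, mb.tend))
            ):
                hit = m
                break
        if hit is None:
            merged[cand.key + (len(merged),)] = cand
        else:
            hit.read_ids.extend(cand.read_ids)
            hit.artifact = hit.artifact and cand.artifact
            hit.artifact_reasons = [
                r for r in hit.artifact_reasons if r in cand.artifact_reasons
            ]
    return list(merged.values())


def support_depth(
    cand: FusionCandidate,
    all_reads: dict[str, str],
    read_library: dict[str, str | None],
    config: PipelineConfig,
) -> dict[str, int]:
    """Reads containing the junction-spanning probe (+/- ``support_flank``
    around the junction midpoint) at >=95% identity, split by strict-mode
    library; reads of undefined origin are tallied under 'U'."""
    flank = config.support_flank
    mid = (cand.junction_lo + cand.junction_hi) // 2
    lo, hi = max(0, mid - flank), min(len(cand.sequence), mid + flank)
    probe = cand.sequence[lo:hi].upper()
    probe_rc = revcomp(probe)
    k = int(len(probe) * (1.0 - config.support_min_identity))
    counts: dict[str, int] = {}
    for rid, seq in all_reads.items():
        s = seq.upper()
        hit = edlib.align(probe, s, mode="HW", task="distance", k=k)["editDistance"] >= 0
        if not hit:
            hit = edlib.align(probe_rc, s, mode="HW", task="distance", k=k)["editDistance"] >= 0
        if hit:
            lib = read_library.get(rid) or "U"
            counts[lib] = counts.get(lib, 0) + 1
    cand.support = counts
    return counts


def write_candidates_tsv(cands: list[FusionCandidate], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene_a\tgene_b\tchrom_a\tchrom_b\tclass\tn_reads\tsupport_total\t"
            "support\tMH\tNT\tnt_seq\tartifact\treasons\n"
        )
        for c in cands:
            supp = ",".join(f"{k}:{v}" for k, v in sorted(c.support.items()))
            fh.write(
                f"{c.gene_a}\t{c.gene_b}\t{c.chrom_a}\t{c.chrom_b}\t{c.cls}\t"
                f"{len(c.read_ids)}\t{c.support_total}\t{supp}\t{c.mh_len}\t"
                f"{c.nt_len}\t{c.nt_seq}\t{int(c.artifact)}\t{','.join(c.artifact_reasons)}\n"
            )
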