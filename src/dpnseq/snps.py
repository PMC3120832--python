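"""Pileup-based SNP candidate discovery from single-hit complete alignments.

The filter dimensions follow the study design: per-library base coverage,
proximity to exon-intron boundaries, proximity to alignment ends, the number
of distinct non-reference bases at the site (biallelic only), the
divergent/reference ratio, presence in both libraries, and the
validation-stage context rules (no second mismatch within a 50 bp window, no
homopolymer runs, no repeat-masked reference). Per-read bases within
``snp_end_margin`` of an alignment end are excluded from the pileup, so
every counted supporting base honours the end-distance filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .align import AlignmentRecord
from .config import PipelineConfig
from .genome import GeneModel, ToyGenome
from .util import homopolymer_run, revcomp

_ENC = {b: i for i, b in enumerate("ACGT")}


@dataclass
class SNPCandidate:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    depth: dict[str, int]
    alt_count: dict[str, int]
    boundary_dist: int
    end_dist: int
    window_mismatches: int  # other divergent positions within the 50 bp window
    homopolymer: bool
    repeat: bool
    present_in_both: bool
    zygosity: dict[str, str] = field(default_factory=dict)
    known: bool | None = None
    region: str | None = None  # UTR5 | CDS | UTR3 | noncoding
    consequence: str | None = None  # synonymous | non_synonymous | None

    @property
    def total_depth(self) -> int:
        return sum(self.depth.values())

    @property
    def total_alt(self) -> int:
        return sum(self.alt_count.values())

    @property
    def alt_ratio(self) -> float:
        return self.total_alt / self.total_depth if self.total_depth else 0.0


class Pileup:
    """Per-position, per-library base counts with end-distance tracking."""

    def __init__(self, chrom_lengths: dict[str, int], libraries: list[str]):
        self.libraries = libraries
        self.depth = {
            lib: {c: np.zeros(n, dtype=np.int32) for c, n in chrom_lengths.items()}
            for lib in libraries
        }
        # (chrom, pos) -> {lib: {base: count}}, plus min end distance per base
        self.mismatches: dict[tuple[str, int], dict] = {}

    def divergent_positions(self) -> list[tuple[str, int]]:
        return sorted(self.mismatches)


def pileup(
    records: dict[str, AlignmentRecord],
    read_seqs: dict[str, str],
    genome: ToyGenome,
    read_library: dict[str, str | None],
    config: PipelineConfig,
) -> Pileup:
    """Build the pileup from single-hit records; reads without a strict-mode
    library tag carry no per-library evidence and are skipped."""
    libs = sorted({lib for lib in read_library.values() if lib})
    pile = Pileup({c: len(s) for c, s in genome.chromosomes.items()}, libs)
    margin = config.snp_end_margin
    enc_chrom = {
        c: np.frombuffer(s.upper().encode(), dtype=np.uint8) for c, s in genome.chromosomes.items()
    }
    for rid in sorted(records):
        lib = read_library.get(rid)
        if not lib:
            continue
        rec = records[rid]
        seq = read_seqs[rid]
        aln_q = seq.upper() if rec.strand == "+" else revcomp(seq).upper()
        enc_q = np.frombuffer(aln_q.encode(), dtype=np.uint8)
        lo, hi = rec.qstart + margin, rec.qend - margin
        tarr = enc_chrom[rec.chrom]
        darr = pile.depth[lib][rec.chrom]
        for q0, t0, ln in rec.blocks:
            qa, qb = max(q0, lo), min(q0 + ln, hi)
            if qb <= qa:
                continue
            ta = t0 + (qa - q0)
            tb = t0 + (qb - q0)
            darr[ta:tb] += 1
            neq = np.nonzero(enc_q[qa:qb] != tarr[ta:tb])[0]
            for off in neq.tolist():
                qpos = qa + off
                tpos = ta + off
                base = aln_q[qpos]
                end_dist = min(qpos - rec.qstart, rec.qend - 1 - qpos)
                entry = pile.mismatches.setdefault(
                    (rec.chrom, tpos), {"counts": {}, "end_dist": {}}
                )
                cnts = entry["counts"].setdefault(lib, {})
                cnts[base] = cnts.get(base, 0) + 1
                ed = entry["end_dist"]
                ed[base] = min(ed.get(base, 10**9), end_dist)
    return pile


def _boundaries(genes: list[GeneModel]) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for g in genes:
        bs = out.setdefault(g.chrom, [])
        for s, e in g.introns():
            bs.extend((s, e))
    for c in out:
        out[c].sort()
    return out


def call_candidates(
    pile: Pileup,
    genome: ToyGenome,
    genes: list[GeneModel],
    config: PipelineConfig,
) -> tuple[list[SNPCandidate], list[tuple[str, int, str]]]:
    """Emit candidates passing every filter; returns (candidates, rejects)
    where rejects are (chrom, pos, reason). Every filter value is stored on
    the candidate so it can be re-asserted post hoc."""
    bounds = _boundaries(genes)
    divergent = pile.divergent_positions()
    div_by_chrom: dict[str, list[int]] = {}
    for c, p in divergent:
        div_by_chrom.setdefault(c, []).append(p)
    cands: list[SNPCandidate] = []
    rejects: list[tuple[str, int, str]] = []
    for chrom, pos in divergent:
        entry = pile.mismatches[(chrom, pos)]
        ref = genome.chromosomes[chrom][pos]
        ref_u = ref.upper()
        totals: dict[str, int] = {}
        for lib_counts in entry["counts"].values():
            for b, n in lib_counts.items():
                totals[b] = totals.get(b, 0) + n
        alts = [b for b in totals if b != ref_u]
        if len(alts) > 1:
            rejects.append((chrom, pos, "triallelic"))
            continue
        alt = alts[0]
        depth = {lib: int(pile.depth[lib][chrom][pos]) for lib in pile.libraries}
        alt_count = {lib: entry["counts"].get(lib, {}).get(alt, 0) for lib in pile.libraries}
        cand = SNPCandidate(
            chrom=chrom,
            pos=pos,
            ref=ref_u,
            alt=alt,
            depth=depth,
            alt_count=alt_count,
            boundary_dist=min(
                (abs(pos - b) for b in bounds.get(chrom, [])), default=10**9
            ),
            end_dist=entry["end_dist"][alt],
            window_mismatches=sum(
                1
                for p in div_by_chrom[chrom]
                if p != pos and abs(p - pos) < config.snp_window
            ),
            homopolymer=homopolymer_run(genome.chromosomes[chrom], pos)
            >= config.homopolymer_min_run,
            repeat=ref.islower(),
            present_in_both=len(pile.libraries) >= 2
            and all(alt_count[lib] >= 1 for lib in pile.libraries),
        )
        reason = None
        if any(depth[lib] < config.snp_min_depth for lib in pile.libraries):
            reason = "depth"
        elif not cand.present_in_both:
            reason = "single_library"
        elif cand.alt_ratio < config.snp_min_alt_ratio:
            reason = "ratio"
        elif cand.boundary_dist < config.snp_min_boundary_dist:
            reason = "boundary"
        elif cand.end_dist < config.snp_end_margin:
            reason = "alignment_end"
        elif cand.window_mismatches > 0:
            reason = "window"
        elif cand.homopolymer:
            reason = "homopolymer"
        elif cand.repeat:
            reason = "repeat"
        if reason:
            rejects.append((chrom, pos, reason))
            continue
        for lib in pile.libraries:
            r = alt_count[lib] / depth[lib] if depth[lib] else 0.0
            cand.zygosity[lib] = "hom" if r >= config.snp_hom_ratio else "het"
        cands.append(cand)
    return cands, rejects


def annotate_candidates(
    cands: list[SNPCandidate],
    known_snps: list[tuple[str, int, str, str]],
    genes: list[GeneModel],
    genome: ToyGenome,
) -> list[SNPCandidate]:
    """Known/novel status against a local known-SNP list, plus gene region
    (UTR5/CDS/UTR3/noncoding) and coding consequence by CDS translation."""
    known = {(c, p): (r, a) for c, p, r, a in known_snps}
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for cand in cands:
        hit = known.get((cand.chrom, cand.pos))
        cand.known = hit is not None and cand.alt in hit
        host = next(
            (
                g
                for g in genes
                if g.chrom == cand.chrom and not g.is_pseudogene
                and g.genomic_to_tx(cand.pos) is not None
            ),
            None,
        )
        if host is None:
            cand.region = "noncoding"
            continue
        tpos = host.genomic_to_tx(cand.pos)
        if host.cds is None:
            cand.region = "noncoding"
            continue
        cs, ce = host.cds
        ta, tb = host.genomic_to_tx(cs), host.genomic_to_tx(ce - 1)
        lo, hi = min(ta, tb), max(ta, tb) + 1
        if tpos < lo:
            cand.region = "UTR5"
        elif tpos >= hi:
            cand.region = "UTR3"
        else:
            cand.region = "CDS"
            if (hi - lo) % 3 != 0:
                cand.consequence = None  # CDS not a multiple of 3
                continue
            tx = host.transcript_seq(genome.chromosomes[host.chrom])
            off = tpos - lo
            ci = off // 3
            codon = tx[lo + 3 * ci : lo + 3 * ci + 3]
            alt_tx = cand.alt if host.strand == "+" else comp[cand.alt]
            alt_codon = codon[: off % 3] + alt_tx + codon[off % 3 + 1 :]
            same = str(Seq(codon).translate()) == str(Seq(alt_codon).translate())
            cand.consequence = "synonymous" if same else "non_synonymous"
    return cands


def novel_fraction(cands: list[SNPCandidate]) -> float:
    if not cands:
        return 0.0
    return sum(1 for c in cands if not c.known) / len(cands)


def write_candidates_tsv(cands: list[SNPCandidate], path) -> None:
    cols = (
        "CHROM\tPOS\tREF\tALT\tKNOWN\tREGION\tCONSEQUENCE\tBOUNDARY_DIST\t"
        "END_DIST\tINFO\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for c in cands:
            info = ";".join(
                f"{lib}:AD={c.alt_count[lib]},DP={c.depth[lib]},GT={c.zygosity.get(lib, '.')}"
                for lib in sorted(c.depth)
            )
            fh.write(
                f"{c.chrom}\t{c.pos + 1}\t{c.ref}\t{c.alt}\t"
                f"{'known' if c.known else 'novel'}\t{c.region}\t{c.consequence}\t"
                f"{c.boundary_dist}\t{c.end_dist}\t{info}\n"
            )
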