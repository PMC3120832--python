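"""Toy genome and gene models.

Coordinates are 0-based half-open throughout the package; GFF3 output is
1-based per the format. Multi-exon gene introns are canonical (GT..AG on the
coding strand) by construction unless an event is explicitly planted
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .util import revcomp


@dataclass(frozen=True)
class GeneModel:
    """An annotated transcription unit with one constitutive isoform."""

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]
    cds: tuple[int, int] | None = None
    is_pseudogene: bool = False

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def tx_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def introns(self) -> list[tuple[int, int]]:
        return [(self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)]

    def transcript_seq(self, chrom_seq: str) -> str:
        s = "".join(chrom_seq[a:b] for a, b in self.exons).upper()
        return revcomp(s) if self.strand == "-" else s

    def genomic_to_tx(self, pos: int) -> int | None:
        """Transcript coordinate of a genomic position, or None if intronic."""
        off = 0
        for a, b in self.exons:
            if a <= pos < b:
                t = off + (pos - a)
                return self.tx_length - 1 - t if self.strand == "-" else t
            off += b - a
        return None

    def tx_to_genomic(self, tpos: int) -> int:
        """Genomic coordinate of a transcript position."""
        if not 0 <= tpos < self.tx_length:
            raise IndexError(f"transcript position {tpos} outside {self.gene_id}")
        if self.strand == "-":
            tpos = self.tx_length - 1 - tpos
        off = 0
        for a, b in self.exons:
            if tpos < off + (b - a):
                return a + (tpos - off)
            off += b - a
        raise AssertionError("unreachable")


@dataclass
class ToyGenome:
    """A small multi-chromosome genome plus its gene annotation."""

    chromosomes: dict[str, str]
    genes: list[GeneModel] = field(default_factory=list)
    pseudogene_pairs: list[tuple[str, str]] = field(default_factory=list)

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def transcript(self, gene_id: str) -> str:
        g = self.gene(gene_id)
        return g.transcript_seq(self.chromosomes[g.chrom])

    def validate(self) -> None:
        """Assert the structural invariants of the annotation."""
        for g in self.genes:
            if g.chrom not in self.chromosomes:
                raise ValueError(f"{g.gene_id}: unknown chromosome {g.chrom}")
            clen = len(self.chromosomes[g.chrom])
            if not g.exons:
                raise ValueError(f"{g.gene_id}: no exons")
            prev_end = -1
            for a, b in g.exons:
                if not (0 <= a < b <= clen):
                    raise ValueError(f"{g.gene_id}: exon ({a},{b}) outside chromosome")
                if a <= prev_end:
                    raise ValueError(f"{g.gene_id}: exons overlap or are unsorted")
                prev_end = b
            seq = self.chromosomes[g.chrom].upper()
            for s, e in g.introns():
                don, acc = seq[s : s + 2], seq[e - 2 : e]
                ok = (don, acc) == ("GT", "AG") if g.strand == "+" else (don, acc) == ("CT", "AC")
                if not ok:
                    raise ValueError(f"{g.gene_id}: non-canonical intron ({s},{e}) {don}..{acc}")
            if g.cds is not None:
                cs, ce = g.cds
                span = g.span
                if not (span[0] <= cs < ce <= span[1]):
                    raise ValueError(f"{g.gene_id}: CDS outside exon union")

    # ---------------------------------------------------------------- output
    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.chromosomes.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    def write_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in self.genes:
                s, e = g.span
                bt = "pseudogene" if g.is_pseudogene else "gene"
                fh.write(
                    f"{g.chrom}\tdpnseq\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id};biotype={bt}\n"
                )
                for i, (a, b) in enumerate(g.exons, 1):
                    fh.write(
                        f"{g.chrom}\tdpnseq\texon\t{a + 1}\t{b}\t.\t{g.strand}\t.\t"
                        f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                    )

    def write_bed(self, path: str | Path) -> None:
        """BED12, one line per gene."""
        with open(path, "w") as fh:
            for g in self.genes:
                s, e = g.span
                sizes = ",".join(str(b - a) for a, b in g.exons)
                starts = ",".join(str(a - s) for a, b in g.exons)
                fh.write(
                    f"{g.chrom}\t{s}\t{e}\t{g.gene_id}\t0\t{g.strand}\t{s}\t{e}\t0\t"
                    f"{len(g.exons)}\t{sizes},\t{starts},\n"
                )
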