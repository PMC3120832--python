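"""Toy genome construction, ground-truth event planting, and library simulation.

The simulator emulates the barcoded DpnII library protocol: poly(A)+
transcripts are sampled per their configured abundance, digested at every
GATC (cutting 5' of the site, so internal fragments begin with GATC),
size-selected to the 150-600 nt window, and emitted as single-end reads of
the form adapter + 4-nt tag + GATC-starting insert with flat per-base
substitution errors and matching Phred qualities. Ground truth (SNPs,
splice-variant isoforms, intergenic novel genes, fusions with planted
microhomology or non-templated junction bases, and DpnII-junction chimeric
artifacts) is machine-readable so every downstream stage can be scored.

Planting guarantees recoverability: GATC sites are forced a fixed distance
either side of each planted junction and accidental GATC occurrences are
edited out of the protected span, so a size-selected fragment always spans
the event with generous anchors.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .config import SimConfig
from .genome import GeneModel, ToyGenome
from .util import child_rng, digest, gatc_positions, homopolymer_run, revcomp

_BASES = "ACGT"
_COMP1 = {"A": "T", "C": "G", "G": "C", "T": "A"}

# tx-space geometry of a planted junction's guaranteed spanning fragment
_FORCE_DIST = 82  # GATC forced this far either side of the outermost junctions
_PROTECT_PAD = 86


class PlantingError(ValueError):
    pass


# --------------------------------------------------------------------- truth
@dataclass
class PlantedSNP:
    chrom: str
    pos: int  # 0-based genomic
    ref: str
    alt: str
    gene_id: str
    known: bool
    zygosity: dict[str, str]  # sample -> 'hom' | 'het'


@dataclass
class PlantedIsoform:
    isoform_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    category: str  # expected SpliceEvent category
    coords: tuple[int, int]  # expected event coordinates (genomic)
    abundance: dict[str, float]

    def model(self) -> GeneModel:
        return GeneModel(self.isoform_id, self.chrom, self.strand, self.exons)


@dataclass
class PlantedNovelGene:
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    min_distance: int  # to the nearest annotated gene
    abundance: dict[str, float]

    @property
    def multi_exon(self) -> bool:
        return len(self.exons) > 1

    def model(self) -> GeneModel:
        return GeneModel(self.gene_id, self.chrom, self.strand, self.exons)


@dataclass
class PlantedFusion:
    fusion_id: str
    gene_a: str
    gene_b: str
    chrom_a: str
    pos_a: int  # genomic coordinate of the junction on the A side (end, exclusive)
    chrom_b: str
    pos_b: int  # genomic coordinate of the junction on the B side (start)
    cls: str  # 'inter' | 'intra'
    mh_len: int
    nt_seq: str
    origin: str  # 'genomic' | 'trans_splicing'
    tx_seq: str  # the chimeric fragment (GATC-leading)
    junction: int  # junction position within tx_seq (end of the A segment)
    abundance: dict[str, float]


@dataclass
class GroundTruth:
    snps: list[PlantedSNP] = field(default_factory=list)
    isoforms: list[PlantedIsoform] = field(default_factory=list)
    novel_genes: list[PlantedNovelGene] = field(default_factory=list)
    fusions: list[PlantedFusion] = field(default_factory=list)
    erbb2_gene: str | None = None  # the planted high-fold gene
    erbb2_fold: float = 1.0

    def is_empty(self) -> bool:
        return not (self.snps or self.isoforms or self.novel_genes or self.fusions)

    def known_snp_list(self) -> list[tuple[str, int, str, str]]:
        return [(s.chrom, s.pos, s.ref, s.alt) for s in self.snps if s.known]

    def to_json(self, path: str | Path) -> None:
        obj = {
            "snps": [asdict(s) for s in self.snps],
            "isoforms": [asdict(i) for i in self.isoforms],
            "novel_genes": [asdict(n) for n in self.novel_genes],
            "fusions": [asdict(f) for f in self.fusions],
            "erbb2_gene": self.erbb2_gene,
            "erbb2_fold": self.erbb2_fold,
        }
        Path(path).write_text(json.dumps(obj, indent=1, default=list))


@dataclass
class EventPlan:
    """How many of each ground-truth event to plant (auto-placed)."""

    n_snps: int = 8
    n_known_snps: int = 5
    n_inclusions: int = 3
    n_skips: int = 2
    n_alt_donor: int = 2
    n_alt_acceptor: int = 2
    n_retention: int = 2
    n_novel_multi: int = 2
    n_novel_single: int = 1
    # (class, mh_len, nt_seq) triples
    fusions: tuple = (("inter", 10, ""), ("intra", 4, ""), ("inter", 0, "CA"))
    fold_gene: float = 15.0
    explicit_snps: tuple = ()  # optional (chrom, pos, alt) triples

    @classmethod
    def none(cls) -> "EventPlan":
        return cls(0, 0, 0, 0, 0, 0, 0, 0, 0, (), 1.0)


# ------------------------------------------------------------------- editor
class _Editor:
    """Mutable view of the chromosomes with a collision registry."""

    def __init__(self, chromosomes: dict[str, str]):
        self.seqs = {c: bytearray(s, "ascii") for c, s in chromosomes.items()}
        self.reserved: dict[str, list[tuple[int, int]]] = {c: [] for c in chromosomes}
        self.locked: dict[str, set[int]] = {c: set() for c in chromosomes}

    def get(self, chrom: str, a: int, b: int) -> str:
        return self.seqs[chrom][a:b].decode()

    def put(self, chrom: str, pos: int, s: str) -> None:
        self.seqs[chrom][pos : pos + len(s)] = s.encode()

    def lock(self, chrom: str, a: int, b: int) -> None:
        self.locked[chrom].update(range(a, b))

    def reserve(self, chrom: str, a: int, b: int, pad: int = 50) -> None:
        for ra, rb in self.reserved[chrom]:
            if a - pad < rb and ra < b + pad:
                raise PlantingError(f"planted events collide on {chrom}: ({a},{b}) vs ({ra},{rb})")
        self.reserved[chrom].append((a, b))

    def finish(self) -> dict[str, str]:
        return {c: s.decode() for c, s in self.seqs.items()}


def _tx_view(ed: _Editor, model: GeneModel) -> str:
    s = "".join(ed.get(model.chrom, a, b) for a, b in model.exons).upper()
    return revcomp(s) if model.strand == "-" else s


def _write_tx(ed: _Editor, model: GeneModel, tpos: int, s: str) -> None:
    """Write ``s`` at transcript positions [tpos, tpos+len) through the exon map."""
    if model.strand == "-":
        s = revcomp(s)
        g = [model.tx_to_genomic(tpos + len(s) - 1 - i) for i in range(len(s))]
    else:
        g = [model.tx_to_genomic(tpos + i) for i in range(len(s))]
    if g != list(range(g[0], g[0] + len(s))):
        raise PlantingError("transcript span crosses an exon boundary")
    if any(p in ed.locked[model.chrom] for p in g):
        raise PlantingError("transcript span touches locked bases")
    ed.put(model.chrom, g[0], s)


def _sanitize(ed: _Editor, model: GeneModel, t0: int, t1: int) -> None:
    """Edit out every GATC whose occurrence overlaps tx span [t0, t1)."""
    for _ in range(200):
        tx = _tx_view(ed, model)
        hit = None
        for p in gatc_positions(tx):
            if p + 4 > t0 and p < t1:
                hit = p
                break
        if hit is None:
            return
        for off in range(4):
            tp = hit + off
            gp = model.tx_to_genomic(tp)
            if gp not in ed.locked[model.chrom]:
                new = {"G": "C", "A": "C", "T": "G", "C": "A"}[tx[tp]]
                ed.put(model.chrom, gp, _COMP1[new] if model.strand == "-" else new)
                break
        else:
            raise PlantingError("cannot sanitize GATC: all bases locked")
    raise PlantingError("sanitize did not converge")


def _force_gatc(ed: _Editor, model: GeneModel, tpos: int) -> None:
    _write_tx(ed, model, tpos, "GATC")
    for i in range(4):
        ed.lock(model.chrom, model.tx_to_genomic(tpos + i), model.tx_to_genomic(tpos + i) + 1)


def _guard_junctions(ed: _Editor, model: GeneModel, junctions: list[int]) -> None:
    """Sanitize around the junctions and force the flanking GATC pair so a
    size-selected fragment always spans every junction with wide anchors."""
    j0, j1 = min(junctions), max(junctions)
    t0, t1 = j0 - _PROTECT_PAD, j1 + _PROTECT_PAD
    if t0 < 0 or t1 > model.tx_length:
        raise PlantingError("junction too close to transcript end")
    _sanitize(ed, model, t0, t1)
    _force_gatc(ed, model, j0 - _FORCE_DIST)
    _force_gatc(ed, model, j1 + _FORCE_DIST - 4)


# ------------------------------------------------------------- genome build
def _random_seq(rng: np.random.Generator, n: int) -> bytearray:
    return bytearray(bytes(np.frombuffer(b"ACGT", dtype=np.uint8)[rng.integers(0, 4, n)]))


def _set_intron_sites(seq: bytearray, exons: list[tuple[int, int]], strand: str) -> None:
    for (a0, b0), (a1, b1) in zip(exons, exons[1:]):
        s, e = b0, a1
        if strand == "+":
            seq[s : s + 2] = b"GT"
            seq[e - 2 : e] = b"AG"
        else:
            seq[s : s + 2] = b"CT"
            seq[e - 2 : e] = b"AC"


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    n_mut = int(round(rate * len(seq)))
    for p in rng.choice(len(seq), size=n_mut, replace=False):
        choices = [b for b in _BASES if b != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return "".join(out)


def _eligible_fragments(tx: str, window: tuple[int, int]) -> list[tuple[int, int]]:
    lo, hi = window
    return [
        (a, b)
        for a, b in digest(tx)
        if tx[a : a + 4].upper() == "GATC" and lo <= b - a <= hi
    ]


def _ensure_digestible(ed: _Editor, model: GeneModel, window: tuple[int, int]) -> None:
    tx = _tx_view(ed, model)
    if _eligible_fragments(tx, window) or model.tx_length < window[0] + 15:
        return
    p = 15
    while p < model.tx_length - window[0]:
        try:
            _write_tx(ed, model, p, "GATC")
        except PlantingError:
            pass
        p += 400
    # leave as-is if still dark; the simulator logs unproductive transcripts


def generate_genome(config: SimConfig) -> ToyGenome:
    """Build the toy genome: >=2 chromosomes, single- and multi-exon genes
    with canonical introns, and one gene/processed-pseudogene pair."""
    rng = child_rng(config.seed, 11)
    chrom_names = [f"chr{i + 1}" for i in range(len(config.chrom_lengths))]
    seqs = {name: _random_seq(rng, L) for name, L in zip(chrom_names, config.chrom_lengths)}

    desert_chrom, desert_lo, _ = config.desert
    limits = {}
    for name, L in zip(chrom_names, config.chrom_lengths):
        hi = min(L - 4000, desert_lo - 2000) if name == desert_chrom else L - 4000
        limits[name] = (2500, hi)
    total_room = sum(hi - lo for lo, hi in limits.values())

    genes: list[GeneModel] = []
    gid = 0
    exon_weights = [0.12, 0.13, 0.2, 0.2, 0.2, 0.15]
    for name in chrom_names:
        lo, hi = limits[name]
        share = int(round(config.n_genes * (hi - lo) / total_room))
        cursor = lo
        for _ in range(share):
            if gid >= config.n_genes:
                break
            n_ex = int(rng.choice(np.arange(1, 7), p=exon_weights))
            if n_ex == 1:
                ex_lens = [int(rng.integers(400, 800))]
                in_lens = []
            else:
                ex_lens = [int(x) for x in rng.integers(120, 281, n_ex)]
                in_lens = [int(x) for x in rng.integers(80, 401, n_ex - 1)]
            span = sum(ex_lens) + sum(in_lens)
            if cursor + span > hi:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            p = cursor
            for i, el in enumerate(ex_lens):
                exons.append((p, p + el))
                p += el
                if i < len(in_lens):
                    p += in_lens[i]
            _set_intron_sites(seqs[name], exons, strand)
            gid += 1
            genes.append(GeneModel(f"G{gid:02d}", name, strand, tuple(exons)))
            cursor += span + int(rng.integers(1800, 3200))

    # CDS for every gene long enough (length a multiple of 3 by construction)
    final_genes = []
    for g in genes:
        cds = None
        if g.tx_length >= 150:
            cds_len = ((g.tx_length - 60) // 3) * 3
            t0, t1 = 30, 30 + cds_len
            ga = g.tx_to_genomic(t0)
            gb = g.tx_to_genomic(t1 - 1)
            cds = (min(ga, gb), max(ga, gb) + 1)
        final_genes.append(GeneModel(g.gene_id, g.chrom, g.strand, g.exons, cds=cds))
    genes = final_genes

    # processed pseudogene: intronless, ~97% identical copy of a parent mRNA
    pairs = []
    parent = next((g for g in genes if len(g.exons) >= 3 and g.strand == "+"), None)
    if parent is not None:
        ptx = parent.transcript_seq(seqs[parent.chrom].decode())
        pseudo_seq = _mutate(rng, ptx, 0.03)
        host = chrom_names[0]
        start = max(g.span[1] for g in genes if g.chrom == host) + 2500
        if start + len(pseudo_seq) < len(seqs[host]) - 500:
            seqs[host][start : start + len(pseudo_seq)] = pseudo_seq.encode()
            pg = GeneModel("PSG1", host, "+", ((start, start + len(pseudo_seq)),), is_pseudogene=True)
            genes.append(pg)
            pairs.append((parent.gene_id, "PSG1"))

    genome = ToyGenome({n: s.decode() for n, s in seqs.items()}, genes, pairs)
    ed = _Editor(genome.chromosomes)
    for g in genome.genes:
        if not g.is_pseudogene:
            _ensure_digestible(ed, g, config.size_window)
    genome.chromosomes = ed.finish()
    genome.validate()
    return genome


def generate_contaminants(config: SimConfig) -> dict[str, str]:
    """rRNA / mitochondrial surrogate sequences for the contaminant screen."""
    rng = child_rng(config.seed, 13)
    return {
        "rRNA_surrogate": _random_seq(rng, 1500).decode(),
        "mito_surrogate": _random_seq(rng, 2000).decode(),
    }


# ---------------------------------------------------------------- planting
def _usable_intron(g: GeneModel, min_len: int, max_len: int = 10**9) -> int | None:
    best = None
    for i, (s, e) in enumerate(g.introns()):
        if min_len <= e - s <= max_len:
            best = i
            break
    return best


def _tx_pos_of_boundary(model: GeneModel, gpos_first_base: int) -> int:
    """Transcript position of a genomic base (first transcribed base after a
    junction, in transcription order)."""
    t = model.genomic_to_tx(gpos_first_base)
    if t is None:
        raise PlantingError("boundary base is not exonic in the isoform")
    return t


class _Planter:
    def __init__(self, genome: ToyGenome, plan: EventPlan, seed: int, window: tuple[int, int]):
        self.genome = genome
        self.plan = plan
        self.rng = child_rng(seed, 77)
        self.window = window
        self.ed = _Editor(genome.chromosomes)
        self.truth = GroundTruth()
        self.used: set[str] = set(p for pair in genome.pseudogene_pairs for p in pair)
        self.iso_n = 0
        # lock annotated splice dinucleotides
        for g in genome.genes:
            for s, e in g.introns():
                self.ed.lock(g.chrom, s, s + 2)
                self.ed.lock(g.chrom, e - 2, e)

    # ------------------------------------------------------------- helpers
    def _candidates(self, min_exons: int = 1) -> list[GeneModel]:
        out = [
            g
            for g in self.genome.genes
            if not g.is_pseudogene and g.gene_id not in self.used and len(g.exons) >= min_exons
        ]
        order = self.rng.permutation(len(out))
        return [out[i] for i in order]

    def _new_iso_id(self) -> str:
        self.iso_n += 1
        return f"iso{self.iso_n:02d}"

    def _add_isoform(self, gene: GeneModel, exons, category, coords, abundance) -> None:
        iso = PlantedIsoform(
            self._new_iso_id(), gene.gene_id, gene.chrom, gene.strand, tuple(exons),
            category, tuple(coords), abundance,
        )
        self.truth.isoforms.append(iso)
        self.used.add(gene.gene_id)

    # -------------------------------------------------------------- events
    def plant_inclusion(self, abundance) -> None:
        exlen = 80
        for g in self._candidates(min_exons=2):
            ii = _usable_intron(g, 2 * 60 + exlen + 8)
            if ii is None:
                continue
            s, e = g.introns()[ii]
            estart = s + (e - s - exlen) // 2
            eend = estart + exlen
            try:
                self.ed.reserve(g.chrom, s, e)
            except PlantingError:
                continue
            if g.strand == "+":
                self.ed.put(g.chrom, estart - 2, "AG")
                self.ed.put(g.chrom, eend, "GT")
            else:
                self.ed.put(g.chrom, estart - 2, "AC")
                self.ed.put(g.chrom, eend, "CT")
            self.ed.lock(g.chrom, estart - 2, estart)
            self.ed.lock(g.chrom, eend, eend + 2)
            exons = sorted(list(g.exons) + [(estart, eend)])
            model = GeneModel("tmp", g.chrom, g.strand, tuple(exons))
            t0 = _tx_pos_of_boundary(model, estart if g.strand == "+" else eend - 1)
            t1 = t0 + exlen
            try:
                _guard_junctions(self.ed, model, [t0, t1])
            except PlantingError:
                continue
            self._add_isoform(g, exons, "exon_inclusion_both_flanks", (estart, eend), abundance)
            return
        raise PlantingError("no host gene for exon inclusion")

    def plant_skip(self, abundance) -> None:
        for g in self._candidates(min_exons=3):
            k = len(g.exons) // 2  # internal exon
            exons = [e for i, e in enumerate(g.exons) if i != k]
            model = GeneModel("tmp", g.chrom, g.strand, tuple(exons))
            later = g.exons[k + 1] if g.strand == "+" else g.exons[k - 1]
            gb = later[0] if g.strand == "+" else later[1] - 1
            j = _tx_pos_of_boundary(model, gb)
            if j < _PROTECT_PAD or model.tx_length - j < _PROTECT_PAD:
                continue
            try:
                self.ed.reserve(g.chrom, g.exons[k - 1][1], g.exons[k + 1][0])
                _guard_junctions(self.ed, model, [j])
            except PlantingError:
                continue
            self._add_isoform(
                g, exons, "exon_skipping", (g.exons[k - 1][1], g.exons[k + 1][0]), abundance
            )
            return
        raise PlantingError("no host gene for exon skipping")

    def plant_alt_site(self, kind: str, abundance) -> None:
        """kind: 'donor' or 'acceptor'; shifts the site 14 nt into the exon."""
        d = 14
        for g in self._candidates(min_exons=2):
            ii = _usable_intron(g, 60)
            if ii is None:
                continue
            s, e = g.introns()[ii]
            exons = list(g.exons)
            donor_like = (kind == "donor") == (g.strand == "+")
            if donor_like:
                # move the genomic-left boundary of the intron into exon ii
                a, b = exons[ii]
                if b - a < d + 40:
                    continue
                g_new = b - d
                exons[ii] = (a, g_new)
                dinuc = "GT" if g.strand == "+" else "CT"
                put_at = g_new
                coords = (g_new, e)
            else:
                a, b = exons[ii + 1]
                if b - a < d + 40:
                    continue
                g_new = a + d
                exons[ii + 1] = (g_new, b)
                dinuc = "AG" if g.strand == "+" else "AC"
                put_at = g_new - 2
                coords = (s, g_new)
            try:
                self.ed.reserve(g.chrom, min(coords) - 20, max(coords) + 20)
            except PlantingError:
                continue
            self.ed.put(g.chrom, put_at, dinuc)
            self.ed.lock(g.chrom, put_at, put_at + 2)
            model = GeneModel("tmp", g.chrom, g.strand, tuple(exons))
            later_gb = coords[1] if g.strand == "+" else coords[0] - 1
            j = _tx_pos_of_boundary(model, later_gb)
            if j < _PROTECT_PAD or model.tx_length - j < _PROTECT_PAD:
                continue
            try:
                _guard_junctions(self.ed, model, [j])
            except PlantingError:
                continue
            category = f"alt_{kind}"
            self._add_isoform(g, exons, category, coords, abundance)
            return
        raise PlantingError(f"no host gene for alt {kind}")

    def plant_retention(self, abundance) -> None:
        for g in self._candidates(min_exons=2):
            ii = _usable_intron(g, 60, 320)
            if ii is None:
                continue
            s, e = g.introns()[ii]
            exons = list(g.exons)
            merged = (exons[ii][0], exons[ii + 1][1])
            exons[ii : ii + 2] = [merged]
            model = GeneModel("tmp", g.chrom, g.strand, tuple(exons))
            first_intron_base = s if g.strand == "+" else e - 1
            j = _tx_pos_of_boundary(model, first_intron_base)
            if j < _PROTECT_PAD or model.tx_length - j < _PROTECT_PAD:
                continue
            try:
                self.ed.reserve(g.chrom, s, e)
                _guard_junctions(self.ed, model, [j])
            except PlantingError:
                continue
            self._add_isoform(g, exons, "intron_retention", (s, e), abundance)
            return
        raise PlantingError("no host gene for intron retention")

    def plant_novel_gene(self, multi: bool, start: int, abundance) -> PlantedNovelGene:
        desert_chrom = self._desert[0]
        if multi:
            exons = ((start, start + 160), (start + 280, start + 460))
            strand = "+"
            self.ed.put(desert_chrom, start + 160, "GT")
            self.ed.put(desert_chrom, start + 280 - 2, "AG")
            self.ed.lock(desert_chrom, start + 160, start + 162)
            self.ed.lock(desert_chrom, start + 278, start + 280)
        else:
            exons = ((start, start + 400),)
            strand = "+"
        model = GeneModel("tmp", desert_chrom, strand, exons)
        self.ed.reserve(desert_chrom, exons[0][0], exons[-1][1])
        if multi:
            j = 160
            _guard_junctions(self.ed, model, [j])
        else:
            _sanitize(self.ed, model, 16, 380)
            _force_gatc(self.ed, model, 20)
            _force_gatc(self.ed, model, 336)
        dist = min(
            abs(start - g.span[1]) if g.span[1] <= start else abs(g.span[0] - exons[-1][1])
            for g in self.genome.genes
        )
        ng = PlantedNovelGene(
            f"NG{len(self.truth.novel_genes) + 1}", desert_chrom, strand, exons, dist, abundance
        )
        self.truth.novel_genes.append(ng)
        return ng

    def plant_fusion(self, cls: str, mh_len: int, nt_seq: str, abundance) -> None:
        LA = LB = 110
        cands = [g for g in self._candidates(min_exons=1) if max(b - a for a, b in g.exons) >= 160]
        pair = None
        for i, ga in enumerate(cands):
            for gb in cands[i + 1 :]:
                if cls == "inter" and ga.chrom == gb.chrom:
                    continue
                if cls == "intra" and (
                    ga.chrom != gb.chrom or abs(ga.span[0] - gb.span[0]) < 30000
                ):
                    continue
                pair = (ga, gb)
                break
            if pair:
                break
        if pair is None:
            raise PlantingError(f"no gene pair for {cls} fusion")
        ga, gb = pair
        ea = max(ga.exons, key=lambda x: x[1] - x[0])
        eb = max(gb.exons, key=lambda x: x[1] - x[0])
        pa = ea[0] + 5 + LA  # junction: A side ends here (exclusive)
        pb = eb[0] + 10  # junction: B side starts here
        self.ed.reserve(ga.chrom, pa - LA - 4, pa + mh_len + 4)
        self.ed.reserve(gb.chrom, pb - 4, pb + LB + 4)
        # lead the A segment with a genomic GATC so the chimeric fragment is
        # exactly the digested genomic sequence
        self.ed.put(ga.chrom, pa - LA, "GATC")
        self.ed.lock(ga.chrom, pa - LA, pa - LA + 4)
        if mh_len:
            mh = self.ed.get(ga.chrom, pa, pa + mh_len).upper()
            self.ed.put(gb.chrom, pb, mh)
            self.ed.lock(gb.chrom, pb, pb + mh_len)
        # force divergence at the microhomology boundaries
        a_cont = self.ed.get(ga.chrom, pa + mh_len, pa + mh_len + 1).upper()
        b_at = self.ed.get(gb.chrom, pb + mh_len, pb + mh_len + 1).upper()
        if nt_seq == "" and a_cont == b_at:
            self.ed.put(gb.chrom, pb + mh_len, {"A": "C", "C": "A", "G": "T", "T": "G"}[b_at])
        a_last = self.ed.get(ga.chrom, pa - 1, pa).upper()
        b_prev = self.ed.get(gb.chrom, pb - 1, pb).upper()
        if nt_seq == "" and a_last == b_prev:
            self.ed.put(gb.chrom, pb - 1, {"A": "C", "C": "A", "G": "T", "T": "G"}[b_prev])
        if nt_seq:
            if nt_seq[0] == self.ed.get(ga.chrom, pa, pa + 1).upper():
                self.ed.put(ga.chrom, pa, {"A": "C", "C": "A", "G": "T", "T": "G"}[nt_seq[0]])
            if nt_seq[-1] == self.ed.get(gb.chrom, pb - 1, pb).upper():
                self.ed.put(gb.chrom, pb - 1, {"A": "C", "C": "A", "G": "T", "T": "G"}[nt_seq[-1]])
        # build the chimeric fragment and sanitize internal GATC on both loci
        def frag() -> str:
            return (
                self.ed.get(ga.chrom, pa - LA, pa).upper()
                + nt_seq
                + self.ed.get(gb.chrom, pb, pb + LB).upper()
            )

        for _ in range(50):
            f = frag()
            hits = [p for p in gatc_positions(f) if p > 0]
            if not hits:
                break
            p = hits[0]
            for off in range(4):
                q = p + off
                if q < LA:
                    chrom, gpos = ga.chrom, pa - LA + q
                elif q < LA + len(nt_seq):
                    chrom = None  # inside nt_seq; cannot happen for default seqs
                else:
                    chrom, gpos = gb.chrom, pb + (q - LA - len(nt_seq))
                if chrom and gpos not in self.ed.locked[chrom]:
                    old = f[q]
                    self.ed.put(chrom, gpos, {"G": "C", "A": "C", "T": "G", "C": "A"}[old])
                    break
            else:
                raise PlantingError("cannot sanitize fusion fragment")
        fus = PlantedFusion(
            f"FUS{len(self.truth.fusions) + 1}",
            ga.gene_id, gb.gene_id, ga.chrom, pa, gb.chrom, pb, cls, mh_len, nt_seq,
            "genomic" if cls == "inter" else "trans_splicing",
            frag(), LA, abundance,
        )
        self.truth.fusions.append(fus)
        self.used.update((ga.gene_id, gb.gene_id))

    def plant_snp(self, known: bool, zygosity: str, abundance) -> None:
        for g in self._candidates(min_exons=1):
            tx = _tx_view(self.ed, g)
            frags = _eligible_fragments(tx, self.window)
            placed = False
            for fa, fb in frags:
                for tp in range(fa + 25, fb - 25, 7):
                    gp = g.tx_to_genomic(tp)
                    exon = next((a, b) for a, b in g.exons if a <= gp < b)
                    if gp - exon[0] < 10 or exon[1] - gp <= 10:
                        continue
                    ctx = self.ed.get(g.chrom, gp - 6, gp + 7).upper()
                    if homopolymer_run(ctx, 6) >= 4:
                        continue
                    if "GATC" in tx[max(0, tp - 4) : tp + 5]:
                        continue
                    ref_tx = tx[tp]
                    alt_tx = None
                    for b in _BASES:
                        if b == ref_tx:
                            continue
                        ctx = tx[tp - 3 : tp] + b + tx[tp + 1 : tp + 4]
                        if "GATC" not in ctx:
                            alt_tx = b
                            break
                    if alt_tx is None:
                        continue
                    try:
                        self.ed.reserve(g.chrom, gp - 25, gp + 25, pad=50)
                    except PlantingError:
                        continue
                    ref_g = self.ed.get(g.chrom, gp, gp + 1).upper()
                    alt_g = alt_tx if g.strand == "+" else _COMP1[alt_tx]
                    self.truth.snps.append(
                        PlantedSNP(
                            g.chrom, gp, ref_g, alt_g, g.gene_id, known,
                            {s: zygosity for s in ("HB4a", "C5.2")},
                        )
                    )
                    placed = True
                    break
                if placed:
                    break
            if placed:
                self.used.add(g.gene_id)
                return
        raise PlantingError("no host position for SNP")

    # ---------------------------------------------------------------- main
    def run(self) -> tuple[ToyGenome, GroundTruth]:
        plan = self.plan
        for chrom, pos, alt in plan.explicit_snps:
            self.ed.reserve(chrom, pos - 25, pos + 25, pad=50)
            ref = self.ed.get(chrom, pos, pos + 1).upper()
            if ref == alt:
                raise PlantingError("explicit SNP alt equals reference")
            host = next((g for g in self.genome.genes if g.chrom == chrom and g.genomic_to_tx(pos) is not None), None)
            self.truth.snps.append(
                PlantedSNP(chrom, pos, ref, alt, host.gene_id if host else "", False,
                           {s: "hom" for s in ("HB4a", "C5.2")})
            )

        # desert: the region kept gene-free by the generator
        # (recomputed from the annotation: after the last gene on each chrom)
        last_end = {c: 0 for c in self.genome.chromosomes}
        for g in self.genome.genes:
            last_end[g.chrom] = max(last_end[g.chrom], g.span[1])
        desert_chrom = max(
            self.genome.chromosomes,
            key=lambda c: len(self.genome.chromosomes[c]) - last_end[c],
        )
        self._desert = (desert_chrom, last_end[desert_chrom])

        for i in range(plan.n_inclusions):
            self.plant_inclusion({"HB4a": 0.005, "C5.2": 0.010})
        for i in range(plan.n_skips):
            self.plant_skip({"HB4a": 0.005, "C5.2": 0.009})
        for i in range(plan.n_alt_donor):
            self.plant_alt_site("donor", {"HB4a": 0.005, "C5.2": 0.008})
        for i in range(plan.n_alt_acceptor):
            self.plant_alt_site("acceptor", {"HB4a": 0.005, "C5.2": 0.008})
        for i in range(plan.n_retention):
            self.plant_retention({"HB4a": 0.006, "C5.2": 0.006})

        start = last_end[desert_chrom] + 8200
        for i in range(plan.n_novel_multi):
            self.plant_novel_gene(True, start, {"HB4a": 0.006, "C5.2": 0.006})
            start += 2500
        for i in range(plan.n_novel_single):
            self.plant_novel_gene(False, start, {"HB4a": 0.006, "C5.2": 0.006})
            start += 2000

        fusion_ab = [
            {"HB4a": 0.005, "C5.2": 0.005},
            {"HB4a": 0.004, "C5.2": 0.004},
            {"HB4a": 0.0, "C5.2": 0.008},
        ]
        for i, (cls, mh, nt) in enumerate(plan.fusions):
            self.plant_fusion(cls, mh, nt, fusion_ab[i % len(fusion_ab)])

        for i in range(plan.n_snps):
            self.plant_snp(known=i < plan.n_known_snps, zygosity="hom" if i % 2 == 0 else "het",
                           abundance=None)

        if plan.fold_gene and plan.fold_gene != 1.0:
            for g in self._candidates():
                self.truth.erbb2_gene = g.gene_id
                self.truth.erbb2_fold = plan.fold_gene
                self.used.add(g.gene_id)
                break

        genome = ToyGenome(self.ed.finish(), self.genome.genes, self.genome.pseudogene_pairs)
        genome.validate()
        return genome, self.truth


def plant_events(
    genome: ToyGenome, plan: EventPlan, seed: int = 0, size_window: tuple[int, int] = (150, 600)
) -> tuple[ToyGenome, GroundTruth]:
    """Plant the requested ground-truth events; returns a new genome plus the
    machine-readable truth. An all-zero plan returns the genome unchanged."""
    if (
        plan.n_snps == 0 and plan.n_inclusions == 0 and plan.n_skips == 0
        and plan.n_alt_donor == 0 and plan.n_alt_acceptor == 0 and plan.n_retention == 0
        and plan.n_novel_multi == 0 and plan.n_novel_single == 0 and not plan.fusions
        and not plan.explicit_snps and (not plan.fold_gene or plan.fold_gene == 1.0)
    ):
        return genome, GroundTruth()
    return _Planter(genome, plan, seed, size_window).run()


# ----------------------------------------------------------------- profiles
def default_profiles(genome: ToyGenome, truth: GroundTruth) -> dict[str, dict[str, float]]:
    """Per-sample expression fractions over all transcription units.

    SNP host genes get 1.2% each; the planted high-fold gene gets 1.2% in
    HB4a and 1.2% x fold in C5.2; isoforms/novel genes/fusions use their
    planted abundances; the remaining mass is spread uniformly over the other
    annotated genes (pseudogene silent).
    """
    samples = ("HB4a", "C5.2")
    profiles: dict[str, dict[str, float]] = {s: {} for s in samples}
    snp_hosts = {s.gene_id for s in truth.snps if s.gene_id}
    for s in samples:
        prof = profiles[s]
        for snp_host in sorted(snp_hosts):
            prof[snp_host] = 0.012
        if truth.erbb2_gene:
            base = 0.012
            prof[truth.erbb2_gene] = base * (truth.erbb2_fold if s == "C5.2" else 1.0)
        for iso in truth.isoforms:
            prof[iso.isoform_id] = iso.abundance[s]
        for ng in truth.novel_genes:
            prof[ng.gene_id] = ng.abundance[s]
        for fu in truth.fusions:
            prof[fu.fusion_id] = fu.abundance[s]
        rest = [
            g.gene_id
            for g in genome.genes
            if not g.is_pseudogene and g.gene_id not in prof
        ]
        remaining = 1.0 - sum(prof.values())
        if remaining <= 0 or not rest:
            raise ValueError("expression fractions exceed 1")
        for gid in rest:
            prof[gid] = remaining / len(rest)
    return profiles


# ---------------------------------------------------------------- simulate
@dataclass
class SimRead:
    read_id: str
    sequence: str
    qualities: str


@dataclass
class ReadLogEntry:
    read_id: str
    sample: str
    kind: str  # gene | isoform | novel | fusion | artifact | contaminant
    origin: str
    adapter: str  # full | truncated | none
    frag: tuple[int, int] | None = None
    artifact_junction: int | None = None  # insert coordinate of the chimeric join


class SimulationResult:
    def __init__(self, reads: list[SimRead], log: dict[str, ReadLogEntry], skipped: list[str]):
        self.reads = reads
        self.log = log
        self.skipped = skipped  # units that yielded no eligible fragment


def _unit_sequences(
    genome: ToyGenome, truth: GroundTruth, sample: str
) -> dict[str, list[tuple[str, float]]]:
    """unit id -> [(haplotype sequence, weight)] for one sample."""
    snps_by_gene: dict[str, list[PlantedSNP]] = {}
    for s in truth.snps:
        snps_by_gene.setdefault(s.gene_id, []).append(s)
    units: dict[str, list[tuple[str, float]]] = {}
    for g in genome.genes:
        if g.is_pseudogene:
            continue
        tx = genome.transcript(g.gene_id)
        snps = snps_by_gene.get(g.gene_id, [])
        if not snps:
            units[g.gene_id] = [(tx, 1.0)]
            continue
        hets = [s for s in snps if s.zygosity[sample] == "het"]
        homs = [s for s in snps if s.zygosity[sample] == "hom"]

        def apply(txs: str, snp_list: list[PlantedSNP]) -> str:
            out = list(txs)
            for s in snp_list:
                tp = g.genomic_to_tx(s.pos)
                alt_tx = s.alt if g.strand == "+" else _COMP1[s.alt]
                out[tp] = alt_tx
            return "".join(out)

        base = apply(tx, homs)
        if hets:
            units[g.gene_id] = [(base, 0.5), (apply(base, hets), 0.5)]
        else:
            units[g.gene_id] = [(base, 1.0)]
    for iso in truth.isoforms:
        units[iso.isoform_id] = [(iso.model().transcript_seq(genome.chromosomes[iso.chrom]), 1.0)]
    for ng in truth.novel_genes:
        units[ng.gene_id] = [(ng.model().transcript_seq(genome.chromosomes[ng.chrom]), 1.0)]
    for fu in truth.fusions:
        units[fu.fusion_id] = [(fu.tx_seq, 1.0)]
    return units


def simulate_library(
    genome: ToyGenome,
    truth: GroundTruth,
    sample: str,
    config: SimConfig,
    contaminants: dict[str, str] | None = None,
) -> SimulationResult:
    """Simulate one sample's reads. Fixed seed => byte-identical output."""
    if sample not in config.barcodes:
        raise ValueError(f"sample {sample!r} has no barcode")
    samples = list(config.barcodes)
    rng = child_rng(config.seed, 101, samples.index(sample))
    if contaminants is None:
        contaminants = generate_contaminants(config)
    profiles = config.expression or default_profiles(genome, truth)
    prof = profiles[sample]
    units = _unit_sequences(genome, truth, sample)

    frag_table: dict[str, list[tuple[float, list[tuple[int, int]], str]]] = {}
    skipped: list[str] = []
    for uid, haps in units.items():
        rows = []
        for hseq, hw in haps:
            elig = _eligible_fragments(hseq, config.size_window)
            if elig:
                rows.append((hw, elig, hseq))
        if rows:
            frag_table[uid] = rows
        else:
            skipped.append(uid)

    unit_ids = [u for u in prof if u in frag_table and prof[u] > 0]
    weights = np.array([prof[u] for u in unit_ids], dtype=float)
    weights = weights / weights.sum()

    n_total = config.n_reads
    n_art = int(round(n_total * config.artifact_fraction))
    n_cont = int(round(n_total * config.contaminant_fraction))
    n_norm = n_total - n_art - n_cont

    tag = config.barcodes[sample]
    adapter = config.adapter
    err = config.error_rate
    q = 40 if err <= 0 else max(2, min(40, int(round(-10 * math.log10(err)))))
    qchar = chr(33 + q)

    reads: list[SimRead] = []
    log: dict[str, ReadLogEntry] = {}

    def draw_fragment() -> tuple[str, str, tuple[int, int]]:
        ui = int(rng.choice(len(unit_ids), p=weights))
        uid = unit_ids[ui]
        rows = frag_table[uid]
        if len(rows) == 1:
            hw, elig, hseq = rows[0]
        else:
            hi = int(rng.choice(len(rows), p=[r[0] for r in rows]))
            hw, elig, hseq = rows[hi]
        fi = int(rng.integers(0, len(elig)))
        a, b = elig[fi]
        return uid, hseq[a:b], (a, b)

    def finish(read_id: str, insert: str, kind: str, origin: str, frag, art_j=None) -> None:
        cap = int(rng.normal(config.read_cap_mean, config.read_cap_sd))
        cap = max(60, cap)
        insert = insert[:cap]
        r = rng.random()
        if r < config.adapterless_fraction:
            seq, adp = insert, "none"
        elif r < config.adapterless_fraction + config.adapter_truncated_fraction:
            seq, adp = adapter[-10:] + tag + insert, "truncated"
        else:
            seq, adp = adapter + tag + insert, "full"
        if err > 0:
            arr = list(seq)
            hits = np.nonzero(rng.random(len(arr)) < err)[0]
            for p in hits:
                cur = arr[p].upper()
                alts = [b for b in _BASES if b != cur]
                arr[p] = alts[int(rng.integers(0, 3))]
            seq = "".join(arr)
        reads.append(SimRead(read_id, seq, qchar * len(seq)))
        log[read_id] = ReadLogEntry(read_id, sample, kind, origin, adp, frag, art_j)

    for i in range(n_norm):
        uid, frag_seq, frag = draw_fragment()
        kind = "gene"
        if uid.startswith("iso"):
            kind = "isoform"
        elif uid.startswith("NG"):
            kind = "novel"
        elif uid.startswith("FUS"):
            kind = "fusion"
        finish(f"{sample}_{i:06d}", frag_seq, kind, uid, frag)

    lo, hi = config.size_window
    for i in range(n_art):
        rid = f"{sample}_art{i:05d}"
        for _ in range(40):
            ua, fa, _ = draw_fragment()
            ub, fb, _ = draw_fragment()
            fa = fa[: int(rng.integers(60, max(61, len(fa))))]
            if not (lo <= len(fa) + len(fb) <= hi):
                continue
            finish(rid, fa + fb, "artifact", f"{ua}+{ub}", None, art_j=len(fa))
            break
        else:
            ua, fa, _ = draw_fragment()
            finish(rid, fa, "gene", ua, None)

    cont_ids = sorted(contaminants)
    for i in range(n_cont):
        cid = cont_ids[int(rng.integers(0, len(cont_ids)))]
        cseq = contaminants[cid]
        ln = int(rng.integers(150, 400))
        start = int(rng.integers(0, max(1, len(cseq) - ln)))
        finish(f"{sample}_cont{i:05d}", "GATC" + cseq[start : start + ln], "contaminant", cid, None)

    return SimulationResult(reads, log, skipped)


def write_fastq(reads: list[SimRead], path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in r.qualities]
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


def read_fastq(path: str | Path) -> list[SimRead]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append(SimRead(rec.id, str(rec.seq), quals))
    return out
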