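# Methods

## The library model the simulator emulates

Double-stranded cDNA from poly(A)+ mRNA is digested with DpnII, which cuts
5' of every GATC so that each internal fragment begins with the site.
Y-shaped adapters carrying a sample-specific 4-nt barcode ligate to the
GATC overhang; after PCR, a single-end read therefore has the layout
`adapter + tag + GATC + insert`. The two tags, TCCC (HB4a) and CCCT (C5.2),
are the bases that differ between the two ligation primers immediately
after the GATC overhang — the published protocol prints the primers but
never isolates the tags, so this is the only reading consistent with the
"barcode flanked by adapter and restriction site" demultiplexing rule.

Simulation per sample: (1) a transcript pool is built from the annotated
genes (with each sample's SNP alleles substituted; heterozygous sites
become two half-weight haplotypes), the planted variant isoforms, novel
genes and fusion transcripts; (2) each molecule is digested at every GATC;
(3) fragments that begin with GATC and fall in the 150–600 nt
size-selection window are sampled — unit chosen by its configured library
fraction, fragment uniformly within the unit; (4) the read covers the full
fragment up to a per-read cap drawn from N(420, 60) nt. With this model the
read-length distribution tracks the fragment-size distribution (restriction
spacing truncated to the window), which is what gives the platform's
~200±67 nt reads, and junction-spanning fragments are sequenced end to end,
making planted-event recovery a property of the plant geometry rather than
of a read-length draw. Errors are independent per-base substitutions at a
flat rate with the matching Phred score; the default rate is 0 because the
recovery guarantees are defined on error-free data (an error model is one
flag away and exercises the identity thresholds). Homopolymer
(pyrosequencing-style) indels are deliberately not modelled.

A configurable fraction of reads (default 1%) are ligation chimeras: two
GATC-leading fragments joined so the second fragment's GATC sits exactly at
the junction — the artifact class the DpnII design makes detectable.
Contaminant reads (default 5.5%) are windows of rRNA/mito surrogate
sequences; 3.3% of reads lose their adapter entirely and 5% keep only a
10 nt adapter stump (separating the lenient from the strict
demultiplexing stringencies).

## Planting and the recoverability guarantee

Every planted event must be recoverable by inspection. The planter
guarantees this geometrically: around each planted junction it removes any
accidental GATC from a protected transcript span (single-base edits mapped
through the exon structure, never touching locked positions such as
annotated splice dinucleotides) and then forces GATC sites 82 nt either
side of the outermost junctions. A size-selected fragment of 164–244 nt
therefore always spans the event with ≥ 78 nt anchors. New splice
boundaries are made canonical on the coding strand (GT..AG; genomic CT..AC
for minus-strand genes). Fusions are built from exonic segments of two
distinct genes (110 nt per side, GATC-led on the A side): microhomology is
planted by copying the A-side genomic continuation over the first `mh`
bases of the B locus and forcing divergence at both microhomology
boundaries; non-templated bases are checked to match neither continuation.
SNPs are placed ≥ 10 nt inside exons, ≥ 25 nt from fragment ends, away from
homopolymer runs and GATC context, with both cell lines sharing the
genotype (hom or het) so the presence-in-both-libraries filter is
satisfiable. Intra-chromosomal fusion partners are kept ≥ 30 kb apart so
the spliced aligner (max intron 5 kb) cannot chain the two segments into
one alignment.

Expression profiles are per-sample *fractions*: SNP-host genes 1.2%,
isoforms 0.4–1%, novel genes 0.6%, fusions 0–0.8%, and the high-fold gene
1.2% in HB4a vs 18% in C5.2 — i.e. the planted truth is a 15-fold RPM
ratio (log2 = 3.907), not a 15x weight that renormalization would shrink.
The remaining mass is uniform over the other annotated genes; the
pseudogene is silent.

## Alignment and partition

The aligner is a toy-scale seed-and-extend spliced aligner: exact 16-mer
seeds every 4 nt, co-diagonal merging, x-drop ungapped extension (+1/-3,
drop 12), and chaining of segments across target gaps up to the maximum
intron size. Blocks are gapless — the simulator's error model is
substitution-only, so indel alignment is out of scope. When the bases at a
splice junction are ambiguous (consistent with both exons) the junction is
placed at a canonical GT..AG/CT..AC if one exists in the ambiguity range,
mirroring how spliced aligners resolve junction wobble. E-values use
Karlin–Altschul statistics with megablast-like +1/−2 constants
(λ=1.28, K=0.46). Records round-trip through standard 21-column PSL, and
externally produced PSL can be fed to the partition instead.

Partition semantics: a read is COMPLETE when some record has coverage
≥ 0.70 and identity ≥ 0.96 and no other locus scores within the nearTop
fraction (0.005) of the best; complete-grade hits at two or more loci are
discarded as multi-hits; otherwise a record with coverage in [0.20, 0.80]
at segment identity ≥ 0.999 makes the read PARTIAL (fusion evidence). A
97%-identical pseudogene copy is *not* within nearTop of a perfect parent
hit, so parent-gene reads stay COMPLETE but drop out of the single-hit
subset (two loci) — matching the published two-stage accounting where the
single-hit set is a proper subset of the complete set. For the PARTIAL band
the prose thresholds are followed rather than the repeated pslReps
parameter listing, which contradicts them.

## Filters with unstated numeric values

The study names the SNP filter dimensions but not their values; defaults
(all configurable) are: per-library depth ≥ 4, divergent/total ratio
≥ 0.25, ≥ 5 nt from exon-intron boundaries, ≥ 5 nt from alignment ends,
reject if any second divergent position lies within a 50 nt window,
homopolymer run ≥ 5, soft-masked (lowercase) reference, biallelic only
(sites with two distinct non-reference bases are rejected with a dedicated
reason). The alignment-end rule is applied per read base: evidence within
5 nt of an alignment end never enters the pileup, so the reported
end-distance (min over counted supporting reads) honours the filter by
construction instead of letting a single unlucky read-length draw veto a
clean site. Zygosity is reported (alt ratio ≥ 0.8 → hom) but never
filtered on. Fusion "perfect match" is operationalized as 100% segment
identity over ≥ 20 nt with joint coverage ≥ 90%; the support-depth scan
uses a ±10 nt junction probe at ≥ 95% identity (the published "less
stringent criteria" are unquantified). The GATC artifact test fires when
any GATC occurrence on the read overlaps the junction placement range
± 4 nt. When per-read candidates merge into one junction, only artifact
reasons shared by every supporting read survive: a chimeric read can
legitimately contain a genuine fusion junction (its ligation join lying
elsewhere on the read), so a single clean junction-spanning read rescues
the event, while junctions seen only with the ligation signature stay
flagged.

## Statistics

The Bayes Error Rate treats the two per-library counts as binomial with
independent conjugate priors (default Beta(1,1)); the reported value is
min{P(p1<p2), P(p1>p2)} computed by adaptive quadrature of
f1(p)·S2(p), cross-checked in the tests against a 10^6-draw Monte-Carlo
oracle (agreement well inside 0.01). Fold change replaces zero counts by 1
before forming the C5.2/HB4a RPM ratio; RPM columns themselves use the raw
counts so RPM mass is conserved. AS-category enrichment uses a two-sided
Fisher exact test of event count vs library total per category (the
original does not name its test). Rapamycin response is a magnitude
decrease or sign inversion of the treated fold change. Spearman
correlation (midranks, scipy) associates read counts with qRT-PCR Ct
values; constant vectors are flagged undefined rather than guessed.

## Problem sizes

The packaged simulation uses a 230 kb genome (two chromosomes, 38 genes
plus one processed pseudogene at 97% identity) and 20,000 reads per
sample — small enough that the whole pipeline runs in about two minutes on
one core while every planted event still collects tens of supporting
reads, so the 100%-recovery checks are far from their statistical edge.
The brute-force oracles (banded ungapped alignment, junction-placement
enumeration) run on reads ≤ 80 nt against ≤ 5 kb references.

## What passing tests do and do not show

The simulator plants events with guaranteed spanning fragments, generous
anchors, clean junction context and error-free bases; real libraries have
PCR duplication bias, homopolymer indels, partially degraded adapters,
repetitive genomes and annotation errors, none of which are modelled.
Passing recovery tests therefore demonstrates that the *rules* (filters,
partitions, junction arithmetic, statistics) are implemented correctly and
self-consistently — not that the pipeline would achieve these rates on
archival 454 data. Known limitations: no flowgram (SFF) emulation, no
PCR-duplicate model, gapless alignment blocks, GT/AG-only conserved sites
by default (GC..AG behind a flag), biallelic SNPs only, and trans-splicing
vs genomic-rearrangement origin of fusions is reported but cannot be
resolved without DNA evidence.
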