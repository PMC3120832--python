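# dpnseq

Toy-scale, fully tested reimplementation of a barcoded **DpnII
restriction-digest cDNA** transcriptome analysis: two poly(A)+ libraries
(an *ERBB2*-overexpressing mammary cell line, C5.2, and its parental line,
HB4a) are tagged with 4-nt Y-adapter barcodes, pooled, sequenced single-end,
and mined for novel genes, alternative-splicing variants, SNPs, gene
fusions, and differential expression.

Because the original sequencing data is archival, the package ships a
first-class **simulator with planted ground truth**: a ~230 kb
multi-chromosome toy genome with annotated multi-exon genes, a
gene/pseudogene pair, planted SNPs, exon inclusions/skips, alternative
donor/acceptor sites, intron retentions, intergenic novel genes, genuine
fusions with controlled junction microhomology (MH) or non-templated (NT)
bases, and DpnII-junction chimeric artifacts. Every downstream stage is
scored against that truth.

## Pipeline

1. **Simulation** — transcripts sampled by abundance, digested at every
   GATC (DpnII cuts 5' of the site), 150–600 nt size selection, reads =
   adapter + 4-nt tag (TCCC/CCCT) + GATC-leading insert, flat per-base
   substitution errors with matching Phred scores.
2. **Demultiplexing & filters** — a barcode is valid when flanked by the 5'
   adapter and the 3' restriction site; lenient and strict stringencies;
   rRNA/mito contaminant screen (E ≤ 1e-20, identity ≥ 85%, coverage ≥ 90%).
3. **Genome alignment & partition** — in-repo seed/extend spliced aligner
   (PSL in/out); *completely aligning* reads (coverage ≥ 70%, identity
   ≥ 96%, no near-top second locus), *partially aligning* reads (coverage
   20–80%, segment identity ≥ 99.9% — fusion evidence), multi-hit discards,
   and the single-hit subset.
4. **Features** — gene mapping, intergenic novel-gene clusters with GT..AG
   checks (≥ 8 kb from annotation), splice events (gaps > 50 nt with
   conserved sites are introns): intron retention, alt donor/acceptor, exon
   skipping, exon inclusion with one/both flanking constitutive exons.
5. **SNPs** — pileup over single-hit reads with per-library depth,
   divergent-base ratio, boundary/alignment-end distances, 50 bp mismatch
   window, homopolymer and repeat masks, biallelic-only; known/novel status
   and coding consequence.
6. **Fusions** — split reads with two unique, perfectly matching exonic
   segments; DpnII-junction artifacts flagged (GATC at the join), same-gene
   and gene/pseudogene chimeras flagged; junction MH/NT character; support
   depth across all reads.
7. **Differential expression** — per-gene counts to RPM; C5.2/HB4a ratio
   with zero→1 replacement, differential at |log2| ≥ 2; **Bayes Error Rate**
   = min{P(p1<p2), P(p1>p2)} under independent Beta posteriors
   (beta-binomial model, prior Beta(1,1)); Fisher-exact AS-category
   enrichment; rapamycin-response classification; Spearman count-vs-Ct
   association.

## Worked example

```python
from dpnseq import RunConfig, run_pipeline

res = run_pipeline(RunConfig(seed=1))          # 2 x 20,000 reads, ~2 min
print(res.partition.counts())
# {'COMPLETE': 35821, 'PARTIAL': 740, 'DISCARDED_MULTIHIT': 0, 'UNALIGNED': 1}

gene = res.truth.erbb2_gene                    # the planted 15-fold gene
print(res.expression.loc[gene, ["count_HB4a", "count_C52", "log2_ratio"]])
# count_HB4a     210
# count_C52     3104
# log2_ratio    3.9176...
```

The partition shows nearly all error-free reads aligning completely (the
740 PARTIAL reads are the planted fusion and chimeric-artifact reads); the
planted 15-fold gene is recovered at log2 RPM ratio 3.92 ≈ log2(15) = 3.91,
with a Bayes Error Rate below 1e-9. On the same run all 11 planted splice
isoforms are recovered with the correct category, 8/8 planted SNPs are
called with zero false calls, the three planted fusions are recovered with
their exact planted MH (10, 4) and NT ("CA") junctions, and every
artifact-derived candidate is flagged `dpnii_junction`.

A CLI mirrors the library: `dpnseq sim genome|plant|reads`,
`dpnseq pipeline --seed 1 --out runs/demo`, `dpnseq percent 731628 802214`.

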