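# locuskit

Locus-level visualization of genetic association results: a Python
library and command-line tool for harmonizing GWAS/QTL summary
statistics, computing linkage disequilibrium (LD) on the fly from a
PLINK 1 reference panel, identifying genome-wide significant loci and
their closest protein-coding genes, parsing GTF gene models, and
rendering stacked regional-association ("LocusZoom"-style) plots,
Manhattan plots, QQ plots, and LD heatmaps as publication-quality static
figures.

It is aimed at statistical geneticists who iterate over many traits and
many loci at once — e.g. stacking dozens of phenotypes over one region —
and therefore puts no cap on the genomic range, the number of genes, or
the number of stacked trait panels.

## What it computes

- **Munging.** Heterogeneous summary-statistic dialects are mapped onto a
  canonical table via a synonym dictionary. Missing Z-scores are filled by
  priority: provided Z, then β/SE, then ln(OR)/SE, then
  sign(β)·Φ⁻¹(1 − P/2). P values shared as 0 (double-precision underflow,
  common for saturated GWAS) are clamped to the smallest positive
  subnormal double (≈4.9e−324), and −log₁₀P is evaluated from the normal
  log-survival function of Z so it stays finite and strictly monotone in
  |Z|. Alleles are aligned to a reference panel with swap/strand-flip
  rules (flips negate Z and complement the effect-allele frequency);
  ambiguous palindromic A/T, C/G variants are dropped by default.
  Harmonized tables persist as Arrow/Feather caches.
- **LD.** r² is the squared Pearson correlation of unphased dosages
  (composite LD), computed on the fly from a PLINK 1 `.bed/.bim/.fam`
  panel; missing genotypes are mean-imputed per variant.
- **Loci.** Greedy clumping: the most significant remaining SNP with
  P < 5e−8 anchors a ±1 Mb window; SNPs inside it are removed; windows
  never overlap. Each locus is annotated with the closest
  protein-coding gene (gene-body distance, TSS mode available).
- **Figures.** Regional panels color SNPs by r² to the index SNP with a
  continuous light-grey→red scale, draw the purple genome-wide
  significance line at −log₁₀(5e−8), and can mark a highlighted gene's
  start/end with yellow guide lines above a packed gene/isoform track.
  QQ plots report the genomic inflation factor
  λ_GC = median(χ²)/0.4549 with χ² = [Φ⁻¹(P/2)]².

A synthetic-data module generates all three input kinds — genotype
panels with tunable LD decay, summary statistics with a planted causal
signal, and small multi-transcript GTFs — so the entire pipeline runs
and is tested without downloads.

## Worked example

```sh
locuskit simulate --out-dir demo --seed 1 --n-samples 2000 --n-variants 200
locuskit munge --gwas demo/gwas.tsv --out demo/gwas.feather --bfile demo/panel
locuskit loci  --gwas demo/gwas.feather --gtf demo/genes.gtf --out demo/loci.tsv
locuskit locuszoom --gwas demo/gwas.feather --bfile demo/panel \
    --gtf demo/genes.gtf --region 1:1000000-1995000 \
    --highlight-gene ALPHA --out demo/locus.png
```

This simulates a 2,000-sample panel with a causal variant in the middle
of the region explaining 5% of phenotypic variance, harmonizes the
resulting GWAS, and prints:

```
INFO locuskit: simulated 2000 samples x 200 variants (dialect=canonical) under demo
INFO locuskit: munged 200 records from demo/gwas.tsv -> demo/gwas.feather
INFO locuskit: found 1 loci (P < 5e-08, +/-1000000 bp) -> demo/loci.tsv
```

`demo/loci.tsv` (BED-like, window coordinates 0-based half-open):

```
chrom  start   end      snp_id  pos      p                      closest_gene  gene_distance
1      499999  2500000  rs101   1500000  2.2802203585641482e-21 ALPHA         0
```

The single reported locus is anchored at the planted causal variant
(`rs101`, the middle of the 200-marker region) at P ≈ 2.3e−21, and the
closest protein-coding gene is the fixture gene ALPHA at distance 0 —
the index SNP falls inside its gene body. `demo/locus.png` shows the
association panel with SNPs shaded grey→red by r² to rs101, the purple
significance line, yellow guide lines at ALPHA's boundaries, and the
gene track beneath.

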