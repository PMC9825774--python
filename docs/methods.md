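# Methods

This note documents the statistical conventions, numerical choices and
design decisions behind locuskit, and what the synthetic-data tests do
and do not establish about behavior on real data.

## Summary-statistic harmonization

**Canonical table.** One row per variant with `snp_id, chrom, pos`
(1-based), uppercase `allele_effect/allele_other`, `z`, `p` ∈ (0, 1],
`neglog10p`, optional `eaf`, `n`, and a `trait` label. Chromosome labels
are emitted without a `chr` prefix; numeric aliases map 23→X, 24→Y,
25→X (pseudo-autosomal regions are treated as X), 26→MT. Keeping one
canonical dialect internally and converting at the boundaries avoids
repeated off-by-one and prefix bugs.

**Column detection.** Case-insensitive lookup in a synonym dictionary
(METAL, PLINK, GWAS-Catalog and similar dialects), extendable through
the config file. A table is usable if it provides either (chrom, pos) or
an identifier, and at least one of: Z; β and SE; OR and SE; or P plus a
sign source. Two source headers claiming one canonical field is an
error rather than a silent first-wins choice, because the two columns
usually disagree.

**Z-scores.** Filled by priority from the least-derived source:
provided Z, then β/SE, then ln(OR)/SE (SE taken on the log-odds scale),
then sign(effect)·Φ⁻¹(1 − P/2). Records with SE ≤ 0, or with P outside
(0, 1] on the P-only path, are dropped and counted. Converting the
P-derived Z back through 2·Φ̄(|z|) recovers P to 1e−10 relative error
down to P = 1e−300 (tested), so the inverse-normal path loses nothing.

**P clamping.** Saturated GWAS share underflowed P values as literal 0.
We replace them with the smallest positive *subnormal* double
(≈4.94e−324) — the literal smallest representable float, maximizing the
retained dynamic range — and the constant is configurable for users who
prefer the smallest normal double. Because a clamped P is uninformative,
−log₁₀P is computed from the normal log-survival function of Z whenever
P has underflowed: `-(log(2) + logsf(|z|))/log(10)`. This keeps
−log₁₀P finite and strictly increasing in |z| across the underflow
point (tested on z = 1…60, where two-sided P underflows near |z| ≈ 38.5).

**Panel alignment.** Records are matched to the reference panel by
(chrom, pos). An exact allele-pair match is kept; a swapped pair flips
the signs of Z and β and complements eaf; a strand-complement match
(with or without swap) rewrites the alleles to the panel's
representation and applies the same flip rules. Palindromic A/T and C/G
pairs cannot be strand-resolved from alleles alone; the default policy
drops them when eaf is missing or inside [0.4, 0.6] (the conventional
ambiguity zone) and otherwise assumes same-strand orientation; both the
band and the policy (`keep_all`, `drop_all`) are configurable. The
operation is idempotent: after one pass the alleles equal the panel's,
so a second pass is the identity (tested).

**Duplicates.** Order-insensitive (chrom, pos, allele-pair) keys; the
first occurrence is kept by default (deterministic and order-stable),
`keep_min_p` is available via config.

## Linkage disequilibrium

r² is the squared Pearson correlation of dosage vectors — composite LD
on unphased genotypes — not a haplotype-based EM estimator; reference
panels here are unphased and composite LD is the common practice for
coloring regional plots. Missing dosages are mean-imputed per variant
before correlation (deterministic and vectorizable; pairwise deletion
would make r² depend on the partner variant). A variant with zero
variance after imputation (including all-missing) is monomorphic: its
r² is missing, and a monomorphic *index* variant is an error since
coloring by LD against it is undefined. Dosages count the first `.bim`
allele; r² is invariant to which allele is counted (tested).

The PLINK 1 `.bed` reader/writer implements the published 2-bit
variant-major format directly (magic `0x6C 0x1B`, mode `0x01`, codes
00/10/11/01 → 2/1/0/missing copies, one byte-padded block per variant)
and is verified against a hand-decoded byte fixture and byte-identical
round trips.

`unique_entry_count(n) = n(n+1)/2` is the matrix-size accounting used
when reasoning about very large heatmaps: a symmetric pairwise matrix
over a 66,000-SNP region (the MHC at full density) holds ≈2.18 billion
unique entries, which is why the renderer draws only the lower triangle
and rasterizes it.

## Locus discovery

Greedy clumping: repeatedly take the remaining record with the smallest
P (< 5e−8 by default), emit a closed window pos ± 1 Mb (floored at bp 1),
remove every record inside it, and stop when nothing significant
remains. Ties are broken by chromosome order (1…22, X, Y, MT), then
position, then snp_id, which makes the procedure invariant to input row
order. Two desiderata — windows that never overlap, and every
significant SNP belonging to exactly one window — cannot both hold under
the naive rule when two index SNPs sit between one and two half-widths
apart, so a later (less significant) window is truncated where it abuts
an earlier one. This preserves the greedy anchor set exactly and only
shrinks window edges. The independently coded test oracle implements
the same rule from scratch; the two agree on 1,000 random tables.

Closest-gene annotation measures distance 0 inside the gene body and
otherwise the distance to the nearer gene-body endpoint; a TSS mode
(strand-aware) is available. Genes are filtered to `protein_coding` by
default, reading `gene_type` (GENCODE) with `gene_biotype` (Ensembl) as
the fallback. Ties go to the alphabetically first gene name; a
chromosome with no qualifying gene yields a None sentinel, not an error.

## Gene models and track layout

The GTF parser keeps coordinates 1-based inclusive end to end;
conversion to 0-based half-open happens only at the BED-style output
boundary. Genes or transcripts present only through child features are
synthesized from the children's span; an exon without a `transcript_id`
is a parse error with its line number. Within a transcript, exons are
sorted and must not overlap; introns are the complementary gaps, so
exons ∪ introns tile [start, end] exactly (tested).

Row packing is greedy first-fit on items sorted by start: each item —
its body united with an estimated label extent (character count × a
configurable per-character width) plus padding — lands on the lowest
row it does not intersect. For intervals, first-fit-by-start uses
exactly as many rows as the maximum overlap depth, so the layout is
optimal; rows are unbounded, so gene count never caps a figure. Label
width estimation is deterministic (no font engine), which keeps layout
testable; the cost is that the estimate is approximate for proportional
fonts. Strand is encoded in the label (`NAME>` forward, `<NAME`
reverse).

## Figures

The LD scale is a continuous light-grey→red colormap (r² = 0 → grey
floor, r² = 1 → full red, monotone between); the classic five-bin
palette is available via `ld_bins`. The index SNP defaults to the
minimum-P SNP in the region and can be overridden per trait with a
sentinel id. The significance line sits at exactly −log₁₀(threshold).
Manhattan x-coordinates are pos + a running offset (sum of previous
chromosomes' maximum positions plus a fixed 10 Mb gap per boundary).
QQ expected quantiles are −log₁₀((i − 0.5)/n);
λ_GC = median(χ²)/F⁻¹_{χ²₁}(0.5) with χ² from the two-sided normal
quantile of P. Extreme −log₁₀P can be capped (`y_cap`) with a dotted
break line, since clamped P values otherwise dominate the axis.
Rendering has no hidden randomness: fixed inputs reproduce PNG output
byte for byte (tested).

## Synthetic data

The generator is the package's stand-in for real GWAS inputs, with the
study conditions as defaults: 2,000 samples, 200 markers 5 kb apart,
adjacency-copy parameter ρ = 0.9, allele frequencies uniform in
[0.05, 0.95], the causal variant at the middle marker explaining 5% of
phenotypic variance against unit noise.

*Panels.* Per haplotype, marker j copies marker j−1 with probability ρ
and is otherwise a fresh Bernoulli(f_j) draw; two haplotypes sum to a
diploid dosage. ρ = 1 gives perfect adjacent LD, ρ = 0 independence
(mean off-diagonal r² ≈ 1/(n−1)), and intermediate ρ gives geometric LD
decay in lag (all tested). *Sumstats.* A phenotype
y = β·g_causal + ε is regressed on every variant separately (marginal
simple regression with intercept); β is chosen so that
β²·Var(g) = h²/(1−h²)·σ² with h² the configured variance explained.
Emission under seeded real-world header dialects exercises column
detection end to end. *GTF.* A nested gene/transcript/exon spec is
validated and written as parseable GTF in either biotype dialect.

What this emulates — and does not: the copying process produces
realistic short-range LD but no recombination hotspots, no population
structure or relatedness, no allele-frequency spectrum from demography,
and marginal regression assumes a quantitative trait with Gaussian
noise. Passing tests therefore establish the correctness of the
estimators and procedures under these idealized conditions, not
robustness to confounding or case-control ascertainment.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` run at desk scale by design:
LD oracles on 50-variant × 200-sample panels, clumping oracles on
tables of ≤400 rows, causal-signal recovery over 100 replicates at
n = 2,000, and a 20-trait × 3,000-SNP stacked render standing in for
the full phenome-scale figure; the 66,000-SNP heatmap and the
120-trait stack are covered by exact matrix-size accounting plus the
scaled-down stress render. All randomness flows from explicit seeds;
the acceptance script derives every generator seed from `--seed`.
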