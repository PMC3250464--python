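# Methods

## The screening model

The package operationalizes a four-stage post-GWAS screen for
expression-altering risk variants.

**LD proxy expansion.**  Loci are biallelic; genotypes code copies of a
designated allele, and the sample minor allele is recomputed from the
data (ties at frequency 0.5 break to the lexicographically smaller
allele).  Two-locus haplotype frequencies come from direct counting
when phased haplotypes are present, otherwise from an EM
maximum-likelihood estimate that iterates the phase split of double
heterozygotes (relative tolerance 1e-10, at most 1000 iterations; the
two estimators agree exactly whenever no individual is doubly
heterozygous).  LD is summarised by D = p_AB − p_A p_B and
r² = D²/(p_A(1−p_A)p_B(1−p_B)).  Proxies are same-chromosome SNPs
within 500 kb (configurable; precomputed HapMap LD files impose their
own radius, so no canonical value exists) with defined r² ≥ 0.8.
Monomorphic candidates, whose r² is undefined, are excluded with a
warning rather than treated as r² = 0 — mirroring how precomputed LD
tables simply omit such pairs.  Risk alleles propagate to proxies by
the sign of D after orienting both loci to (risk allele, candidate
allele); D = 0 yields an explicit *ambiguous* result, never a guess.
"Matching genotype ratios" has no published formula, so sign-of-D
haplotype matching is this package's stated operationalization.

**Cis-eQTL regression.**  A gene's cis window is the closed 1-based
interval from 300 kb upstream of the TSS to 100 kb downstream of the
TES.  Upstream/downstream are strand-aware by default (`--no-strand-
aware` gives the genomic-left alternative; whether the original screen
oriented by strand is unknowable from its description, so the choice is
recorded in run metadata).  Each SNP–probe pair with the SNP in the
window is tested by OLS of expression on minor-allele count, two-sided
p from the t distribution on n−2 degrees of freedom.  Missing data are
handled by pairwise-complete deletion; pairs with fewer than 3 complete
observations or zero genotype variance are excluded and do not count
toward the multiplicity m.  BH adjustment is the step-up
adjusted_(i) = min_{j≥i} min(1, m·p_(j)/j); m defaults to the number of
testable pairs but can be set larger to adjust a reported subset
against a full test count (used to re-derive the published table at
m = 613).  Significance: adjusted p < 0.20.  Direction is per copy of
the minor allele; an exact-zero slope reports *undirected* rather than
an arbitrary arrow, and when a risk allele differing from the minor
allele is known, both codings are reported.

**Motif disruption screen.**  PWMs are count matrices with a total
pseudocount of 0.8 apportioned by the background (a common JASPAR
practice; configurable), scored as
log2(((count + pc·bg)/(total + pc))/bg).  Only windows overlapping the
variant are scanned, on both strands — a variant cannot alter a window
it does not touch.  Per-allele binding p-values compare the best
overlapping-window score against an exact discretized null (scores
binned at 0.01 bits, per-position distributions convolved across the
motif; equal to exhaustive enumeration for short motifs), combined
across the 2L windows under an independence approximation whose error
the enumeration oracle bounds for short motifs.  When at least one
allele is significantly bound (p < 0.05), the allele score difference
is tested by seeded Monte Carlo: flanks are resampled from the
background, both alleles substituted into the *same* resampled context,
and the two-sided tail of |Δbest| estimated with the add-one
correction.  Difference p-values are BH-adjusted across the whole
(context × motif) library; predicted disruption means adjusted
p < 0.05.  No numerical agreement with any external web tool is
claimed; the screen is defined entirely by the statistics above.

A property of the max-over-windows statistic worth knowing: a
substitution is detectable only when it sits at a motif position that
discriminates the two alleles far more strongly than any other
position.  For uniformly sharp motifs every window placement offers the
same contrast and the paired null is as dispersed as the signal; for
motifs with a single critical core (the shape of many real TF motifs)
the planted variant is flagged essentially always.  The power
experiment therefore uses a 12-column motif with one high-information
position discriminating T from G and T/G-neutral flanking columns.

**Conservation filter.**  Conserved regions are maximal runs of
alignment columns in which *every* 100-column subwindow reaches ≥70%
identity (boundary inclusive: exactly 70/100 passes).  Gap and N
columns count as mismatches and the denominator is the full column
count; "100 nucleotides" is read as 100 alignment columns.  The
all-subwindow rule, and the gap handling, are this package's explicit
choices — the original web service's internal counting is unpublished —
and both are recorded in output metadata.  A SNP is conserved when its
±100 bp neighbourhood overlaps such a region versus mouse *or* rat; a
SNP covered by no alignment reports *unevaluable*, distinct from a
covered-but-unconserved call.  Alignment is an input (aligned FASTA or
pairs), not something the package computes.

## Synthetic data

LD blocks use a founder-copy model: each haplotype draws one latent
uniform u per block, its founder allele at SNP i is 1{u < freq_i}
(comonotone across SNPs), and each allele is independently *resampled*
from Bernoulli(freq_i) with probability `mutation_rate`.  Marginal
allele frequencies are therefore exact; with equal within-block
frequencies the haplotype correlation between two SNPs is
(1 − mutation_rate)², so r² ≈ (1 − mutation_rate)⁴ tunes within-block
LD and 0 gives perfect copies.  This is deliberately not a coalescent:
the analysis only consumes the statistical interface (tunable r²,
stable frequencies), and the founder-copy construction is verifiable in
closed form.  Expression is baseline + Σ beta·genotype + N(0, σ²),
independent across probes and samples.  All randomness flows from one
integer seed through named generators.

The study-scale fixture fixes 12 single-locus blocks with SNP counts
(20, 16, 13, 10, 10, 10, 8, 8, 8, 6, 6, 5) — 120 SNPs — and per-locus
probe counts (5, 5, 6, 5, 5, 5, 5, 5, 5, 5, 5, 5), with each gene's cis
window covering its whole block and loci isolated on separate
chromosomes, so the pair count is exactly
Σ snps×probes = 613 by interval geometry.  Planted signal: the 16-SNP
block lowers one gene's expression (β = −0.8 per minor allele,
σ = 1), and three-gene locus 3 raises two genes (β = +0.8); block
frequencies are drawn uniformly in 0.15–0.45.  At the default
`mutation_rate = 0`, every block SNP is a perfect proxy of its index,
making the planted significant sets deterministic by construction.  At
β = 0.8, σ = 1, n = 60 the per-pair power is high (|t| ≈ 4), so planted
pairs clear BH < 0.20 comfortably.

What the generator does *not* emulate: population structure,
relatedness, coalescent LD decay, X-chromosome dosage, probe
cross-hybridisation, or expression covariance between genes.  Passing
tests therefore demonstrate the correctness and calibration of the
statistical machinery under its stated model, not robustness to those
real-data complications.

## Numerical choices

- BH step-up is computed by a reverse cumulative minimum over the
  sorted p-values (stable mergesort; ties share the step-up value).
- The regression uses `scipy.stats.linregress` per pair; a closed-form
  vectorized version (`regress_many`) powers simulation-scale
  calibration and is tested row-by-row against `linregress`.  A flat
  response returns slope 0, p 1; p-values are clipped into (0, 1].
- PWM score discretization: 0.01-bit bins; the observed score is binned
  with the same rounding as the null support, so discretization error
  is bounded by L·bin/2 and vanishes in the enumeration comparison.
- Window-scan ties break to the lowest offset, then the + strand.
- EM haplotype frequencies start from the uniform (¼,¼,¼,¼) point; the
  likelihood in the biallelic two-locus problem is well-behaved there.

## Calibration experiments and problem sizes

The acceptance script and test suite re-run, at fixed seeds: the
published-table BH reconstruction (21 rows, m = 613); a 200-seed global
null at study scale (613 pairs, n = 60) checking the raw p < 0.05 rate
and that BH < 0.20 typically rejects nothing; 500 replicates of a
planted β = 0.8 effect checking ~95% CI coverage and > 99% direction
recovery; a 20-seed motif-disruption power run at n_null = 10,000; EM
accuracy at n = 500 over 20 seeds (max haplotype-frequency error
< 0.05); and brute-force oracle equivalence for the BH step-up, the
exact PWM score null (motif lengths ≤ 5), and the conservation scan.
These sizes keep the whole suite in the minutes range while leaving
Monte-Carlo standard errors small enough for 3-SE assertions.

## Known limitations

- The EM estimator assumes Hardy–Weinberg-type random pairing of
  haplotypes within individuals; strong inbreeding would bias it.
- The independence approximation across overlapping motif windows makes
  per-allele binding p-values slightly conservative for repetitive
  motifs.
- The disruption screen's power depends on motif shape as described
  above; a null result for a uniformly sharp motif is uninformative.
- Conservation calls depend on the supplied alignments' quality and
  coverage; `unevaluable` is common near alignment edges.
- No covariate adjustment (population structure, expression batch
  factors) — out of scope by design.
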