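# Methods

This note documents the models behind `asqtl`, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical decisions a maintainer would want spelled out.

## Parental-origin assignment

Child genotypes arrive phased (two haplotypes per animal, consistent along
a chromosome) but without parental labels.  Labels are derived from sire
genotypes, walking each chromosome in position order per animal:

* homozygous child sites are trivially labelled;
* at a heterozygous site with a homozygous sire, the sire's allele is
  paternal — this also fixes which input haplotype is paternal from here on;
* at a heterozygous site with a heterozygous sire, the orientation of the
  nearest previously resolved SNP is carried through the input phasing
  (`carried-phase`); if no site has been resolved yet on the chromosome the
  entry stays `unphased` and is excluded downstream rather than guessed;
* sites where neither child allele occurs in the sire are flagged
  Mendelian-inconsistent and excluded.

## Allele counts and the heterogeneity G-test

Per feature (ChIP peak or exon) and animal, maternal/paternal read counts
are summed over the animal's heterozygous, phase-resolved sites inside the
feature.  Sites where exactly one parental count is zero while the other is
positive are excluded as monoallelic (likely imputation errors); no
minimum-depth threshold is imposed beyond that.  Before summing, the s×2
site-by-parent table is tested for ratio heterogeneity with the
log-likelihood-ratio G statistic; we use df = s−1 (the standard independence
df for an s×2 table) and the convention 0·ln 0 = 0.  A single-site table is
degenerate (G = 0, df = 0, p = 1) and flagged.

## Two-stage allele-specific scan

All SNPs within 1 Mb of the feature midpoint (midpoint =
floor((start+end)/2) in 0-based half-open coordinates) are candidate
drivers.  Stage one pools reads over driver heterozygotes onto the
alternate-carrying haplotype: A = ΣM_i + ΣQ_j, T = ΣM_i+ΣP_i+ΣN_j+ΣQ_j, and
Z = (A/T − 0.5)·√(4T), which is the square root of the binomial(T, ½) score
statistic and approximately standard normal under no cis effect.  Two-sided
p-values are used throughout (no directional prior on imbalance); the
stage-two gate is p < 10⁻³ and joint significance requires p < 10⁻⁴ in both
stages.  Stage two regresses Y_i = ln((maternal+10)/(paternal+10)) on
X_i ∈ {+1, −1, 0} by OLS, one observation per animal (the feature-summed
counts, not per-site observations), with no covariates; animals with
unresolved driver phase are dropped.  A perfect fit (zero residual
variance) reports the slope with an undefined p, flagged degenerate.

The normal approximation to the exact binomial p is excellent in the tail:
for T ≥ 100 the two of them agree within 0.01 wherever the exact p ≤ 0.05
(verified by exhaustive enumeration).  Near p ≈ 1 the discrete central atom
(mass ≈ √(2/πT)) keeps the gap larger; this has no effect on any decision
threshold the pipeline uses.

## Traditional QTL mapping

**Peak phenotype.** Counts are divided by the per-animal mean across peaks
(ChIP and input separately); per peak, ln(PN+1) is regressed on ln(IN+1)
and the residual is the phenotype.  QC first removes peaks whose total
count falls below the empirical 1% quantile (linear interpolation, totals
across animals) and peaks whose total input exceeds 5× the mean (reference
artefacts).

**Exon phenotype.** Exons with median count < 5 are dropped.  The
variance-stabilizing step is a deliberately simple, fully specified
transform: log2(count / size_factor + 1) with median-of-ratios size
factors; a heavier model-based stabilization would change no contract in
this package and would make the transform harder to reason about in tests.
Batch effects are removed after the transform by per-batch mean-centring
(grand mean preserved); single-animal batches are left uncentred with a
warning.

**Outliers.** One pass of PCA on the phenotype matrix; animals beyond 4 SD
on any of the first 7 components are removed (components cap at n−1).

**Mixed model.** y = Xc + gβ + u + e with cov(u) = σ²g·K, K the first
VanRaden GRM (W W′/m with columns standardized by √(2p(1−p)), monomorphic
SNPs skipped), leave-one-chromosome-out per tested feature.  Variance
components are estimated by REML after one eigendecomposition of the LOCO
GRM (cached per chromosome), maximizing over δ = σ²e/σ²g on a bounded log
scale; each SNP is then a generalized-least-squares fit with a Wald p.
With K = I this reduces to OLS up to an exchangeable variance split (tested
to 10⁻³ in p).  Batch enters as a one-hot categorical covariate with a
reference level.  Dosage is the count of alternate alleles, so β shares a
sign convention with the allele-specific slope (alt-maternal coded +1).

## Intersection

Overlap odds ratios use the sample cross-product a·d/(b·c); this
reproduces the printed values of the reported overlap tables at printed
precision (one borderline rounding case: a table that prints 5.26 where
the cross-product gives 5.266).  Direction concordance maps both effect
estimates onto the alternate-allele axis before comparing signs;
zero-effect entries are excluded from the fraction.  Peak enrichment
(C/A)/(B/D) merges overlapping peak intervals first and supports two
position conventions — tested SNP sites (default) or base pairs — because
the formula's "positions" are used in both senses in practice.  The
combined p converts each of the four p-values to its upper-tail 1-df
chi-squared quantile, sums, and takes the 4-df upper tail (closed form
e^(−x/2)(1+x/2)); p = 0 inputs are clamped to 10⁻³⁰⁰.  Causal-candidate
selection applies the three filters (all four analyses significant at
10⁻⁴, driver inside its peak, concordant directions), then keeps the
lowest combined p per (peak, exon) pair, ties broken by genomic position.

## Motif discovery

Selection thresholds follow the analysis design: asbQTL drivers inside
their peak at p < 10⁻⁸ / 10⁻⁷ / 10⁻⁶ for H3K4me1 / H3K4me3 / H3K27ac (the
in-peak requirement is waived for H3K27ac, where too few such sites exist),
and aseQTL drivers within 10 kb of the exon start at p < 10⁻¹⁵.  The
stage-one p gates selection since it exists for every result row.  21-bp
flanks (variant at position 11) and their reverse complements enter the
pool; sequences with N or within 10 bp of a contig end are excluded; a
sequence and its own reverse complement may co-cluster and both are kept.

Clustering is complete linkage on Levenshtein distances over the central
nine bases, cut at height 3, so every intra-cluster pair differs by at most
three edits; clusters under ten members are discarded.  With integer
distances, tie-breaking can legitimately produce different partitions at
the cut; the test oracle therefore enumerates all tie-consistent merge
orders and accepts any of them.

Consensus: flanking PFM columns are trimmed while their information
content (2 − entropy, bits) is below 0.2 — i.e. near-random flanks are
dropped.  A literal reading of the trimming rule ("entropy below 0.2")
would delete the *most conserved* columns; we treat that as an
inconsistency and implement the information-content reading as the
default, with `literal_entropy_trim` available for the literal behaviour.
Per retained column, bases are sorted by descending frequency (ties in
fixed A,C,G,T order) and accumulated until the running sum strictly
exceeds 0.85; one base is emitted bare, several as a bracketed class.

Genomic enrichment counts non-overlapping forward-strand regex matches
(reverse complements already entered the cluster pool) and divides by
Π(Σ included base frequencies) × total sequence length; the default base
frequencies are A=T=0.291, C=G=0.209 (mammalian autosome values),
overridable or recomputable from any FASTA.  The raw total length is used
rather than length−width+1 per contig; the difference is negligible at
genome scale.  The allele-skew test compares the cluster's
positive-effect (or reference) alleles against uniform 25% with the
multinomial log-likelihood ratio; p is exact by composition enumeration
for N ≤ 20 and seeded Monte-Carlo (10⁵ draws, reported with its method)
otherwise.  PFM similarity is an ungapped sliding alignment of
column-normalized frequencies, per-column score 2 − Σ|q−t|, relScore =
100·total/(2·aligned width); this scoring contract is our own emulation of
percent-of-maximum PFM matching, and matches above 90% are reported with
the database's collection label.

## Synthetic data: what it emulates, what it does not

The generator draws a trio-design population: maternal alleles Bernoulli
at the SNP's population frequency, paternal alleles transmitted from a
drawn sire genotype (so Mendelian consistency is exact by construction),
positions uniform per chromosome, frequencies uniform in `maf_range`
(default 0.1–0.5).  Features are anchored on SNPs so every feature has at
least one informative site; a `frac_causal_features` fraction receives one
driver SNP (inside the feature with probability 0.5, otherwise in the
1 Mb window), with allelic log-odds effect drawn from
`effect_size_range` (default 1.0–2.5) and additive log-count effect 0.25×
that, sharing its sign.  A causal exon reuses a nearby causal peak's
driver with probability `frac_shared_drivers` (default 0.5), planting the
coordinated peak–exon regulation the intersection stage looks for.

Counts: allelic counts are beta-binomial (default intraclass correlation
0.02) around logistic(X·effect) at Poisson site depth (default mean 50);
feature totals are negative-binomial (default dispersion 0.05) with batch
shifts (default SD 0.1 on the log scale, 2 batches), a polygenic term with
GRM covariance (default SD 0.2) and lognormal library sizes; input counts
share the library structure but not the genotype effects.  The reference
sequence is i.i.d. from `base_freqs` with the reference allele written at
SNP positions and planted motif instances centred on variant sites
(causal in-feature drivers first), kept non-overlapping so the planted
count is a construction guarantee.

Deliberately not modelled: linkage disequilibrium (SNPs are independent,
so only the causal driver itself associates — power and type-I properties
are clean, but LD-induced multiplicity of significant dSNPs around a
causal site, a prominent feature of real data, is absent), read-level
effects (mapping/reference bias, fragment structure), imprinting, trans
effects, and splicing variation in exon counts.  Passing tests therefore
demonstrate correctness and calibration of the statistics, not robustness
to those real-data phenomena.

## Problem sizes and reproducibility

All randomness flows from one master seed through fixed per-generator
streams, so identical configurations are byte-identical.  The benchmark
studies run at desk scale chosen to keep the full suite fast while leaving
comfortable statistical margins: the calibration study uses 2000 null
feature–driver pairs at 100 heterozygotes × depth 50; the planted-recovery
study uses 200 animals, 2×250 SNPs on two 1.5-Mb chromosomes, 240 features
with ~100 causal drivers at allelic log-odds 2.0 and additive effect 0.5;
the motif study uses 30 planted + 100 background variants on a 200-kb
genome with the motif topped up to exactly 5× its expected background
count.  Published-table odds ratios are recomputed directly from the
reported marginals and are deterministic.

## Known limitations

* The second allele-specific test fits no covariates; batch effects on the
  within-animal log ratio are assumed to cancel (they act on totals, not on
  the maternal:paternal split).
* The pooled Z treats reads as independent given the haplotype; PCR or
  overdispersion beyond the planted beta-binomial inflates Z moderately,
  which the two-stage thresholding is designed to absorb.
* PFM similarity is an emulation with a stated contract, not a
  re-implementation of any external tool's scoring.
* Exact multinomial enumeration is O(N³) in compositions and switches to
  Monte-Carlo above N = 20; Monte-Carlo p-values are floored at 1/draws.
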