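# Methods

This note documents the statistical models, defaults and numerical
conventions behind `radpopgen`, and what the synthetic-data tests do and
do not demonstrate about real data.

## Data model

Genotypes are diploid biallelic alt-allele dosages in {0, 1, 2} with a
single missing marker (−1). Phase is discarded; no analysis here uses it.
VCF positions stay 1-based and locus order is file order. Indels and
multi-allelic records survive reading but carry flags, so the QC cascade
— not the reader — decides their fate; a genotype call touching an allele
index above 1 cannot be expressed as a biallelic dosage and is stored as
missing at that cell. The genepop dialect uses 2-digit allele codes
(ref = 01, alt = 02, missing = 0000) and writes sample labels as
`site:sample_id` so that site assignment survives a round trip.

## QC cascade

Filters are applied in a fixed order — non-biallelic/indel, QUAL < 20,
per-locus missingness > 30%, pooled MAF < 0.05, one SNP per RAD tag,
per-individual missingness > 30% — and the report attributes each dropped
item to the first filter that removed it. The order matters only for that
attribution, not for the final locus set, except where the MAF and
missingness criteria interact; fixing it makes the report reproducible.
Boundary conventions: MAF is kept at exactly 0.05 (inclusive), missingness
removes strictly greater than 0.30. The per-tag rule keeps the highest-MAF
SNP, breaking ties by the smallest position and then lexicographic locus
id. Sites falling below any particular sample size are never auto-dropped;
a warning is logged instead, since small but genuine collections can still
inform diversity summaries.

The Hardy–Weinberg screen uses the exact conditional test for biallelic
loci: conditioning on the observed allele counts, heterozygote counts of
matching parity are enumerated by recurrence and the p-value sums all
outcomes no more probable than the observed one (a two-sided
probability-ordering test; monomorphic samples return p = 1). The
Benjamini–Hochberg family is the set of testable loci within one site, and
a locus is removed only when q < 0.05 in at least two sites — deviations
replicated across sites indicate assembly or genotyping artifacts, while
single-site deviations are expected by chance at these locus counts.

Genotyping error from replicate-sequenced individuals is defined at the
genotype level: discordant cells over cells called in both members of a
pair. An allele-level definition would roughly halve the number, and
published summary rates do not always state their denominator; the
per-locus mismatch histogram is reported so either convention can be
recovered.

## Differentiation estimators

Weir–Cockerham (1984) per-locus variance components a (among populations),
b (among individuals within populations) and c (within individuals) are
computed for the biallelic case with unequal and per-locus varying sample
sizes (populations with zero calls at a locus drop out of that locus).
The multi-locus estimate is the ratio of sums θ = Σa/Σ(a+b+c), never a
mean of per-locus ratios; monomorphic loci contribute zeros; negative
estimates are reported untruncated. The bootstrap CI resamples loci with
replacement (1,000 draws, percentile interval, seeded) — the standard
choice for a ratio-of-sums estimator whose locus contributions are
heterogeneous. F<sub>IS</sub> is the Weir–Cockerham within-population f
computed per locus from the single-population b and c components and
averaged over loci polymorphic within the site; H<sub>E</sub> uses the
small-sample correction 2p(1−p)·2n/(2n−1).

Genic differentiation uses the log-likelihood-ratio G statistic on the
2×2 allele-count table per locus (0·log 0 = 0), with p-values from
Monte-Carlo permutation of individuals between the two groups,
(count + 1)/(n_perm + 1). This is an exchangeability-based substitute for
Markov-chain exact tests: the two differ in their null computation but
target the same hypothesis, and the permutation version is exactly valid
(if conservative under heavy ties, as the calibration test documents).
Locus p-values combine by Fisher's method, −2Σln p ~ χ²(2k).

## AMOVA

Three levels: among groups of sites, among sites within groups, within
sites. Distances are squared Euclidean distances between individual
dosage vectors; under missingness the mean squared difference over
jointly-called loci is rescaled to the full locus count (pairwise-complete
handling). Sums of squares follow the distance formulation (SS of a set =
sum of pairwise squared distances over set size), mean squares use the
standard unbalanced-design coefficients, and components may be negative.
The within-individual level is collapsed into the within-site component,
keeping three levels. Permutation schemes are per level: Φ<sub>CT</sub>
permutes whole sites among groups, Φ<sub>SC</sub> permutes individuals
among sites within groups; 1,000 iterations by default. With few sites
the Φ<sub>CT</sub> permutation space is tiny and a warning reports it.

## Isolation by distance and dispersal

Pairwise θ is linearized as θ/(1−θ) (negative values pass through) and
regressed by OLS on pairwise in-water distance; adjusted R² treats site
pairs as independent observations, which mirrors common reporting practice
but overstates the effective sample size — the one-sided Mantel test on
the same matrices is the inferential guard. The Mantel permutation null
co-permutes rows and columns of one matrix; for up to 6 sites the 720 or
fewer permutations are enumerated exactly, otherwise 9,999 seeded draws
are used.

Mean per-generation dispersal distance follows a one-dimensional habitat
model conditioned on effective density D (adults per km of coastline):
σ = (k·D·b)<sup>−1/2</sup> with k = 8. The constant is an empirical
calibration of this model family (Rousset-style one-dimensional IBD theory
puts the slope at 1/(4Dσ²); the factor 8 corresponds to a particular
convention for σ as mean dispersal distance rather than axial standard
deviation) and is exposed as `DISPERSAL_CONSTANT`. Report tables round
half-up to integer km — half-up, not banker's, because a .5 value occurs
on the default density grid — with full precision retained alongside;
σ rounding to 0 at extreme densities is legal and kept.

## Two-deme drift–migration simulator

Two Wright–Fisher demes of constant diploid size N<sub>e</sub> start from
binomial samples of an infinitely large ancestral pool (default: 1,864
loci with ancestral frequencies uniform on [0.05, 0.95], matching a
MAF-filtered neutral SNP panel; empirical frequencies can be supplied).
Each generation applies migration then reproduction. Migration defaults
to deterministic frequency mixing, p<sub>i</sub>′ = (1−m)p<sub>i</sub> +
m p<sub>j</sub>: the expected-count semantics of proportional exchange,
which keeps replicate variance attributable to drift alone; a stochastic
migrant-count mode (binomial emigrant numbers with hypergeometric allele
draws) is available behind a flag. Reproduction redraws each deme's 2N<sub>e</sub>
allele copies binomially from the post-migration frequency — the exact
per-locus marginal of random mating with biparental choice with
replacement and no selection, so an individual-based implementation would
match it in distribution. Migration-before-reproduction is a fixed
convention; at the small m of interest the stationary θ is insensitive to
the order.

θ between the demes treats each full deme as a sampled population
(census = sample) and takes within-deme heterozygosity at its
Hardy–Weinberg value, consistent with the model's random mating; a test
confirms this count-level estimator agrees with the genotype-level
Weir–Cockerham estimator on individuals sampled from the same final state.
The default grid is N<sub>e</sub> ∈ {500, 2500, 10000} ×
m ∈ {0.01%, …, 30%} × T ∈ {10, 100, 1000}, five replicates per cell with
independent sub-seeds, and each cell's replicate-mean θ is labelled
below/within/above an empirical pairwise-F<sub>ST</sub> range with
inclusive bounds.

## Adaptive/neutral partition

A SNP is putatively adaptive if any rule fires: either external
F<sub>ST</sub>-outlier flag; Bayes factor ≥ 10 (inclusive — "strong"
support on the usual evidence scale) for at least one environmental
predictor; or an ordination loading more than 3 population SDs from the
axis mean on any retained axis (population vs sample SD is negligible at
thousands of loci). The neutral set is the complement, making the
partition disjoint and exhaustive by construction. The package does not
re-implement the external scans themselves; a naive top-quantile
per-locus-θ flagger exists purely as test plumbing and is labelled
non-publication-grade.

## Synthetic data: what passing tests show

The Balding–Nichols generator draws site frequencies from
Beta(p(1−F)/F, (1−p)(1−F)/F) around uniform ancestral frequencies and
genotypes binomially under within-site HWE, giving E[θ̂] ≈ F for parameter
recovery tests. The stepping-stone generator reuses the drift kernel
across K demes in a line to produce genuine distance decay for Mantel/IBD
recovery. Artifact injection flips each allele with a set probability
(dosage moves ±1, capped), masks cells at a set missingness, and
duplicates individuals into replicate pairs with independent errors; the
closed-form heterozygote discordance expectation anchors the error tests.

These generators validate the estimators under their own assumptions:
unlinked loci, HWE within sites, no null alleles, missingness completely
at random, and island-like or strictly linear spatial structure. Passing
tests therefore demonstrate correctness of the computations and
recoverability of parameters under idealized conditions — not robustness
to linked RAD loci, allele dropout, batch effects in missingness, or
two-dimensional coastal geometry, none of which the generators emulate.

## Problem sizes and determinism

Default test and acceptance problem sizes (hundreds to low thousands of
loci, tens of individuals per site, five simulator replicates) were chosen
as the smallest scales at which the Monte-Carlo bands in the assertions
are still tight enough to be meaningful. Every stochastic stage takes an
explicit seed; the pipeline derives per-stage substreams from a master
seed by hashing stage names, so single-stage reruns reproduce the full-run
result and repeated runs are byte-identical.

## Known limitations

* The AMOVA distance rescaling under missingness assumes missingness is
  unrelated to genotype; informative missingness would bias components.
* Permutation p-values are tie-inclusive and hence conservative for
  low-information loci.
* The dispersal model inherits all assumptions of one-dimensional IBD
  theory (drift–migration equilibrium, uniform density, narrow habitat)
  and its constant is a calibration, not a derivation.
* The simulator is strictly two demes, no mutation, selection or linkage;
  at T = 1,000 and small m it approximates, but does not guarantee,
  migration–drift equilibrium.
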