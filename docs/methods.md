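# Methods

This note documents the statistical models and simulators in `founderpop`,
the defaults they run under, the numerical choices that are not visible
from the API, and what the synthetic-data tests do and do not demonstrate
about real data.

## Sequence diversity

Haplotype diversity is the small-sample-corrected heterozygosity of the
haplotype spectrum, h = n(1 − Σp²)/(n − 1), with Nei's (1987, eq. 8.12)
sampling variance. Nucleotide diversity π is the mean proportion of
differing sites over all C(n, 2) sequence pairs; sites carrying N or an
alignment gap in either sequence of a pair are excluded pairwise, so π is
per *valid* site. Its SD is the total (stochastic + sampling) variance of
Nei (1987, eq. 10.7). Both reduce to the textbook haplotype-frequency
forms; the pair-average implementation is the brute-force oracle used in
the tests.

Haplotype labels (`Hap01`, `Hap02`, …) are assigned by first occurrence
after sorting individual ids, so collapsing is deterministic and
insensitive to record order in the input FASTA.

## Microsatellite diversity

All per-locus statistics use locus-wise pairwise deletion: each locus uses
the individuals fully typed at that locus. The missing sentinel is 0; a
half-missing genotype is coerced to fully missing so that no statistic ever
sees a single gene copy of a diploid.

Rarefaction works in gene copies (2 per typed individual). For a locus
with N gene copies of which N_i belong to allele i, the probability that
allele i appears in a rarefied draw of g copies is
1 − C(N − N_i, g)/C(N, g); allelic richness A_R sums this over alleles and
averages over loci. Private allelic richness A_P multiplies each allele's
focal presence probability by the probability it is absent from every
other population's independent rarefied draw of the same g. The default g
is the smallest per-locus gene-copy count over the populations being
compared. Binomial coefficients go through log-gamma, so large samples
cannot overflow.

Expected heterozygosity carries Nei's unbiased factor 2n/(2n − 1). F_IS is
the single-population Weir & Cockerham (1984) f assembled from per-allele
b and c variance components summed over alleles and loci; it is exactly −1
for a fully heterozygous biallelic sample and 0 in expectation at
Hardy–Weinberg proportions.

The Hardy–Weinberg test conditions on allele counts. When the number of
distinct genotype tables is at most 10⁵ the p-value is computed by
complete enumeration (the per-table conditional probability uses the
2^het multinomial form; the enumerated probabilities sum to 1 in the
tests); larger tables fall back to seeded Monte-Carlo permutation of gene
copies, with p = (b + 1)/(m + 1). Bonferroni correction multiplies by the
number of tests and caps at 1.

## Differentiation

Φ_ST and R_ST are two-level AMOVA fixation indices. For sequences, the
squared inter-individual distance is the pairwise nucleotide difference
count between haplotypes; for microsatellites the analysis is at the
gene-copy level with squared allele-size differences, and the among/within
variance components are summed over loci before the ratio is formed (not
averaged per locus). Significance comes from permuting individuals between
the two populations, p = (b + 1)/(m + 1), default 10,000 permutations.
Small negative values are legitimate estimator noise; on two samples of
one panmictic source (n = 60 each) |Φ_ST| and |R_ST| stay below 0.02.

Isolation by distance correlates, over all (non-reference individual,
reference individual) pairs, an individual-pair genetic distance with the
geodesic distance between their sites. The genetic distance is Nei's
(1972) standard distance applied to the two individuals' allele-frequency
vectors (entries 0/0.5/1), J-terms averaged over shared typed loci; a pair
sharing no alleles anywhere gets +inf, which rank statistics handle
naturally. Geographic distance is the iterative Vincenty inverse solution
on the WGS-84 ellipsoid (checked against an independent geodesy
implementation to sub-metre agreement). The permutation null shuffles the
site assignments of non-reference individuals; an asymptotic Spearman p is
also available.

## LD effective population size

Burrows' composite disequilibrium between unphased loci is estimated per
allele pair as Δ̂ = n/(n−1) · (mean(g·h)/2 − 2p̂q̂) from gene counts g, h ∈
{0, 1, 2}, and r² = Δ̂²/(p̂(1−p̂)q̂(1−q̂)). The n/(n−1) factor matters: with
it, the observed mean r² of independent loci matches the sampling
expectation E[r²] = 1/S + 3.19/S² (S ≥ 30; for S < 30,
0.0018 + 0.907/S + 4.44/S²) — verified here by simulation at S = 50
(observed 0.02133 vs 0.02128). A locus pair's r² is the mean over its
allele combinations, computed on pairwise-complete individuals with
frequencies from that subset; locus pairs are combined by an
n-weighted mean with the harmonic mean S entering the bias formula.
Alleles below the MAF cutoff are dropped, not pooled; loci monomorphic
after screening are skipped.

The drift transform is N̂e = (1/3 + √(1/9 − 2.76 r²'))/(2 r²') for S ≥ 30
and (0.308 + √(0.308² − 2.08 r²'))/(2 r²') below, where r²' is the mean r²
minus its sampling expectation; a non-positive r²' (or negative
discriminant) reports +inf — no drift signal resolvable. The 95% CI is a
delete-one jackknife over locus pairs on the mean r², converted to a
normal-theory band and pushed through the transform (the lower r² bound
gives the upper Ne bound; it is +inf whenever that bound falls below the
sampling expectation).

Known sensitivity: with many rare alleles near the cutoff at small sample
sizes (e.g. 8-allele loci at S = 25, MAF 0.05) the estimate is biased
upward — a documented property of the method, which is why published
guidance raises the cutoff for small samples. The calibration tests
therefore use loci segregating 2–4 alleles (the realistic state of a small
drifted population); under those conditions the median estimate is within
25% of truth for N ∈ {25, 50, 100}, with more replicates at N = 25 where
the estimator's sampling variance is largest.

## Founder-female simulation

Each replicate draws k maternal haplotypes i.i.d. from the source
frequency spectrum and counts distinct haplotypes; this is the
large-source limit of drawing k females from a realized source population,
and is exact as the source size grows. A finite-source mode (drawing
without replacement from a multinomially realized pool, default 178 copies
= 2 × 89 individuals) is available for sensitivity. The analytic
expectation E[H] = Σ_h (1 − (1 − p_h)^k) is the oracle: Monte-Carlo means
agree within 3 SE in the tests. "Consistent with the observed haplotype
number" is operationalized as the interquartile range of the replicate
distribution containing the observation (the replicate summaries are
exactly box-plot statistics); a median-equality rule is available. The
default is 100 repetitions per k over k = 1…10. Haplotype loss *after*
founding is deliberately not modelled in this stage — the bottleneck/drift
simulator handles post-founding loss for nuclear markers — so the inferred
k is a lower bound on the true female founder number.

## Forward simulator

An individual carries a sex, an age in years, one diploid genotype per
locus (allele identities drawn allele-wise from the source frequencies —
linkage equilibrium, since per-locus genotype tables are generally not
published for source populations), and optionally a maternal haplotype.
Defaults: lifespan 4 years, maturation at 2, pre-bottleneck pool of 100,
founder sex ratio 1:3 female:male applied exactly (rounded counts; e.g.
B = 40 → 10 females, 30 males), newborn sex Bernoulli(1/2), capacity 5000,
100 simulated years. Founder ages are uniform on {1, …, lifespan − 1} so a
founder cohort is never artificially synchronized into a reproduction gap.

Yearly update: survivors age and die deterministically past the lifespan;
the logistic recurrence N* = N + (λ−1)N(1 − N/K) sets the target census;
the shortfall is filled by newborns, each taking an independently uniform
mature mother and mature father (lottery polygamy, unlimited fecundity —
amphibian clutch sizes make fecundity non-limiting); extinction is
declared when births are required but no mature pair exists. Statistics
(census, mean alleles per locus N_a, expected heterozygosity) are recorded
after each year's survival + reproduction; year 0 is the founder state.

Two numerical points. First, the integer-rounded logistic recurrence traps
small populations (an increment under 0.5 rounds to zero forever), so the
simulator stochastically rounds the fractional individual — the expected
trajectory is exactly the recurrence at every size, and the deterministic
`logistic_target` helper retains the plain rounded form for closed-form
checks. Second, a discrete-generation mode (whole population replaced each
year; with `dioecious=False` parents are drawn independently with selfing
allowed) reproduces the classical Wright–Fisher heterozygosity decay
H_t = H_0 (1 − 1/(2N))^t exactly in expectation — measured within 0.1% at
N = 50, t = 20 — and doubles as the constant-size generator for the LD-Ne
calibration. A `max_recruits_per_female` hook caps yearly recruitment for
sensitivity analyses; it defaults to unlimited.

Known model limitation: with unlimited fecundity, even 4 founder females
keep a population demographically viable, so extreme male-biased founder
ratios (1:9) produce only 8–28% extinction here rather than the
near-certain extinction some age-structured bottleneck simulators report
for fewer than ~6 females; that behaviour evidently requires a per-female
recruitment limit or generation-resampling rule whose parameters are not
recoverable from published descriptions. The corresponding acceptance test
is expected to fail under the default model and is retained as an explicit
record of the discrepancy.

## Grid-matching inference

The scenario grid crosses B ∈ {20, 40, 60, 80} with λ ∈ {1.02, 1.04, 1.06,
1.08, 1.10}. A growth rate is accepted when the mean census at the
evaluation year (default 90: introduction ≈ 90 years before sampling;
simulations run to 100) lies inside the observed census range for at least
one not-fully-extinct founder size. The census mean is taken over *all*
iterations with extinct replicates contributing zero: the question is
which growth rates make the introduction, as planned, *expected* to yield
the observed census — an expectation over demographic outcomes; a
surviving-only aggregation is exposed on the trajectory objects. N_a
summaries, by contrast, are over surviving iterations only (an extinct
population has no allele count).

A founder size is accepted when the observed N_a falls inside the central
band of its terminal N_a distribution for at least one accepted λ. The
default band is mean ± 1 SD — a deliberate formalization of matching a
dashed line against simulated curves, and intentionally strict (it covers
~68% of replicates). For *parameter recovery* experiments the calibrated
2.5–97.5% quantile band is the appropriate acceptance region (a ±1 SD band
cannot contain ~95% of repeated observations by construction); both rules
are switchable. Self-consistency at 200 iterations per scenario: over a
3×3 truth grid with 20 single-run observations per cell, the true B lands
in the quantile-rule accepted set in ≈99% of trials.

N_e/N_c combines the extreme quotients of the two ranges,
[min Ne/max Nc, max Ne/min Nc], rounded to 1 significant figure by default
(the convention such ratio ranges are reported in; the precision is a
parameter).

Problem sizes used by the test suite: 200 iterations per grid scenario
(4 × 5 grid), 20 recovery trials per truth cell, 100–200 replicates per
LD-Ne calibration point, 100 iterations for the heterozygosity-decay
check. These are the package's standard verification sizes; the library
itself defaults to 1000 iterations per scenario.

## Synthetic data generator

The generator produces *source models* (haplotype spectrum + per-locus
allele frequencies), then samples datasets from them. The default targets
mirror a diverse coastal source population: 38 haplotypes at diversity
0.967 in n = 89, and 11 loci with ≈17.3 alleles observable per locus at
H_E ≈ 0.795; a second preset mirrors the bottlenecked descendant
(2 haplotypes, h 0.433, 11 loci, N_a 6.0, H_E 0.581).

Haplotype spectra are geometric with Dirichlet perturbation — so rare
haplotypes exist, as in real spectra — rescaled by bisection on the
geometric ratio until 1 − Σp² matches the target within 10⁻³. Allele
spectra cannot be geometric: a geometric tail at H_E ≈ 0.8 saturates near
13 observable alleles regardless of how many exist. Each locus instead
carries one dominant allele plus a Dirichlet-jittered near-uniform tail;
the dominant frequency follows from H_E in closed form
(p₀ = [c + √(1 − H_E(1 + c))]/(1 + c), c = Σ tail²), and the tail length is
chosen so the expected number of distinct alleles in a sample of 2n copies
hits the target (mixing two adjacent tail lengths across loci to hit a
fractional mean). Allele sizes sit on a dinucleotide-like ladder.

Synthetic sequences: haplotype i carries i private substitutions at
globally disjoint positions of a random reference (default length 1827),
so all haplotypes are pairwise distinct by construction and inter-haplotype
distances are positive and increasing in the label index. The sequences
live on the source model, so independent samples from one source agree on
them.

The radial layout places sites due north of an origin at evenly spaced
geodesic distances (positions solved by bisection against the Vincenty
distance). The serial-founder dataset seeds each successive site's
frequencies from the previous one through a founder event of 4 diploids by
default, embedding an isolation-by-distance signal whose detectability was
checked at 8 sites × 20 individuals (median ρ ≈ 0.18, median permutation
p ≈ 0.003 over replicates); shorter chains make the site-level random walk
too often non-monotone for a rank test, which mirrors the weak-but-real
signals typical of fine-scale empirical IBD.

What passing these closed-loop tests shows — and does not. The generator
reproduces the *marginal* summary statistics the analyses consume
(spectrum shape, heterozygosity, allele counts, drift structure between
populations), under linkage equilibrium, selective neutrality, exact
Hardy–Weinberg reproduction, and no genotyping error, null alleles, or
allelic dropout. Real microsatellite data violate several of these —
loci are routinely dropped in practice for HWE departures and null
alleles — so the tests validate the estimators and the inference logic,
not the field accuracy of any particular dataset.

## Degenerate inputs and tie-breaking

Monomorphic loci: skipped by the HWE test and LD screening with notice;
A_R reports exactly 1. Zero total molecular variance makes Φ_ST/R_ST
undefined and raises. Permutation p-values use the (b + 1)/(m + 1) form,
so p = 0 is impossible. Ne estimates report +inf rather than clamping.
Half-missing genotypes become fully missing. All simulations accept a
single integer seed and are bit-reproducible; replicate streams come from
`SeedSequence.spawn`, so iteration counts do not perturb one another.
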