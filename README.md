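# founderpop

Population-genetic inference of an introduction history: how many founders
started an isolated population, and how did it grow?

`founderpop` implements the full analysis chain used to reconstruct the
founding of a small, isolated amphibian population established by a single
historical translocation — the motivating case is the oriental fire-bellied
toad population of Beijing, descended from roughly 200 animals moved from
Yantai in 1927 and never supplemented since. The same chain applies to any
introduced or reintroduced population with one candidate source:

- **Diversity** — haplotype diversity *h* and nucleotide diversity *π* from
  aligned mtDNA sequences (with Nei 1987 sampling SDs); allele counts,
  private alleles, rarefied allelic richness *A*<sub>R</sub> and private
  richness *A*<sub>P</sub> (HP-RARE-style rarefaction over gene copies),
  observed/unbiased expected heterozygosity, and the Weir & Cockerham
  (1984) inbreeding coefficient *f* for microsatellite genotypes.
- **Differentiation** — pairwise Φ<sub>ST</sub> (AMOVA on inter-haplotype
  nucleotide differences) and R<sub>ST</sub> (AMOVA on squared allele-size
  differences, variance components summed over loci), permutation
  p-values; Hardy–Weinberg exact tests (full enumeration or Guo–Thompson
  Monte Carlo) with Bonferroni correction; isolation by distance via
  Spearman's ρ between Nei genetic distance and Vincenty (WGS-84) geodesic
  distance from a reference site.
- **Effective population size** — the single-sample LD method: Burrows'
  composite disequilibrium Δ̂ between unphased loci,
  r² = Δ̂²/(p(1−p)q(1−q)), the finite-sample expectation
  E[r²] = 1/S + 3.19/S² (S ≥ 30), and
  N̂<sub>e</sub> = (1/3 + √(1/9 − 2.76 r²'))/(2 r²') with delete-one
  jackknife confidence intervals over locus pairs and MAF screening at
  cutoffs {0, 0.01, 0.02, 0.05}.
- **Founder-female number** — how many females must be drawn from the
  source haplotype spectrum to retain the observed number of mtDNA
  haplotypes (replicated draws per candidate k, with the analytic oracle
  E[H] = Σ<sub>h</sub> (1 − (1 − p<sub>h</sub>)<sup>k</sup>)).
- **Founding bottleneck and drift** — an individual-based, age-structured
  forward simulator with completely overlapping generations (lifespan 4,
  maturation 2), dioecious lottery mating, logistic growth
  N* = N + (λ−1)N(1 − N/K) to capacity K = 5000, founder sizes
  B ∈ {20, 40, 60, 80} and growth rates λ ∈ {1.02 … 1.10}, tracking the
  mean allele number per locus N<sub>a</sub>, census size, heterozygosity,
  and extinction.
- **Grid-matching inference** — which (B, λ) scenarios reproduce both the
  observed census range (Lincoln–Petersen mark–recapture estimate,
  extrapolated over breeding sites) and the observed N<sub>a</sub> about
  90 years after introduction, plus the N<sub>e</sub>/N<sub>c</sub> ratio.
- **Synthetic data** — generators for source populations, genotype and
  sequence samples, and radial site layouts with a serial-founder
  isolation-by-distance signal, so every stage is testable offline.

## Worked example

```python
from founderpop import (
    lincoln_petersen, ne_nc_ratio, haplotype_diversity,
    make_source_model, draw_females, infer_female_range,
)
from founderpop.synthetic import yantai_like_spec

# Census at one breeding waterhole: 81 marked, 51 captured a week later,
# 21 of them marked.
est = lincoln_petersen(81, 51, 21)
print(est.N_c_hat)                       # 197

# Effective/census size ratio from Ne 20-57 and Nc 1500-4000:
print(ne_nc_ratio((20, 57), (1500, 4000)))   # (0.005, 0.04)

# Haplotype diversity of a two-haplotype population (counts 103 and 47):
h, sd = haplotype_diversity([103, 47])
print(round(h, 3), round(sd, 3))         # 0.433 0.029

# How many founder females could leave 2 haplotypes, given a source with
# 38 haplotypes at diversity 0.967?
model = make_source_model(yantai_like_spec(seed=7))
results = [draw_females(model, k, reps=100, seed=100 + k) for k in range(1, 11)]
print(infer_female_range(results, observed_haplotypes=2))   # {2}
```

`lincoln_petersen` says about 197 toads used the surveyed waterhole; at
150–200 per site over 10–20 breeding sites that extrapolates to a census of
1500–4000, which against N<sub>e</sub> = 20–57 gives the very low
N<sub>e</sub>/N<sub>c</sub> ratio 0.005–0.04. The founder-female draw shows
that a handful of females (here k = 2; the interquartile band rule) suffices
to carry two haplotypes out of a diverse source.

The same analyses are scriptable from the shell:

```sh
founder census --marked 81 --captured 51 --recaptured 21 \
    --per-site 150:200 --sites 10:20
# N_hat = 197
# total N_c range = 1500-4000

founder synth --preset yantai-like --seed 7 --out demo/
founder ne --genotypes demo/genotypes.csv --pop yantai \
    --maf 0,0.01,0.02,0.05 --out demo/ne.csv
```

Subcommands: `stats`, `diff`, `ibd`, `census`, `ne`, `mtdna-sim`,
`forward-sim`, `infer`, `synth`. Every run writes a JSON manifest with its
parameters and seed.

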