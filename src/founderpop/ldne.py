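"""Contemporary effective population size from linkage disequilibrium.

Implements the single-sample LD method: Burrows' composite disequilibrium
Delta-hat between unphased diploid loci, the squared correlation
r^2 = Delta^2 / (pA(1-pA) pB(1-pB)), the finite-sample expectation of r^2
under random mating, and the drift-signal transform

    Ne_hat = (1/3 + sqrt(1/9 - 2.76 r2'))/(2 r2')        (S >= 30)
    Ne_hat = (0.308 + sqrt(0.308^2 - 2.08 r2'))/(2 r2')  (S < 30)

with r2' the mean r^2 minus its sampling expectation.  A non-positive
drift signal (or a negative discriminant) yields an infinite estimate.
Confidence intervals are delete-one jackknife over locus pairs on the mean
r^2, propagated through the transform.  Alleles rarer than the MAF cutoff
are dropped, not pooled; loci monomorphic after screening are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import MISSING, GenotypeTable

Z95 = 1.959963984540054


@dataclass
class AllelePairR2:
    """Per-allele-pair composite-LD r-squared values for one locus pair."""

    locus_a: str
    locus_b: str
    n: int  # individuals typed at both loci
    r2_values: np.ndarray  # one value per (allele_a, allele_b) combination

    @property
    def mean_r2(self) -> float:
        return float(self.r2_values.mean())


@dataclass
class NeEstimate:
    maf_cutoff: float
    r2_mean: float
    r2_expected: float
    ne_hat: float  # finite positive or +inf
    ci_low: float | None = None
    ci_high: float | None = None
    s_harmonic: float | None = None
    n_pairs: int = 0
    pair_results: list[AllelePairR2] = field(default_factory=list, repr=False)


def _screened_gene_counts(
    alleles: np.ndarray, maf_cutoff: float
) -> tuple[np.ndarray, np.ndarray] | None:
    """(gene-count matrix per kept allele, frequencies) or None if <2 alleles."""
    values, counts = np.unique(alleles, return_counts=True)
    freqs = counts / counts.sum()
    keep = freqs >= maf_cutoff
    values, freqs = values[keep], freqs[keep]
    if values.size < 2:
        return None
    g = (alleles[:, :, None] == values[None, None, :]).sum(axis=1)  # (n, K)
    return g.astype(float), freqs


def burrows_r2(
    table: GenotypeTable,
    locus_a: str,
    locus_b: str,
    maf_cutoff: float = 0.0,
    population: str | None = None,
) -> AllelePairR2:
    """Burrows' composite-disequilibrium r^2 per allele pair of two loci.

    Computed on individuals typed at both loci; allele frequencies are taken
    from that pairwise-complete subset.  Delta-hat carries the n/(n-1)
    small-sample correction.
    """
    sub = table if population is None else table.subset(population)
    ja, jb = sub.loci.index(locus_a), sub.loci.index(locus_b)
    typed = sub.typed_mask()
    rows = typed[:, ja] & typed[:, jb]
    n = int(rows.sum())
    if n < 2:
        raise ValueError("need >=2 individuals typed at both loci")
    ga = _screened_gene_counts(sub.alleles[rows, ja, :], maf_cutoff)
    gb = _screened_gene_counts(sub.alleles[rows, jb, :], maf_cutoff)
    if ga is None or gb is None:
        raise ValueError("a locus is monomorphic after MAF screening: pair skipped")
    counts_a, p = ga
    counts_b, q = gb
    # Delta_ab = n/(n-1) * ( E[g h]/2 - 2 p q ) for every allele combination
    cross = counts_a.T @ counts_b / n  # (Ka, Kb) mean of g*h
    delta = (n / (n - 1.0)) * (cross / 2.0 - 2.0 * np.outer(p, q))
    denom = np.outer(p * (1.0 - p), q * (1.0 - q))
    r2 = (delta**2) / denom
    return AllelePairR2(locus_a, locus_b, n, r2.ravel())


def _expected_r2(s: float) -> float:
    if s >= 30:
        return 1.0 / s + 3.19 / s**2
    return 0.0018 + 0.907 / s + 4.44 / s**2


def _ne_from_r2prime(r2p: float, s: float) -> float:
    if r2p <= 0:
        return np.inf
    if s >= 30:
        disc = 1.0 / 9.0 - 2.76 * r2p
        if disc < 0:
            return np.inf
        return (1.0 / 3.0 + np.sqrt(disc)) / (2.0 * r2p)
    disc = 0.308**2 - 2.08 * r2p
    if disc < 0:
        return np.inf
    return (0.308 + np.sqrt(disc)) / (2.0 * r2p)


def _collect_pairs(
    table: GenotypeTable, population: str, maf_cutoff: float
) -> list[AllelePairR2]:
    sub = table.subset(population)
    pairs: list[AllelePairR2] = []
    for a in range(len(sub.loci)):
        for b in range(a + 1, len(sub.loci)):
            try:
                pairs.append(
                    burrows_r2(sub, sub.loci[a], sub.loci[b], maf_cutoff=maf_cutoff)
                )
            except ValueError:
                continue
    return pairs


def _weighted_summary(pairs: list[AllelePairR2]) -> tuple[float, float]:
    """(weighted mean r2, harmonic mean S) over locus pairs; weight = n."""
    w = np.array([p.n for p in pairs], float)
    r2 = np.array([p.mean_r2 for p in pairs])
    r2_mean = float((w * r2).sum() / w.sum())
    s_harm = float(len(pairs) / (1.0 / w).sum())
    return r2_mean, s_harm


def ldne_estimate(
    table: GenotypeTable,
    population: str,
    maf_cutoff: float = 0.0,
    ci: bool = True,
    level: float = 0.95,
) -> NeEstimate:
    """LD-based single-sample Ne estimate for one population at one MAF cutoff."""
    pairs = _collect_pairs(table, population, maf_cutoff)
    if len(pairs) < 1:
        raise ValueError("fewer than 2 usable polymorphic loci")
    r2_mean, s_harm = _weighted_summary(pairs)
    e_r2 = _expected_r2(s_harm)
    ne = _ne_from_r2prime(r2_mean - e_r2, s_harm)
    est = NeEstimate(
        maf_cutoff=maf_cutoff,
        r2_mean=r2_mean,
        r2_expected=e_r2,
        ne_hat=float(ne),
        s_harmonic=s_harm,
        n_pairs=len(pairs),
        pair_results=pairs,
    )
    if ci:
        lo, hi = _jackknife_bounds(pairs, level=level)
        est.ci_low, est.ci_high = lo, hi
    return est


def _jackknife_bounds(
    pairs: list[AllelePairR2], level: float = 0.95
) -> tuple[float, float]:
    j = len(pairs)
    if j < 3:
        raise ValueError("jackknife CI needs >=3 locus pairs")
    thetas = np.empty(j)
    for k in range(j):
        rest = pairs[:k] + pairs[k + 1 :]
        thetas[k], _ = _weighted_summary(rest)
    r2_mean, s_harm = _weighted_summary(pairs)
    var = (j - 1.0) / j * ((thetas - thetas.mean()) ** 2).sum()
    se = float(np.sqrt(var))
    from scipy.stats import norm

    z = Z95 if abs(level - 0.95) < 1e-9 else float(norm.ppf(0.5 + level / 2.0))
    e_r2 = _expected_r2(s_harm)
    r2_lo, r2_hi = r2_mean - z * se, r2_mean + z * se
    ci_low = _ne_from_r2prime(r2_hi - e_r2, s_harm)  # large r2 -> small Ne
    ci_high = _ne_from_r2prime(r2_lo - e_r2, s_harm)
    return float(ci_low), float(ci_high)


def jackknife_ci(
    table: GenotypeTable, population: str, maf_cutoff: float = 0.0, level: float = 0.95
) -> tuple[float, float]:
    """95% jackknife CI bounds on Ne (delete-one over locus pairs)."""
    pairs = _collect_pairs(table, population, maf_cutoff)
    return _jackknife_bounds(pairs, level=level)


def ldne_table(
    table: GenotypeTable,
    population: str,
    maf_cutoffs: tuple[float, ...] = (0.05, 0.02, 0.01, 0.0),
) -> list[NeEstimate]:
    """Ne estimates across the standard MAF screening grid."""
    return [
        ldne_estimate(table, population, maf_cutoff=c, ci=True) for c in maf_cutoffs
    ]
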