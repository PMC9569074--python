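"""Within-population diversity statistics.

Sequence side: haplotype diversity h with its sampling SD, and per-site
nucleotide diversity pi with SD (Nei 1987, eqs. 8.4/8.12 and 10.5/10.7).
Microsatellite side: allele counts and private alleles, rarefied allelic
richness and private allelic richness (HP-RARE style, in units of gene
copies), observed/unbiased-expected heterozygosity, and the Weir &
Cockerham (1984) within-population inbreeding coefficient f (= F_IS).

Missing data are handled by locus-wise pairwise deletion: every per-locus
statistic uses the individuals typed at that locus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datatypes import MISSING, GenotypeTable, HaplotypeDataset


# ---------------------------------------------------------------------------
# mtDNA: haplotype and nucleotide diversity
# ---------------------------------------------------------------------------

def haplotype_diversity(counts) -> tuple[float, float]:
    """Haplotype diversity h = n(1 - sum p_i^2)/(n - 1) and its SD.

    The variance is Nei's (1987) estimator:
    V(h) = 2/(n(n-1)) * { 2(n-2)[sum p^3 - (sum p^2)^2] + sum p^2 - (sum p^2)^2 }.
    """
    c = np.asarray(counts, dtype=float)
    if c.size == 0 or (c <= 0).any() or not np.allclose(c, np.round(c)):
        raise ValueError("counts must be positive integers")
    n = c.sum()
    if n < 2:
        raise ValueError("need at least two sequences")
    p = c / n
    s2 = float((p**2).sum())
    s3 = float((p**3).sum())
    h = n * (1.0 - s2) / (n - 1.0)
    var = (2.0 / (n * (n - 1.0))) * (2.0 * (n - 2.0) * (s3 - s2**2) + s2 - s2**2)
    return h, float(np.sqrt(max(var, 0.0)))


def pairwise_differences(a: str, b: str) -> tuple[int, int]:
    """(differences, valid sites) for two aligned sequences.

    Sites containing N or a gap in either sequence are excluded pairwise.
    """
    x = np.frombuffer(a.upper().encode(), dtype="S1")
    y = np.frombuffer(b.upper().encode(), dtype="S1")
    if x.size != y.size:
        raise ValueError("sequences differ in length")
    bad = np.isin(x, [b"N", b"-"]) | np.isin(y, [b"N", b"-"])
    valid = ~bad
    return int((x[valid] != y[valid]).sum()), int(valid.sum())


def nucleotide_diversity(dataset: HaplotypeDataset) -> tuple[float, float]:
    """Per-site nucleotide diversity pi (mean over all sequence pairs) and SD.

    pi is the average proportion of differing sites over all C(n,2)
    individual pairs (pairwise-valid sites only), which equals the
    n/(n-1)-corrected haplotype-frequency form.  The SD is Nei's (1987)
    eq. 10.7 total variance (stochastic + sampling).
    """
    if dataset.sequences is None:
        raise ValueError("dataset carries no aligned sequences")
    counts = dataset.haplotype_counts()
    seq_of = dataset.haplotype_sequences()
    haps = list(counts.index)
    n = int(counts.sum())
    if n < 2:
        raise ValueError("need at least two sequences")
    total = 0.0
    npairs = n * (n - 1) / 2.0
    for i, hi in enumerate(haps):
        ci = counts[hi]
        for j in range(i, len(haps)):
            hj = haps[j]
            if i == j:
                continue
            d, valid = pairwise_differences(seq_of[hi], seq_of[hj])
            if valid == 0:
                raise ValueError("a sequence pair shares no valid sites")
            total += counts[hi] * counts[hj] * d / valid
        _ = ci
    pi = total / npairs
    L = len(next(iter(seq_of.values())))
    var = ((n + 1.0) / (3.0 * (n - 1.0))) * pi / L + (
        2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    ) * pi**2
    return float(pi), float(np.sqrt(max(var, 0.0)))


# ---------------------------------------------------------------------------
# Microsatellites: allele counts, rarefaction, heterozygosity, F_IS
# ---------------------------------------------------------------------------

def allele_summary(
    table: GenotypeTable, focal_pop: str, other_pops: list[str]
) -> dict[str, float]:
    """Total alleles N_A, private alleles N_PA, and mean alleles/locus N_a."""
    if focal_pop not in table.populations:
        raise ValueError(f"empty population {focal_pop!r}")
    n_a_total = 0
    n_private = 0
    for locus in table.loci:
        focal = set(table.allele_counts(locus, focal_pop).index)
        others: set[int] = set()
        for p in other_pops:
            others |= set(table.allele_counts(locus, p).index)
        n_a_total += len(focal)
        n_private += len(focal - others)
    return {
        "N_A": float(n_a_total),
        "N_PA": float(n_private),
        "N_a": n_a_total / len(table.loci),
    }


def _log_comb(n: np.ndarray | float, k: float) -> np.ndarray:
    return gammaln(np.asarray(n, float) + 1) - gammaln(k + 1) - gammaln(np.asarray(n, float) - k + 1)


def _prob_absent(n_total: int, n_allele: np.ndarray, g: int) -> np.ndarray:
    """P(allele with n_allele copies absent from a rarefied sample of g copies)."""
    n_allele = np.asarray(n_allele, dtype=float)
    out = np.zeros_like(n_allele, dtype=float)
    possible = n_total - n_allele >= g
    out[possible] = np.exp(
        _log_comb(n_total - n_allele[possible], g) - _log_comb(float(n_total), g)
    )
    return out


def rarefied_richness(
    table: GenotypeTable, g: int, populations: list[str] | None = None
) -> pd.DataFrame:
    """Rarefied allelic richness A_R and private allelic richness A_P.

    Per locus, ``A_R = sum_i [1 - C(N_l - N_i, g)/C(N_l, g)]`` with N_l the
    population's valid gene copies at that locus and N_i the copies of allele
    i; A_P multiplies the focal presence probability by the probability that
    the allele is absent from every other population's rarefied sample.  The
    population value is the mean over loci; ``g`` is in gene copies.
    """
    pops = populations or table.population_names
    if g < 2:
        raise ValueError("rarefaction size g must be >= 2 gene copies")
    for pop in pops:
        for locus in table.loci:
            if int(table.allele_counts(locus, pop).sum()) < g:
                raise ValueError(
                    f"g={g} exceeds gene copies of {pop!r} at {locus!r}"
                )
    rows = []
    for pop in pops:
        ar_per_locus = []
        ap_per_locus = []
        for locus in table.loci:
            counts = table.allele_counts(locus, pop)
            n_l = int(counts.sum())
            present = 1.0 - _prob_absent(n_l, counts.to_numpy(), g)
            ar_per_locus.append(float(present.sum()))
            absent_elsewhere = np.ones(len(counts))
            for other in pops:
                if other == pop:
                    continue
                oc = table.allele_counts(locus, other)
                n_o = int(oc.sum())
                n_in_other = np.array([oc.get(a, 0) for a in counts.index], float)
                absent_elsewhere *= _prob_absent(n_o, n_in_other, g)
            ap_per_locus.append(float((present * absent_elsewhere).sum()))
        rows.append(
            {"population": pop, "A_R": np.mean(ar_per_locus), "A_P": np.mean(ap_per_locus)}
        )
    return pd.DataFrame(rows).set_index("population")


def min_gene_copies(table: GenotypeTable, populations: list[str] | None = None) -> int:
    """Smallest per-locus gene-copy count over populations (rarefaction g)."""
    pops = populations or table.population_names
    return min(
        int(table.allele_counts(locus, pop).sum())
        for pop in pops
        for locus in table.loci
    )


def heterozygosities(table: GenotypeTable, population: str) -> pd.DataFrame:
    """Observed and unbiased expected heterozygosity per locus.

    H_E uses Nei's unbiased correction (2n/(2n-1))(1 - sum p^2).  Loci with
    no typed individual are omitted from the result.
    """
    sub = table.subset(population)
    typed = sub.typed_mask()
    rows = []
    for j, locus in enumerate(sub.loci):
        mask = typed[:, j]
        n = int(mask.sum())
        if n == 0:
            continue
        geno = sub.alleles[mask, j, :]
        ho = float((geno[:, 0] != geno[:, 1]).mean())
        freqs = sub.allele_frequencies(locus, population).to_numpy()
        he = (2.0 * n / (2.0 * n - 1.0)) * (1.0 - float((freqs**2).sum())) if n > 0 else np.nan
        rows.append({"locus": locus, "n": n, "H_O": ho, "H_E": he})
    return pd.DataFrame(rows).set_index("locus")


def fis(table: GenotypeTable, population: str) -> float:
    """Weir & Cockerham (1984) within-population inbreeding coefficient f.

    Per locus and allele u, with n typed individuals, sample frequency p_u
    and observed heterozygote proportion H_u involving u:
    b_u = n/(n-1) [ p_u(1-p_u) - (2n-1)/(4n) H_u ],  c_u = H_u / 2,
    and f = 1 - sum(c) / sum(b + c) over all alleles and loci.
    """
    sub = table.subset(population)
    typed = sub.typed_mask()
    sum_b = 0.0
    sum_c = 0.0
    informative = False
    for j, locus in enumerate(sub.loci):
        mask = typed[:, j]
        n = int(mask.sum())
        if n < 2:
            continue
        geno = sub.alleles[mask, j, :]
        freqs = sub.allele_frequencies(locus, population)
        if len(freqs) < 2:
            continue
        informative = True
        het = geno[:, 0] != geno[:, 1]
        for allele, p in freqs.items():
            h_u = float((het & ((geno == allele).any(axis=1))).mean())
            b = (n / (n - 1.0)) * (p * (1.0 - p) - (2.0 * n - 1.0) / (4.0 * n) * h_u)
            sum_b += b
            sum_c += h_u / 2.0
    if not informative or (sum_b + sum_c) == 0.0:
        raise ValueError("F_IS undefined: no polymorphic locus with >=2 typed individuals")
    return 1.0 - sum_c / (sum_b + sum_c)


@dataclass
class DiversitySummary:
    """One population's row of the diversity table."""

    population: str
    N: int
    n_hap: int | None = None
    h: float | None = None
    h_sd: float | None = None
    pi: float | None = None
    pi_sd: float | None = None
    N_A: float | None = None
    N_PA: float | None = None
    N_a: float | None = None
    A_R: float | None = None
    A_P: float | None = None
    H_O: float | None = None
    H_E: float | None = None
    F_IS: float | None = None


def diversity_table(
    haplotypes: HaplotypeDataset | None,
    genotypes: GenotypeTable | None,
    populations: list[str] | None = None,
    rarefaction_g: int | None = None,
) -> pd.DataFrame:
    """Assemble the per-population diversity summary table."""
    if haplotypes is None and genotypes is None:
        raise ValueError("need at least one of haplotypes/genotypes")
    if populations is None:
        src = genotypes if genotypes is not None else haplotypes
        seen: dict[str, None] = {}
        for p in src.populations:  # type: ignore[union-attr]
            seen.setdefault(p)
        populations = list(seen)
    rows = []
    rar = None
    if genotypes is not None:
        g = rarefaction_g or min_gene_copies(genotypes, populations)
        rar = rarefied_richness(genotypes, g, populations)
    for pop in populations:
        row = DiversitySummary(population=pop, N=0)
        if haplotypes is not None and pop in haplotypes.populations:
            sub = haplotypes.subset({pop})
            counts = sub.haplotype_counts()
            row.N = int(counts.sum())
            row.n_hap = len(counts)
            if counts.sum() >= 2:
                row.h, row.h_sd = haplotype_diversity(counts.to_numpy())
                if sub.sequences is not None:
                    row.pi, row.pi_sd = nucleotide_diversity(sub)
        if genotypes is not None and pop in genotypes.populations:
            others = [p for p in populations if p != pop]
            summary = allele_summary(genotypes, pop, others)
            row.N_A, row.N_PA, row.N_a = summary["N_A"], summary["N_PA"], summary["N_a"]
            het = heterozygosities(genotypes, pop)
            row.H_O = float(het["H_O"].mean())
            row.H_E = float(het["H_E"].mean())
            row.A_R = float(rar.loc[pop, "A_R"])  # type: ignore[union-attr]
            row.A_P = float(rar.loc[pop, "A_P"])  # type: ignore[union-attr]
            try:
                row.F_IS = fis(genotypes, pop)
            except ValueError:
                row.F_IS = np.nan
            if row.N == 0:
                row.N = sum(p == pop for p in genotypes.populations)
        rows.append(row.__dict__)
    return pd.DataFrame(rows).set_index("population")
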