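"""Hardy-Weinberg exact tests for multi-allelic loci.

The test conditions on the observed allele counts: under HWE every way of
pairing the 2n gene copies into n genotypes is equally likely, giving the
genotype-table probability

    P(table) = n! * prod_u(m_u!) * 2^het / ( (2n)! * prod_{u<=v} n_uv! )

where m_u are allele counts, n_uv genotype counts and het the number of
heterozygous individuals.  The p-value is the total probability of tables
no more probable than the observed one, computed by complete enumeration
when the table space is small and otherwise by Monte-Carlo permutation of
gene copies (Guo & Thompson style).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datatypes import GenotypeTable


def _log_prob(geno_counts: dict[tuple[int, int], int], allele_counts: dict[int, int]) -> float:
    n = sum(geno_counts.values())
    two_n = 2 * n
    het = sum(c for (u, v), c in geno_counts.items() if u != v)
    lp = (
        math.lgamma(n + 1)
        + sum(math.lgamma(m + 1) for m in allele_counts.values())
        + het * math.log(2.0)
        - math.lgamma(two_n + 1)
        - sum(math.lgamma(c + 1) for c in geno_counts.values())
    )
    return lp


def _observed_counts(table: GenotypeTable, population: str, locus: str):
    sub = table.subset(population)
    j = sub.loci.index(locus)
    typed = sub.typed_mask()[:, j]
    geno = np.sort(sub.alleles[typed, j, :], axis=1)
    geno_counts: dict[tuple[int, int], int] = {}
    for a, b in geno:
        geno_counts[(int(a), int(b))] = geno_counts.get((int(a), int(b)), 0) + 1
    allele_counts: dict[int, int] = {}
    for a in geno.ravel():
        allele_counts[int(a)] = allele_counts.get(int(a), 0) + 1
    return geno_counts, allele_counts


def enumerate_tables(allele_counts: dict[int, int], max_tables: int = 100_000):
    """Yield every genotype-count table consistent with the allele counts.

    Tables are dicts {(u, v): count} with u <= v.  Raises OverflowError when
    more than ``max_tables`` tables would be produced.
    """
    alleles = sorted(allele_counts)
    pairs = [
        (alleles[i], alleles[j])
        for i in range(len(alleles))
        for j in range(i + 1, len(alleles))
    ]
    produced = 0

    def recurse(idx: int, remaining: dict[int, int], current: dict[tuple[int, int], int]):
        nonlocal produced
        if idx == len(pairs):
            if all(r % 2 == 0 for r in remaining.values()):
                table = dict(current)
                for u in alleles:
                    if remaining[u]:
                        table[(u, u)] = remaining[u] // 2
                produced += 1
                if produced > max_tables:
                    raise OverflowError("table space too large")
                yield table
            return
        u, v = pairs[idx]
        cap = min(remaining[u], remaining[v])
        for c in range(cap + 1):
            if c:
                current[(u, v)] = c
                remaining[u] -= c
                remaining[v] -= c
            yield from recurse(idx + 1, remaining, current)
            if c:
                remaining[u] += c
                remaining[v] += c
        current.pop((u, v), None)

    yield from recurse(0, dict(allele_counts), {})


@dataclass
class HWEResult:
    p_value: float
    method: str  # "enumeration" or "monte-carlo"
    n_tables_or_reps: int


def hwe_exact(
    table: GenotypeTable,
    population: str,
    locus: str,
    reps: int = 10_000,
    seed: int | None = None,
    max_tables: int = 100_000,
) -> HWEResult:
    """Exact HWE test; enumeration when feasible, else seeded Monte Carlo."""
    geno_counts, allele_counts = _observed_counts(table, population, locus)
    if len(allele_counts) < 2:
        raise ValueError(f"locus {locus!r} is monomorphic in {population!r}: test skipped")
    lp_obs = _log_prob(geno_counts, allele_counts)
    tol = 1e-9
    try:
        total = 0.0
        count = 0
        for t in enumerate_tables(allele_counts, max_tables=max_tables):
            count += 1
            lp = _log_prob(t, allele_counts)
            if lp <= lp_obs + tol:
                total += math.exp(lp)
        return HWEResult(p_value=min(total, 1.0), method="enumeration", n_tables_or_reps=count)
    except OverflowError:
        pass
    rng = np.random.default_rng(seed)
    copies = np.repeat(
        list(allele_counts.keys()), list(allele_counts.values())
    ).astype(np.int64)
    hits = 0
    for _ in range(reps):
        rng.shuffle(copies)
        geno = np.sort(copies.reshape(-1, 2), axis=1)
        gc: dict[tuple[int, int], int] = {}
        for a, b in geno:
            gc[(int(a), int(b))] = gc.get((int(a), int(b)), 0) + 1
        if _log_prob(gc, allele_counts) <= lp_obs + tol:
            hits += 1
    return HWEResult(
        p_value=(hits + 1) / (reps + 1), method="monte-carlo", n_tables_or_reps=reps
    )


def bonferroni(pvals, alpha: float = 0.05):
    """Bonferroni-adjusted p-values (capped at 1) and rejection decisions."""
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = np.minimum(p * p.size, 1.0)
    return adjusted, adjusted <= alpha
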