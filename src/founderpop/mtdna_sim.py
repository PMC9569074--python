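"""How many founder females are needed to retain the observed mtDNA
haplotype count?

Each replicate draws k maternal haplotypes from the source haplotype
frequency spectrum and records how many distinct haplotypes the k females
carry.  Drawing i.i.d. from the frequency vector is the large-source limit
of sampling k females from a finite simulated source; a finite-source
(hypergeometric-style) mode is provided for sensitivity.  The analytic
expectation E[H] = sum_h (1 - (1 - p_h)^k) serves as the oracle for the
Monte-Carlo path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import SourcePopulationModel


@dataclass
class FounderFemaleResult:
    k: int
    haplotype_counts: np.ndarray  # distinct haplotypes per replicate

    @property
    def median(self) -> float:
        return float(np.median(self.haplotype_counts))

    @property
    def quartiles(self) -> tuple[float, float]:
        q1, q3 = np.percentile(self.haplotype_counts, [25, 75])
        return float(q1), float(q3)

    @property
    def min(self) -> int:
        return int(self.haplotype_counts.min())

    @property
    def max(self) -> int:
        return int(self.haplotype_counts.max())


def draw_females(
    source: SourcePopulationModel,
    k: int,
    reps: int = 100,
    seed: int | None = None,
    finite_source_size: int | None = None,
) -> FounderFemaleResult:
    """Draw k females per replicate; record distinct maternal haplotypes.

    With ``finite_source_size`` set (in haplotype copies, e.g. 2x the number
    of source individuals), females are drawn without replacement from a
    realized source of that size instead of i.i.d. from the frequencies.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    p = source.haplotype_freqs
    counts = np.empty(reps, dtype=int)
    if finite_source_size is None:
        draws = rng.choice(p.size, size=(reps, k), p=p)
        for r in range(reps):
            counts[r] = np.unique(draws[r]).size
    else:
        if finite_source_size < k:
            raise ValueError("finite source smaller than k")
        pool_counts = rng.multinomial(finite_source_size, p)
        pool = np.repeat(np.arange(p.size), pool_counts)
        for r in range(reps):
            counts[r] = np.unique(rng.choice(pool, size=k, replace=False)).size
    return FounderFemaleResult(k=k, haplotype_counts=counts)


def expected_haplotypes(source: SourcePopulationModel, k: int) -> float:
    """E[distinct haplotypes] = sum_h (1 - (1 - p_h)^k) under i.i.d. draws."""
    if k < 1:
        raise ValueError("k must be >= 1")
    p = source.haplotype_freqs
    return float((1.0 - (1.0 - p) ** k).sum())


def infer_female_range(
    results: list[FounderFemaleResult],
    observed_haplotypes: int,
    rule: str = "iqr",
) -> set[int]:
    """Founder-female counts k whose replicate distribution is consistent
    with the observed haplotype number.

    ``rule="iqr"`` accepts k when the interquartile range of the replicate
    distribution contains the observation (the default decision rule);
    ``rule="median"`` requires median equality.
    """
    if not results:
        raise ValueError("empty result grid")
    ks = sorted(r.k for r in results)
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("k grid must be contiguous")
    accepted: set[int] = set()
    for r in results:
        if rule == "iqr":
            q1, q3 = r.quartiles
            if q1 <= observed_haplotypes <= q3:
                accepted.add(r.k)
        elif rule == "median":
            if r.median == observed_haplotypes:
                accepted.add(r.k)
        else:
            raise ValueError(f"unknown rule {rule!r}")
    return accepted
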