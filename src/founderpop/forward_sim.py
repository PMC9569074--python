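"""Individual-based, age-structured forward simulation of a founding
bottleneck followed by drift under logistic growth.

The model: a pre-bottleneck pool of individuals is genotyped allele-wise
from the source frequencies (linkage equilibrium across loci); B founders
are sampled from it honouring the configured female:male ratio exactly.
Each simulated year, (1) survivors age by one and individuals exceeding
the lifespan die, (2) the logistic recurrence sets the target census
N* = round(N + (lambda - 1) N (1 - N/K)), (3) the shortfall is filled by
newborns, each drawing a uniformly random mature mother and mature father
(lottery polygamy) and inheriting one uniformly chosen allele per locus
from each parent, with Bernoulli(1/2) sex, and (4) extinction is declared
when births are required but no mature female or no mature male exists.
Generations overlap completely; there is no mutation, so no allele absent
from the founder sample can ever appear.

A discrete-generation (Wright-Fisher) mode replaces the whole population
with newborns every year; with ``dioecious=False`` parents are drawn
independently from the entire previous generation (selfing allowed), which
reproduces the classical heterozygosity decay H_t = H_0 (1 - 1/(2N))^t.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datatypes import GenotypeTable, SourcePopulationModel


@dataclass
class DemographicConfig:
    """Life-history and demographic parameters of one simulated scenario."""

    founder_size: int
    growth_rate: float = 1.06  # annual lambda
    capacity: int = 5000
    lifespan: int = 4
    maturation_age: int = 2
    pre_bottleneck_size: int = 100
    sex_ratio: tuple[int, int] = (1, 3)  # female:male among founders
    years: int = 100
    iterations: int = 1000
    track_mtdna: bool = False
    dioecious: bool = True
    overlapping: bool = True  # False = discrete (Wright-Fisher) generations
    max_recruits_per_female: float | None = None  # sensitivity hook, None = unlimited
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.founder_size <= self.pre_bottleneck_size):
            raise ValueError("need 1 <= founder_size <= pre_bottleneck_size")
        if self.maturation_age > self.lifespan:
            raise ValueError("maturation_age must not exceed lifespan")
        if self.growth_rate <= 1.0:
            raise ValueError("lambda must exceed 1")
        if self.capacity < self.founder_size:
            raise ValueError("capacity must be at least founder_size")
        f, m = self.sex_ratio
        if f <= 0 or m <= 0:
            raise ValueError("sex ratio parts must be positive")

    def founder_sex_counts(self) -> tuple[int, int]:
        """(females, males) among founders: rounded counts, ratio exact."""
        f, m = self.sex_ratio
        n_f = round(self.founder_size * f / (f + m))
        n_m = self.founder_size - n_f
        if self.founder_size >= 2 and self.dioecious and (n_f == 0 or n_m == 0):
            raise ValueError(
                f"sex ratio {f}:{m} rounds to zero of one sex at B={self.founder_size}"
            )
        return n_f, n_m


@dataclass
class PopulationState:
    """Living individuals: ages, sexes, coded genotypes, maternal haplotypes.

    Genotypes store per-locus allele *codes*; ``allele_sizes[l][code]`` maps
    back to the allele size in repeat/bp units.
    """

    ages: np.ndarray  # (n,) int
    sexes: np.ndarray  # (n,) bool, True = female
    geno: np.ndarray  # (n, L, 2) int16 allele codes
    loci: list[str]
    allele_sizes: list[np.ndarray]
    haplotypes: np.ndarray | None = None  # (n,) int codes

    def __len__(self) -> int:
        return int(self.ages.size)

    def allele_numbers(self) -> np.ndarray:
        """Distinct alleles per locus among living individuals."""
        out = np.empty(len(self.loci), dtype=int)
        for j in range(len(self.loci)):
            out[j] = np.unique(self.geno[:, j, :]).size
        return out

    def expected_heterozygosity(self) -> float:
        """Mean over loci of 1 - sum p^2 (frequency-based)."""
        vals = []
        for j in range(len(self.loci)):
            counts = np.bincount(self.geno[:, j, :].ravel())
            p = counts[counts > 0] / counts.sum()
            vals.append(1.0 - float((p**2).sum()))
        return float(np.mean(vals))

    def to_genotype_table(self, population: str = "sim") -> GenotypeTable:
        n = len(self)
        alleles = np.empty((n, len(self.loci), 2), dtype=np.int64)
        for j in range(len(self.loci)):
            alleles[:, j, :] = self.allele_sizes[j][self.geno[:, j, :]]
        return GenotypeTable(
            [f"{population}_{i}" for i in range(n)],
            [population] * n,
            list(self.loci),
            alleles,
        )


def init_founders(
    source: SourcePopulationModel,
    config: DemographicConfig,
    rng: np.random.Generator,
) -> PopulationState:
    """Sample the pre-bottleneck pool and draw B founders from it."""
    pre = config.pre_bottleneck_size
    loci = source.loci
    allele_sizes = [np.asarray(source.allele_freqs[l].index, dtype=np.int64) for l in loci]
    geno = np.empty((pre, len(loci), 2), dtype=np.int16)
    for j, locus in enumerate(loci):
        p = np.asarray(source.allele_freqs[locus], dtype=float)
        geno[:, j, :] = rng.choice(p.size, size=(pre, 2), p=p)
    hap = None
    if config.track_mtdna:
        hap = rng.choice(
            source.n_haplotypes, size=pre, p=source.haplotype_freqs
        ).astype(np.int16)
    picked = rng.choice(pre, size=config.founder_size, replace=False)
    n_f, n_m = config.founder_sex_counts()
    sexes = np.zeros(config.founder_size, dtype=bool)
    sexes[rng.choice(config.founder_size, size=n_f, replace=False)] = True
    ages = rng.integers(1, max(config.lifespan - 1, 1) + 1, size=config.founder_size)
    return PopulationState(
        ages=ages.astype(np.int16),
        sexes=sexes,
        geno=geno[picked],
        loci=list(loci),
        allele_sizes=allele_sizes,
        haplotypes=None if hap is None else hap[picked],
    )


def _make_offspring(
    state: PopulationState,
    mothers: np.ndarray,
    fathers: np.ndarray,
    rng: np.random.Generator,
) -> PopulationState:
    births = mothers.size
    L = len(state.loci)
    cols = np.arange(L)[None, :]
    child = np.empty((births, L, 2), dtype=np.int16)
    child[:, :, 0] = state.geno[mothers[:, None], cols, rng.integers(0, 2, (births, L))]
    child[:, :, 1] = state.geno[fathers[:, None], cols, rng.integers(0, 2, (births, L))]
    hap = None
    if state.haplotypes is not None:
        hap = state.haplotypes[mothers]
    return PopulationState(
        ages=np.zeros(births, dtype=np.int16),
        sexes=rng.random(births) < 0.5,
        geno=child,
        loci=state.loci,
        allele_sizes=state.allele_sizes,
        haplotypes=hap,
    )


def _concat(a: PopulationState, b: PopulationState) -> PopulationState:
    return PopulationState(
        ages=np.concatenate([a.ages, b.ages]),
        sexes=np.concatenate([a.sexes, b.sexes]),
        geno=np.concatenate([a.geno, b.geno]),
        loci=a.loci,
        allele_sizes=a.allele_sizes,
        haplotypes=None
        if a.haplotypes is None
        else np.concatenate([a.haplotypes, b.haplotypes]),
    )


def logistic_target(n: int, growth_rate: float, capacity: int) -> int:
    """Next-year target census under the discrete logistic recurrence."""
    return int(round(n + (growth_rate - 1.0) * n * (1.0 - n / capacity)))


def _stochastic_target(
    n: int, growth_rate: float, capacity: int, rng: np.random.Generator
) -> int:
    """Logistic target with stochastic rounding of the fractional increment.

    Deterministic rounding traps small populations (an increment below 0.5
    always rounds away); randomising the fractional individual keeps the
    expected trajectory on the logistic recurrence at every size.
    """
    raw = n + (growth_rate - 1.0) * n * (1.0 - n / capacity)
    base = int(np.floor(raw))
    return base + int(rng.random() < (raw - base))


def step_year(
    state: PopulationState, config: DemographicConfig, rng: np.random.Generator
) -> PopulationState | None:
    """Advance one year; returns the new state or None on extinction."""
    n = len(state)
    if n == 0:
        return None
    target = _stochastic_target(n, config.growth_rate, config.capacity, rng)

    if config.overlapping:
        ages = state.ages + 1
        alive = ages <= config.lifespan
        survivors = PopulationState(
            ages=ages[alive],
            sexes=state.sexes[alive],
            geno=state.geno[alive],
            loci=state.loci,
            allele_sizes=state.allele_sizes,
            haplotypes=None if state.haplotypes is None else state.haplotypes[alive],
        )
        births = max(0, target - len(survivors))
        if births == 0:
            return survivors if len(survivors) else None
        mature = survivors.ages >= config.maturation_age
        if config.dioecious:
            mothers_pool = np.where(mature & survivors.sexes)[0]
            fathers_pool = np.where(mature & ~survivors.sexes)[0]
        else:
            mothers_pool = fathers_pool = np.where(mature)[0]
        if mothers_pool.size == 0 or fathers_pool.size == 0:
            return None  # demographic failure: no breeding pair
        if config.max_recruits_per_female is not None:
            cap = int(np.floor(config.max_recruits_per_female * mothers_pool.size))
            births = min(births, max(cap, 0))
            if births == 0:
                return survivors if len(survivors) else None
        mothers = rng.choice(mothers_pool, size=births)
        fathers = rng.choice(fathers_pool, size=births)
        return _concat(survivors, _make_offspring(survivors, mothers, fathers, rng))

    # discrete generations: the whole population is replaced by newborns
    if config.dioecious:
        mothers_pool = np.where(state.sexes)[0]
        fathers_pool = np.where(~state.sexes)[0]
    else:
        mothers_pool = fathers_pool = np.arange(n)
    if mothers_pool.size == 0 or fathers_pool.size == 0:
        return None
    mothers = rng.choice(mothers_pool, size=target)
    fathers = rng.choice(fathers_pool, size=target)
    return _make_offspring(state, mothers, fathers, rng)


@dataclass
class TrajectoryResult:
    """Per-year summaries of one (B, lambda) scenario across iterations.

    Matrices have shape (iterations, years + 1); year 0 is the founder
    state.  ``na`` is NaN and ``census`` 0 from the extinction year on.
    """

    config: DemographicConfig
    na: np.ndarray
    census: np.ndarray
    het: np.ndarray
    extinct: np.ndarray  # (iterations,) bool
    extinct_year: np.ndarray  # (iterations,) int, -1 if never

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.na.shape[1])

    @property
    def extinction_fraction(self) -> float:
        return float(self.extinct.mean())

    def mean_na(self, year: int = -1) -> float:
        """Mean allele number per locus across surviving iterations."""
        col = self.na[:, year]
        return float(np.nanmean(col)) if not np.all(np.isnan(col)) else float("nan")

    def sd_na(self, year: int = -1) -> float:
        col = self.na[:, year]
        ok = ~np.isnan(col)
        return float(col[ok].std(ddof=1)) if ok.sum() > 1 else float("nan")

    def mean_census(self, year: int = -1, include_extinct: bool = False) -> float:
        """Mean census; extinct iterations count as zero when included,
        and are excluded otherwise."""
        col = self.census[:, year].astype(float)
        if include_extinct:
            return float(col.mean())
        alive = col > 0
        return float(col[alive].mean()) if alive.any() else float("nan")

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.years:
            rows.append(
                {
                    "year": int(t),
                    "mean_na": self.mean_na(t),
                    "sd_na": self.sd_na(t),
                    "mean_census": self.mean_census(t),
                    "extinct_fraction": float((self.census[:, t] == 0).mean()),
                }
            )
        return pd.DataFrame(rows)


def run_scenario(
    source: SourcePopulationModel,
    config: DemographicConfig,
    return_final_states: bool = False,
) -> TrajectoryResult | tuple[TrajectoryResult, list[PopulationState]]:
    """Run the configured scenario for ``iterations`` replicates."""
    iters, years = config.iterations, config.years
    na = np.full((iters, years + 1), np.nan)
    census = np.zeros((iters, years + 1), dtype=np.int64)
    het = np.full((iters, years + 1), np.nan)
    extinct = np.zeros(iters, dtype=bool)
    extinct_year = np.full(iters, -1, dtype=int)
    finals: list[PopulationState] = []
    seeds = np.random.SeedSequence(config.seed).spawn(iters)
    for it in range(iters):
        rng = np.random.default_rng(seeds[it])
        state: PopulationState | None = init_founders(source, config, rng)
        na[it, 0] = state.allele_numbers().mean()
        census[it, 0] = len(state)
        het[it, 0] = state.expected_heterozygosity()
        for t in range(1, years + 1):
            state = step_year(state, config, rng)
            if state is None:
                extinct[it] = True
                extinct_year[it] = t
                break
            na[it, t] = state.allele_numbers().mean()
            census[it, t] = len(state)
            het[it, t] = state.expected_heterozygosity()
        if return_final_states and state is not None:
            finals.append(state)
    result = TrajectoryResult(
        config=config,
        na=na,
        census=census,
        het=het,
        extinct=extinct,
        extinct_year=extinct_year,
    )
    return (result, finals) if return_final_states else result


def sex_ratio_sweep(
    source: SourcePopulationModel,
    config: DemographicConfig,
    ratios: list[tuple[int, int]],
) -> dict[tuple[int, int], TrajectoryResult]:
    """run_scenario per founder sex ratio; same seed stream per ratio."""
    out: dict[tuple[int, int], TrajectoryResult] = {}
    for ratio in ratios:
        out[ratio] = run_scenario(source, replace(config, sex_ratio=ratio))
    return out
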