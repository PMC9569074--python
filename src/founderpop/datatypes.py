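"""Core in-memory containers shared by every analysis stage.

All containers validate their invariants on construction and are cheap to
copy.  Genotypes are stored as an ``(n_individuals, n_loci, 2)`` integer
array of allele sizes with ``0`` as the missing sentinel (GenAlEx
convention); a genotype with exactly one missing allele is coerced to fully
missing so that frequency estimation never sees half-calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = 0

VALID_BASES = set("ACGTN-")


class FormatError(ValueError):
    """Raised when an input file or table violates the expected layout."""


class AlignmentError(ValueError):
    """Raised when sequences that must share a length do not."""


@dataclass
class HaplotypeDataset:
    """Per-individual mtDNA haplotype assignments with population labels.

    Parameters
    ----------
    individuals : list of str
        Unique individual identifiers.
    populations : list of str
        Population label per individual.
    haplotypes : list of str
        Haplotype identifier per individual.  Two individuals share an
        identifier iff their sequences are identical (when present).
    sequences : list of str, optional
        Aligned nucleotide sequences (uniform length, alphabet ACGTN-).
    """

    individuals: list[str]
    populations: list[str]
    haplotypes: list[str]
    sequences: list[str] | None = None

    def __post_init__(self) -> None:
        n = len(self.individuals)
        if not (len(self.populations) == len(self.haplotypes) == n):
            raise FormatError("field lengths disagree")
        if n == 0:
            raise FormatError("empty haplotype dataset")
        if len(set(self.individuals)) != n:
            raise FormatError("duplicate individual ids")
        if self.sequences is not None:
            if len(self.sequences) != n:
                raise FormatError("sequence count does not match individuals")
            lengths = {len(s) for s in self.sequences}
            if len(lengths) > 1:
                raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
            for s in self.sequences:
                bad = set(s.upper()) - VALID_BASES
                if bad:
                    raise FormatError(f"invalid characters in sequence: {bad}")
            # haplotype id <-> sequence identity must be a bijection
            seq_of: dict[str, str] = {}
            for h, s in zip(self.haplotypes, self.sequences):
                if h in seq_of:
                    if seq_of[h] != s.upper():
                        raise FormatError(f"haplotype {h} maps to two sequences")
                else:
                    if s.upper() in seq_of.values():
                        raise FormatError("identical sequences under two haplotype ids")
                    seq_of[h] = s.upper()
            self.sequences = [s.upper() for s in self.sequences]

    def __len__(self) -> int:
        return len(self.individuals)

    @property
    def n_haplotypes(self) -> int:
        return len(set(self.haplotypes))

    def haplotype_counts(self, population: str | None = None) -> pd.Series:
        """Haplotype counts, optionally restricted to one population."""
        rows = zip(self.populations, self.haplotypes)
        haps = [h for p, h in rows if population is None or p == population]
        if not haps:
            raise ValueError(f"no individuals in population {population!r}")
        return pd.Series(haps).value_counts().sort_index()

    def subset(self, populations: list[str] | set[str]) -> "HaplotypeDataset":
        keep = [i for i, p in enumerate(self.populations) if p in populations]
        if not keep:
            raise ValueError("subset would be empty")
        return HaplotypeDataset(
            [self.individuals[i] for i in keep],
            [self.populations[i] for i in keep],
            [self.haplotypes[i] for i in keep],
            None if self.sequences is None else [self.sequences[i] for i in keep],
        )

    def haplotype_sequences(self) -> dict[str, str]:
        """Mapping from haplotype id to its (unique) sequence."""
        if self.sequences is None:
            raise ValueError("dataset carries no sequences")
        return {h: s for h, s in zip(self.haplotypes, self.sequences)}


@dataclass
class GenotypeTable:
    """Diploid microsatellite genotypes, missing-data aware.

    ``alleles`` has shape ``(n, L, 2)``; 0 encodes a missing gene copy and a
    genotype is valid only when both copies are non-missing.
    """

    individuals: list[str]
    populations: list[str]
    loci: list[str]
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        n = len(self.individuals)
        if len(self.populations) != n:
            raise FormatError("population labels do not match individuals")
        if len(set(self.individuals)) != n:
            raise FormatError("duplicate individual ids")
        if self.alleles.shape != (n, len(self.loci), 2):
            raise FormatError(
                f"allele array shape {self.alleles.shape} != {(n, len(self.loci), 2)}"
            )
        if len(self.loci) == 0:
            raise FormatError("empty locus set")
        if len(set(self.loci)) != len(self.loci):
            raise FormatError("duplicate locus names")
        if (self.alleles < 0).any():
            raise FormatError("allele sizes must be positive integers (0 = missing)")
        # half-missing genotypes -> fully missing
        half = (self.alleles == MISSING).sum(axis=2) == 1
        self.alleles[half] = MISSING

    def __len__(self) -> int:
        return len(self.individuals)

    @property
    def population_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def typed_mask(self) -> np.ndarray:
        """Boolean (n, L): genotype fully observed."""
        return (self.alleles != MISSING).all(axis=2)

    def subset(self, populations: list[str] | set[str] | str) -> "GenotypeTable":
        if isinstance(populations, str):
            populations = {populations}
        keep = [i for i, p in enumerate(self.populations) if p in populations]
        if not keep:
            raise ValueError(f"no individuals in {sorted(populations)}")
        return GenotypeTable(
            [self.individuals[i] for i in keep],
            [self.populations[i] for i in keep],
            list(self.loci),
            self.alleles[keep].copy(),
        )

    def allele_counts(self, locus: str, population: str | None = None) -> pd.Series:
        """Gene-copy counts per allele size at one locus."""
        j = self.loci.index(locus)
        rows = np.ones(len(self), bool)
        if population is not None:
            rows = np.array([p == population for p in self.populations])
        copies = self.alleles[rows, j, :].ravel()
        copies = copies[copies != MISSING]
        return pd.Series(copies).value_counts().sort_index()

    def allele_frequencies(self, locus: str, population: str | None = None) -> pd.Series:
        counts = self.allele_counts(locus, population)
        return counts / counts.sum()


def drop_loci(table: GenotypeTable, locus_names: list[str]) -> GenotypeTable:
    """Return a table without the named loci; individuals unchanged."""
    unknown = set(locus_names) - set(table.loci)
    if unknown:
        raise ValueError(f"unknown loci: {sorted(unknown)}")
    keep = [j for j, name in enumerate(table.loci) if name not in set(locus_names)]
    if not keep:
        raise ValueError("dropping all loci would leave an empty locus set")
    return GenotypeTable(
        list(table.individuals),
        list(table.populations),
        [table.loci[j] for j in keep],
        table.alleles[:, keep, :].copy(),
    )


@dataclass
class SiteTable:
    """Sampling-site coordinates in decimal degrees (WGS-84)."""

    codes: list[str]
    latitudes: list[float]
    longitudes: list[float]

    def __post_init__(self) -> None:
        if not (len(self.codes) == len(self.latitudes) == len(self.longitudes)):
            raise FormatError("site table field lengths disagree")
        if len(set(self.codes)) != len(self.codes):
            raise FormatError("duplicate site codes")
        for lat, lon in zip(self.latitudes, self.longitudes):
            if abs(lat) > 90 or abs(lon) > 180:
                raise FormatError(f"coordinate out of range: {(lat, lon)}")

    def coords(self, code: str) -> tuple[float, float]:
        i = self.codes.index(code)
        return self.latitudes[i], self.longitudes[i]


@dataclass
class SourcePopulationModel:
    """Frequency description of a source population used to seed simulations.

    ``haplotype_freqs`` is a vector over mtDNA haplotypes; ``allele_freqs``
    maps each locus to a Series of frequencies indexed by allele size.
    """

    haplotype_freqs: np.ndarray
    allele_freqs: dict[str, pd.Series] = field(default_factory=dict)
    haplotype_sequences: list[str] | None = None

    def __post_init__(self) -> None:
        self.haplotype_freqs = np.asarray(self.haplotype_freqs, dtype=float)
        if self.haplotype_freqs.size < 1:
            raise ValueError("at least one haplotype required")
        self._check(self.haplotype_freqs, "haplotype_freqs")
        if len(self.allele_freqs) < 1:
            raise ValueError("at least one locus required")
        for name, freqs in self.allele_freqs.items():
            self._check(np.asarray(freqs, dtype=float), f"locus {name}")
        if self.haplotype_sequences is not None:
            if len(self.haplotype_sequences) != self.haplotype_freqs.size:
                raise ValueError("one sequence per haplotype required")
            if len(set(self.haplotype_sequences)) != len(self.haplotype_sequences):
                raise ValueError("haplotype sequences must be distinct")

    @staticmethod
    def _check(v: np.ndarray, what: str) -> None:
        if (v < 0).any() or (v > 1).any():
            raise ValueError(f"{what}: frequencies must lie in [0, 1]")
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(f"{what}: frequencies sum to {v.sum()!r}, not 1")

    @property
    def loci(self) -> list[str]:
        return list(self.allele_freqs)

    @property
    def n_haplotypes(self) -> int:
        return int(self.haplotype_freqs.size)
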