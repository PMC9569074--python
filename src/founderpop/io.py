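"""File readers/writers: FASTA haplotypes, GenAlEx-style genotype CSV,
site tables, and JSON run manifests.

FASTA headers encode the individual and its population as ``id|population``.
Haplotype ids are assigned deterministically by collapsing identical
sequences and naming them ``Hap01, Hap02, ...`` in order of first occurrence
after sorting individual ids, so repeated runs (and shuffled input files)
produce the same labels.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import (
    MISSING,
    AlignmentError,
    FormatError,
    GenotypeTable,
    HaplotypeDataset,
    SiteTable,
)


def _collapse_haplotypes(ids: list[str], seqs: list[str]) -> list[str]:
    """Assign HapNN labels by first occurrence over sorted individual ids."""
    order = sorted(range(len(ids)), key=lambda i: ids[i])
    label_of: dict[str, str] = {}
    for i in order:
        s = seqs[i]
        if s not in label_of:
            label_of[s] = f"Hap{len(label_of) + 1:02d}"
    return [label_of[s] for s in seqs]


def read_fasta(path: str | Path) -> HaplotypeDataset:
    """Read aligned per-individual sequences; collapse into haplotypes."""
    ids: list[str] = []
    pops: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id
        if "|" not in header:
            raise FormatError(f"header {header!r} lacks 'id|population'")
        ind, pop = header.split("|", 1)
        ids.append(ind)
        pops.append(pop)
        seqs.append(str(rec.seq).upper())
    if not ids:
        raise FormatError(f"no FASTA records in {path}")
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate individual ids in FASTA")
    if len({len(s) for s in seqs}) > 1:
        raise AlignmentError("sequences are not aligned to a common length")
    haps = _collapse_haplotypes(ids, seqs)
    return HaplotypeDataset(ids, pops, haps, seqs)


def write_fasta(dataset: HaplotypeDataset, path: str | Path) -> None:
    if dataset.sequences is None:
        raise ValueError("dataset carries no sequences to write")
    records = [
        SeqRecord(Seq(s), id=f"{i}|{p}", description="")
        for i, p, s in zip(dataset.individuals, dataset.populations, dataset.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_genotypes(path: str | Path, drop: list[str] | None = None) -> GenotypeTable:
    """Read a GenAlEx-style genotype CSV.

    Layout: columns ``individual, population`` then two columns per locus
    (``<locus>`` and ``<locus>.1`` or ``<locus>_2`` -- only the first of each
    pair names the locus).  Missing gene copies are 0.
    """
    df = pd.read_csv(path, dtype={0: str, 1: str})
    if df.shape[1] < 4:
        raise FormatError("expected individual, population, and >=1 locus (2 columns)")
    allele_cols = df.columns[2:]
    if len(allele_cols) % 2 != 0:
        raise FormatError(f"odd number of allele columns ({len(allele_cols)})")
    loci = [str(allele_cols[j]).split(".")[0] for j in range(0, len(allele_cols), 2)]
    raw = df[allele_cols].to_numpy()
    try:
        vals = raw.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric allele entry: {exc}") from exc
    vals = np.nan_to_num(vals, nan=MISSING)
    if not np.allclose(vals, np.round(vals)):
        raise FormatError("allele sizes must be integers")
    alleles = vals.astype(np.int64).reshape(len(df), len(loci), 2)
    table = GenotypeTable(
        df.iloc[:, 0].astype(str).tolist(),
        df.iloc[:, 1].astype(str).tolist(),
        loci,
        alleles,
    )
    if drop:
        from .datatypes import drop_loci

        table = drop_loci(table, drop)
    return table


def write_genotypes(table: GenotypeTable, path: str | Path) -> None:
    cols: dict[str, object] = {
        "individual": table.individuals,
        "population": table.populations,
    }
    for j, locus in enumerate(table.loci):
        cols[locus] = table.alleles[:, j, 0]
        cols[f"{locus}.1"] = table.alleles[:, j, 1]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_sites(path: str | Path) -> SiteTable:
    df = pd.read_csv(path)
    required = {"site", "latitude", "longitude"}
    if not required.issubset(df.columns):
        raise FormatError(f"site table needs columns {sorted(required)}")
    return SiteTable(
        df["site"].astype(str).tolist(),
        df["latitude"].astype(float).tolist(),
        df["longitude"].astype(float).tolist(),
    )


def write_sites(sites: SiteTable, path: str | Path) -> None:
    pd.DataFrame(
        {"site": sites.codes, "latitude": sites.latitudes, "longitude": sites.longitudes}
    ).to_csv(path, index=False)


def write_manifest(path: str | Path, command: str, params: dict, seed: int | None) -> None:
    """Log a run's parameters and seed to a JSON manifest."""
    payload = {
        "command": command,
        "parameters": params,
        "seed": seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
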