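"""Between-population differentiation: AMOVA-based Phi_ST and R_ST,
Nei genetic distance, and the isolation-by-distance test.

Phi_ST treats the pairwise nucleotide difference between haplotypes as the
squared inter-individual distance; R_ST applies the same variance
decomposition to squared allele-size differences at the gene-copy level,
with variance components summed across loci before forming the ratio.
P-values come from permuting individuals between the two populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import GenotypeTable, HaplotypeDataset, SiteTable
from .diversity import pairwise_differences
from .geodesy import vincenty_distance


@dataclass
class DifferentiationResult:
    statistic: str  # "Phi_ST" or "R_ST"
    value: float
    p_value: float | None
    permutations: int


# ---------------------------------------------------------------------------
# shared two-level AMOVA machinery
# ---------------------------------------------------------------------------

def _amova_components(sq: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(sigma2_among, sigma2_within) from a squared-distance matrix.

    ``sq`` is the full symmetric matrix of squared distances between
    sampling units; ``labels`` assigns each unit to a population.
    """
    n = sq.shape[0]
    groups = np.unique(labels)
    ss_total = sq.sum() / (2.0 * n)
    ss_within = 0.0
    sizes = []
    for g in groups:
        idx = labels == g
        ng = int(idx.sum())
        sizes.append(ng)
        ss_within += sq[np.ix_(idx, idx)].sum() / (2.0 * ng)
    sizes_arr = np.asarray(sizes, float)
    df_among = len(groups) - 1
    df_within = n - len(groups)
    if df_within <= 0 or df_among <= 0:
        raise ValueError("need >=2 units per population and >=2 populations")
    sigma_within = ss_within / df_within
    ms_among = (ss_total - ss_within) / df_among
    n_prime = (n - (sizes_arr**2).sum() / n) / df_among
    sigma_among = (ms_among - sigma_within) / n_prime
    return float(sigma_among), float(sigma_within)


def _perm_pvalue(obs: float, null: np.ndarray) -> float:
    return (int((null >= obs - 1e-12).sum()) + 1) / (null.size + 1)


# ---------------------------------------------------------------------------
# Phi_ST (sequences)
# ---------------------------------------------------------------------------

def pairwise_phist(
    dataset: HaplotypeDataset,
    pop_a: str,
    pop_b: str,
    permutations: int = 10_000,
    seed: int | None = None,
) -> DifferentiationResult:
    """AMOVA Phi_ST between two populations of aligned sequences."""
    sub = dataset.subset({pop_a, pop_b})
    if sub.sequences is None:
        raise ValueError("Phi_ST requires aligned sequences")
    labels = np.array([0 if p == pop_a else 1 for p in sub.populations])
    if (labels == 0).sum() < 2 or (labels == 1).sum() < 2:
        raise ValueError("both populations need >=2 sequences")
    haps = sorted(set(sub.haplotypes))
    seq_of = sub.haplotype_sequences()
    hd = np.zeros((len(haps), len(haps)))
    for i in range(len(haps)):
        for j in range(i + 1, len(haps)):
            d, _ = pairwise_differences(seq_of[haps[i]], seq_of[haps[j]])
            hd[i, j] = hd[j, i] = d
    hap_idx = np.array([haps.index(h) for h in sub.haplotypes])
    sq = hd[np.ix_(hap_idx, hap_idx)]
    if sq.sum() == 0.0:
        raise ValueError("zero total variance: a single shared haplotype")
    sa, sw = _amova_components(sq, labels)
    phi = sa / (sa + sw)
    p = None
    if permutations > 0:
        rng = np.random.default_rng(seed)
        null = np.empty(permutations)
        lab = labels.copy()
        for k in range(permutations):
            rng.shuffle(lab)
            nsa, nsw = _amova_components(sq, lab)
            null[k] = nsa / (nsa + nsw)
        p = _perm_pvalue(phi, null)
    return DifferentiationResult("Phi_ST", float(phi), p, permutations)


# ---------------------------------------------------------------------------
# R_ST (microsatellites)
# ---------------------------------------------------------------------------

def _rst_components(
    sizes_by_locus: list[np.ndarray],
    ind_by_locus: list[np.ndarray],
    labels: np.ndarray,
) -> tuple[float, float]:
    """Sum gene-copy-level variance components over loci."""
    tot_among = 0.0
    tot_within = 0.0
    for x, ind in zip(sizes_by_locus, ind_by_locus):
        lab = labels[ind]
        groups = np.unique(lab)
        if len(groups) < 2:
            continue
        n = x.size
        ss_total = ((x - x.mean()) ** 2).sum()
        ss_within = 0.0
        sizes = []
        for g in groups:
            xg = x[lab == g]
            sizes.append(xg.size)
            ss_within += ((xg - xg.mean()) ** 2).sum()
        sizes_arr = np.asarray(sizes, float)
        df_among = len(groups) - 1
        df_within = n - len(groups)
        if df_within <= 0:
            continue
        sw = ss_within / df_within
        ms_among = (ss_total - ss_within) / df_among
        n_prime = (n - (sizes_arr**2).sum() / n) / df_among
        tot_among += (ms_among - sw) / n_prime
        tot_within += sw
    return tot_among, tot_within


def pairwise_rst(
    table: GenotypeTable,
    pop_a: str,
    pop_b: str,
    permutations: int = 10_000,
    seed: int | None = None,
) -> DifferentiationResult:
    """Slatkin's R_ST between two populations via distance-based AMOVA
    on squared allele-size differences, components summed across loci."""
    sub = table.subset({pop_a, pop_b})
    labels = np.array([0 if p == pop_a else 1 for p in sub.populations])
    typed = sub.typed_mask()
    sizes_by_locus: list[np.ndarray] = []
    ind_by_locus: list[np.ndarray] = []
    any_polymorphic = False
    for j in range(len(sub.loci)):
        rows = np.where(typed[:, j])[0]
        if rows.size < 2:
            continue
        x = sub.alleles[rows, j, :].astype(float).ravel()
        ind = np.repeat(rows, 2)
        if np.unique(x).size > 1 and np.unique(labels[ind]).size == 2:
            any_polymorphic = True
        sizes_by_locus.append(x)
        ind_by_locus.append(ind)
    if not any_polymorphic:
        raise ValueError("no shared polymorphic locus: R_ST undefined")
    sa, sw = _rst_components(sizes_by_locus, ind_by_locus, labels)
    if sa + sw == 0.0:
        raise ValueError("zero total variance: R_ST undefined")
    rst = sa / (sa + sw)
    p = None
    if permutations > 0:
        rng = np.random.default_rng(seed)
        null = np.empty(permutations)
        lab = labels.copy()
        for k in range(permutations):
            rng.shuffle(lab)
            nsa, nsw = _rst_components(sizes_by_locus, ind_by_locus, lab)
            null[k] = nsa / (nsa + nsw) if (nsa + nsw) != 0 else 0.0
        p = _perm_pvalue(rst, null)
    return DifferentiationResult("R_ST", float(rst), p, permutations)


# ---------------------------------------------------------------------------
# Nei genetic distance and isolation by distance
# ---------------------------------------------------------------------------

def nei_distance_individual(
    table: GenotypeTable, ind_a: str, ind_b: str
) -> float:
    """Nei's (1972) standard genetic distance between two individuals.

    Each individual is treated as a two-copy population with per-locus
    allele frequencies 0/0.5/1; J terms are averaged across loci typed in
    both individuals before forming D = -ln(Jxy / sqrt(Jx * Jy)).
    """
    ia, ib = table.individuals.index(ind_a), table.individuals.index(ind_b)
    typed = table.typed_mask()
    jx = jy = jxy = 0.0
    n_loci = 0
    for j in range(len(table.loci)):
        if not (typed[ia, j] and typed[ib, j]):
            continue
        ga, gb = table.alleles[ia, j, :], table.alleles[ib, j, :]
        alleles = np.unique(np.concatenate([ga, gb]))
        xa = np.array([(ga == a).sum() / 2.0 for a in alleles])
        xb = np.array([(gb == a).sum() / 2.0 for a in alleles])
        jx += float((xa**2).sum())
        jy += float((xb**2).sum())
        jxy += float((xa * xb).sum())
        n_loci += 1
    if n_loci == 0:
        raise ValueError("no locus typed in both individuals")
    if jxy == 0.0:
        return np.inf
    return float(-np.log(jxy / np.sqrt(jx * jy)))


def ibd_spearman(
    table: GenotypeTable,
    sites: SiteTable,
    reference_site: str,
    permutations: int = 10_000,
    seed: int | None = None,
    method: str = "permutation",
) -> tuple[float, float]:
    """Spearman correlation between individual-pair genetic distance and
    geodesic distance from a reference site.

    Pairs are (non-reference individual, reference individual); the
    permutation null shuffles non-reference individuals' site assignments.
    """
    if reference_site not in table.populations:
        raise ValueError(f"reference site {reference_site!r} has no individuals")
    geo_from_ref = {
        code: vincenty_distance(*sites.coords(reference_site), *sites.coords(code))
        for code in sites.codes
    }
    nonref_dists = [geo_from_ref[p] for p in table.populations if p != reference_site]
    if len(set(np.round(nonref_dists, 3))) < 2:
        raise ValueError("all non-reference sites are co-located: IBD degenerate")
    ref_idx = [i for i, p in enumerate(table.populations) if p == reference_site]
    non_idx = [i for i, p in enumerate(table.populations) if p != reference_site]
    if len({table.populations[i] for i in non_idx}) < 2:
        raise ValueError("need >=2 non-reference sites")
    gen = np.empty((len(non_idx), len(ref_idx)))
    for a, i in enumerate(non_idx):
        for b, r in enumerate(ref_idx):
            gen[a, b] = nei_distance_individual(
                table, table.individuals[i], table.individuals[r]
            )
    site_of_non = np.array([table.populations[i] for i in non_idx])
    geo = np.array([geo_from_ref[s] for s in site_of_non])
    gen_flat = gen.ravel()
    geo_flat = np.repeat(geo, len(ref_idx))
    rho, p_asym = stats.spearmanr(gen_flat, geo_flat)
    if method == "asymptotic" or permutations <= 0:
        return float(rho), float(p_asym)
    rng = np.random.default_rng(seed)
    null = np.empty(permutations)
    labels = site_of_non.copy()
    for k in range(permutations):
        rng.shuffle(labels)
        g = np.repeat(np.array([geo_from_ref[s] for s in labels]), len(ref_idx))
        null[k], _ = stats.spearmanr(gen_flat, g)
    p = (int((null >= rho - 1e-12).sum()) + 1) / (permutations + 1)
    return float(rho), float(p)
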