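"""AMOVA Phi_ST / R_ST, permutation behaviour, geodesy, and IBD."""

import numpy as np
import pytest

from founderpop import (
    GenotypeTable,
    HaplotypeDataset,
    ibd_spearman,
    make_radial_layout,
    nei_distance_individual,
    pairwise_phist,
    pairwise_rst,
    sample_dataset,
    serial_founder_dataset,
)
from founderpop.geodesy import vincenty_distance

from .test_diversity import table_from_genotypes


def fixed_difference_dataset():
    ids = [f"i{k}" for k in range(8)]
    pops = ["A"] * 4 + ["B"] * 4
    seqs = ["ACGTACGTAC"] * 4 + ["ACGTACGTTT"] * 4
    haps = ["H1"] * 4 + ["H2"] * 4
    return HaplotypeDataset(ids, pops, haps, seqs)


class TestPhiST:
    def test_fixed_difference_gives_one(self):
        r = pairwise_phist(fixed_difference_dataset(), "A", "B", permutations=99, seed=1)
        assert r.value == pytest.approx(1.0)
        assert r.p_value < 0.05

    def test_identical_frequencies_give_null(self, two_pop_sample):
        _, dataset = two_pop_sample
        r = pairwise_phist(dataset, "A", "B", permutations=99, seed=3)
        assert abs(r.value) <= 0.02
        assert r.p_value > 0.05

    def test_single_shared_haplotype_signalled(self):
        ds = HaplotypeDataset(
            [f"i{k}" for k in range(4)],
            ["A", "A", "B", "B"],
            ["H1"] * 4,
            ["ACGT"] * 4,
        )
        with pytest.raises(ValueError):
            pairwise_phist(ds, "A", "B", permutations=0)


class TestRST:
    def test_fixed_size_difference_gives_one(self):
        genos = [[[100, 100], [200, 200]]] * 5 + [[[120, 120], [220, 220]]] * 5
        t = table_from_genotypes(genos, pops=["A"] * 5 + ["B"] * 5)
        r = pairwise_rst(t, "A", "B", permutations=99, seed=1)
        assert r.value == pytest.approx(1.0)
        assert r.p_value < 0.05

    def test_identical_distributions_give_null(self, two_pop_sample):
        table, _ = two_pop_sample
        r = pairwise_rst(table, "A", "B", permutations=99, seed=3)
        assert abs(r.value) <= 0.02
        assert r.p_value > 0.05

    def test_no_polymorphic_locus_signalled(self):
        t = table_from_genotypes(
            [[[100, 100]], [[100, 100]]], pops=["A", "B"]
        )
        with pytest.raises(ValueError):
            pairwise_rst(t, "A", "B", permutations=0)

    def test_bottleneck_increases_differentiation(self, yantai_model):
        """Stronger founder events between two descendant populations
        produce larger R_ST (drift increases differentiation)."""
        from founderpop.datatypes import SiteTable

        sites = SiteTable(["S0", "S1"], [39.99, 40.05], [116.2, 116.2])
        values = {}
        for bottleneck in (25, 3):
            vals = []
            for rep in range(8):
                tab = serial_founder_dataset(
                    yantai_model, sites, n_per_site=30,
                    chain_bottleneck=bottleneck, seed=600 + rep,
                )
                vals.append(pairwise_rst(tab, "S0", "S1", permutations=0).value)
            values[bottleneck] = np.median(vals)
        assert values[3] > values[25]
        assert values[3] > 0


def test_null_permutation_pvalues_super_uniform(yantai_model):
    """Under the null (one panmictic source split arbitrarily in two), the
    permutation test should reject at about the nominal rate or less."""
    rejections = 0
    n_reps = 120
    for rep in range(n_reps):
        table, _ = sample_dataset(
            yantai_model, 40, seed=3000 + rep, population="X"
        )
        pops = ["A"] * 20 + ["B"] * 20
        t = GenotypeTable(table.individuals, pops, table.loci, table.alleles)
        r = pairwise_rst(t, "A", "B", permutations=99, seed=rep)
        rejections += r.p_value <= 0.05
    # Binomial(120, 0.05): 99% upper bound ~ 13
    assert rejections <= 13


class TestGeodesy:
    def test_vincenty_against_published_oracle(self):
        # value cross-checked against R geosphere::distVincentyEllipsoid
        d = vincenty_distance(39.99, 116.20, 40.08, 116.30)
        assert d == pytest.approx(13141.92, abs=0.5)

    def test_zero_distance(self):
        assert vincenty_distance(40.0, 116.0, 40.0, 116.0) == 0.0

    def test_radial_layout_distances(self):
        sites = make_radial_layout(3, max_km=10.0)
        d = vincenty_distance(*sites.coords("S00"), *sites.coords("S02"))
        assert d == pytest.approx(10_000.0, abs=100.0)


class TestNeiDistance:
    def test_identical_homozygotes_give_zero(self):
        t = table_from_genotypes([[[100, 100]], [[100, 100]]])
        assert nei_distance_individual(t, "i0", "i1") == pytest.approx(0.0)

    def test_disjoint_alleles_give_infinity(self):
        t = table_from_genotypes([[[100, 100]], [[102, 102]]])
        assert nei_distance_individual(t, "i0", "i1") == np.inf

    def test_monotone_in_allele_sharing(self):
        t = table_from_genotypes(
            [[[100, 100]], [[100, 100]], [[100, 102]], [[102, 102]]]
        )
        d_same = nei_distance_individual(t, "i0", "i1")
        d_half = nei_distance_individual(t, "i0", "i2")
        d_none = nei_distance_individual(t, "i0", "i3")
        assert d_same < d_half < d_none


class TestIBD:
    def test_serial_founder_chain_shows_positive_correlation(self, yantai_model):
        """Radial expansion from the release site embeds a genetic-by-
        geographic distance correlation detectable at study-like sample
        sizes (median over replicates)."""
        sites = make_radial_layout(8, max_km=13.0)
        rhos, ps = [], []
        for rep in range(12):
            tab = serial_founder_dataset(
                yantai_model, sites, n_per_site=20, seed=4200 + rep
            )
            rho, p = ibd_spearman(tab, sites, "S00", permutations=299, seed=rep)
            rhos.append(rho)
            ps.append(p)
        assert np.median(rhos) > 0
        assert np.median(ps) < 0.05

    def test_shuffled_sites_destroy_signal(self, yantai_model):
        sites = make_radial_layout(8, max_km=13.0)
        rng = np.random.default_rng(0)
        rhos = []
        for rep in range(6):
            tab = serial_founder_dataset(
                yantai_model, sites, n_per_site=15, seed=900 + rep
            )
            pops = list(tab.populations)
            nonref = [i for i, p in enumerate(pops) if p != "S00"]
            labels = np.array([pops[i] for i in nonref])
            rng.shuffle(labels)
            for i, lab in zip(nonref, labels):
                pops[i] = lab
            t2 = GenotypeTable(list(tab.individuals), pops, tab.loci, tab.alleles.copy())
            rho, _ = ibd_spearman(t2, sites, "S00", permutations=0, method="asymptotic")
            rhos.append(rho)
        assert abs(np.mean(rhos)) < 0.1

    def test_colocated_sites_signalled(self, yantai_model):
        from founderpop.datatypes import SiteTable

        sites = SiteTable(["R", "X", "Y"], [40.0, 40.1, 40.1], [116.0, 116.1, 116.1])
        tab = serial_founder_dataset(yantai_model, sites, n_per_site=5, seed=1)
        with pytest.raises(ValueError):
            ibd_spearman(tab, sites, "R", permutations=0)
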