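"""Diversity statistics against hand-computed and brute-force oracles."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from founderpop import (
    GenotypeTable,
    HaplotypeDataset,
    allele_summary,
    diversity_table,
    fis,
    haplotype_diversity,
    heterozygosities,
    min_gene_copies,
    nucleotide_diversity,
    rarefied_richness,
)


def table_from_genotypes(genos, pops=None, loci=None):
    """Build a GenotypeTable from a list of per-individual locus pair lists."""
    arr = np.asarray(genos)
    n, L = arr.shape[0], arr.shape[1]
    return GenotypeTable(
        [f"i{k}" for k in range(n)],
        pops or ["P"] * n,
        loci or [f"L{j}" for j in range(L)],
        arr,
    )


class TestHaplotypeDiversity:
    def test_single_haplotype_gives_zero(self):
        h, sd = haplotype_diversity([15])
        assert h == 0.0 and sd == 0.0

    def test_two_singletons_give_one(self):
        h, _ = haplotype_diversity([1, 1])
        assert h == 1.0

    def test_beijing_like_counts(self):
        # 150 samples in two haplotypes; 103/47 is the split consistent
        # with the published diversity 0.433 (0.029)
        h, sd = haplotype_diversity([103, 47])
        assert h == pytest.approx(0.433, abs=5e-4)
        assert sd == pytest.approx(0.029, abs=5e-4)

    def test_sample_size_below_two_rejected(self):
        with pytest.raises(ValueError):
            haplotype_diversity([1])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 40), min_size=2, max_size=12))
    def test_invariant_under_relabeling_and_bounds(self, counts):
        h, sd = haplotype_diversity(counts)
        h2, sd2 = haplotype_diversity(sorted(counts, reverse=True))
        assert h == pytest.approx(h2) and sd == pytest.approx(sd2)
        assert 0.0 <= h <= 1.0 and sd >= 0.0


class TestNucleotideDiversity:
    def test_identical_sequences_give_zero(self):
        ds = HaplotypeDataset(
            ["a", "b", "c"], ["P"] * 3, ["H1"] * 3, ["ACGT"] * 3
        )
        pi, sd = nucleotide_diversity(ds)
        assert pi == 0.0

    def test_two_sequences_one_difference(self):
        ds = HaplotypeDataset(
            ["a", "b"], ["P"] * 2, ["H1", "H2"], ["ACGTACGTAC", "ACGTACGTAT"]
        )
        pi, _ = nucleotide_diversity(ds)
        assert pi == pytest.approx(0.1)

    def test_matches_exhaustive_pair_average(self):
        seqs = ["ACGTACGTAC", "ACGTACGTAT", "ACGAACGTAT", "TCGAACGTAT"]
        ds = HaplotypeDataset(
            [f"s{k}" for k in range(4)],
            ["P"] * 4,
            [f"H{k}" for k in range(4)],
            seqs,
        )
        pi, _ = nucleotide_diversity(ds)
        def diffs(a, b):
            return sum(x != y for x, y in zip(a, b)) / len(a)
        brute = np.mean([diffs(a, b) for a, b in combinations(seqs, 2)])
        assert pi == pytest.approx(brute)

    def test_ambiguous_sites_excluded_pairwise(self):
        ds = HaplotypeDataset(
            ["a", "b"], ["P"] * 2, ["H1", "H2"], ["ACGTN", "ACGAA"]
        )
        pi, _ = nucleotide_diversity(ds)  # 1 difference over 4 valid sites
        assert pi == pytest.approx(0.25)

    def test_missing_sequences_rejected(self):
        ds = HaplotypeDataset(["a", "b"], ["P"] * 2, ["H1", "H2"])
        with pytest.raises(ValueError):
            nucleotide_diversity(ds)


class TestAlleleSummary:
    def test_private_alleles_counted_against_others(self):
        t = table_from_genotypes(
            [[[100, 102]], [[104, 104]]], pops=["focal", "other"]
        )
        s = allele_summary(t, "focal", ["other"])
        assert s == {"N_A": 2.0, "N_PA": 2.0, "N_a": 2.0}

    def test_no_private_alleles_when_focal_subset_of_others(self):
        t = table_from_genotypes(
            [[[100, 102]], [[100, 102]], [[104, 104]]],
            pops=["focal", "other", "other"],
        )
        assert allele_summary(t, "focal", ["other"])["N_PA"] == 0.0

    def test_empty_population_rejected(self, yantai_sample):
        table, _ = yantai_sample
        with pytest.raises(ValueError):
            allele_summary(table, "nope", [])


class TestRarefiedRichness:
    def test_matches_exhaustive_subset_enumeration(self):
        # one locus, 6 gene copies with counts {3, 2, 1}, rarefied to g=4
        t = table_from_genotypes([[[100, 100]], [[100, 102]], [[102, 104]]])
        ar = rarefied_richness(t, 4).loc["P", "A_R"]
        copies = [100, 100, 100, 102, 102, 104]
        brute = np.mean([len(set(s)) for s in combinations(copies, 4)])
        assert ar == pytest.approx(brute)

    def test_monomorphic_locus_gives_one(self):
        t = table_from_genotypes([[[100, 100]], [[100, 100]]])
        assert rarefied_richness(t, 2).loc["P", "A_R"] == pytest.approx(1.0)

    def test_full_size_equals_observed_count(self):
        t = table_from_genotypes([[[100, 102]], [[104, 106]]])
        assert rarefied_richness(t, 4).loc["P", "A_R"] == pytest.approx(4.0)

    def test_nondecreasing_in_g(self, yantai_sample):
        table, _ = yantai_sample
        gmax = min_gene_copies(table)
        values = [
            rarefied_richness(table, g).loc["yantai", "A_R"]
            for g in range(2, min(gmax, 30), 4)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(values, values[1:]))

    def test_private_richness_zero_when_pops_identical(self):
        t = table_from_genotypes(
            [[[100, 102]], [[100, 102]]], pops=["A", "B"]
        )
        out = rarefied_richness(t, 2)
        assert out.loc["A", "A_P"] < 0.35  # overlap makes privacy improbable

    def test_invalid_g_rejected(self):
        t = table_from_genotypes([[[100, 102]]])
        with pytest.raises(ValueError):
            rarefied_richness(t, 1)
        with pytest.raises(ValueError):
            rarefied_richness(t, 10)


class TestHeterozygosities:
    def test_monomorphic_gives_zero(self):
        t = table_from_genotypes([[[100, 100]], [[100, 100]]])
        out = heterozygosities(t, "P")
        assert out.loc["L0", "H_O"] == 0.0
        assert out.loc["L0", "H_E"] == 0.0

    def test_single_heterozygote_unbiased(self):
        t = table_from_genotypes([[[100, 102]]])
        out = heterozygosities(t, "P")
        assert out.loc["L0", "H_O"] == 1.0
        assert out.loc["L0", "H_E"] == pytest.approx(1.0)  # (2/1)(1 - 0.5)

    def test_unbiased_correction_factor(self):
        # 2 individuals, alleles 100/100 and 102/102: p = 0.5, n = 2
        t = table_from_genotypes([[[100, 100]], [[102, 102]]])
        out = heterozygosities(t, "P")
        assert out.loc["L0", "H_E"] == pytest.approx((4 / 3) * 0.5)


class TestFis:
    def test_complete_heterozygote_excess(self):
        t = table_from_genotypes([[[100, 102]]] * 6)
        assert fis(t, "P") == pytest.approx(-1.0)

    def test_hwe_proportions_give_near_zero(self):
        genos = [[[100, 100]]] * 25 + [[[100, 102]]] * 50 + [[[102, 102]]] * 25
        t = table_from_genotypes(genos)
        assert abs(fis(t, "P")) < 0.02

    def test_matches_hand_computed_variance_components(self):
        # n=4: genotypes aa, aa, ab, bb -> p_a = 5/8, H_a = H_b = 1/4
        t = table_from_genotypes(
            [[[100, 100]], [[100, 100]], [[100, 102]], [[102, 102]]]
        )
        n, p, h = 4, 5 / 8, 1 / 4
        def b_u(pu):
            return (n / (n - 1)) * (pu * (1 - pu) - (2 * n - 1) / (4 * n) * h)
        sum_b = b_u(p) + b_u(1 - p)
        sum_c = h / 2 + h / 2
        assert fis(t, "P") == pytest.approx(1 - sum_c / (sum_b + sum_c))

    def test_monomorphic_table_signalled(self):
        t = table_from_genotypes([[[100, 100]], [[100, 100]]])
        with pytest.raises(ValueError):
            fis(t, "P")


def test_diversity_table_assembles_all_statistics(yantai_sample):
    table, dataset = yantai_sample
    out = diversity_table(dataset, table)
    row = out.loc["yantai"]
    assert row["N"] == 89
    assert 0.9 < row["h"] < 1.0
    assert row["pi"] > 0
    assert 1 <= row["A_R"] <= row["N_a"] <= row["N_A"]
    assert 0 <= row["H_O"] <= 1 and 0 <= row["H_E"] <= 1
    assert -1 <= row["F_IS"] <= 1
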