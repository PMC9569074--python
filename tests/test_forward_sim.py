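"""Forward simulator: founder initialisation, yearly dynamics, invariants."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from founderpop import (
    DemographicConfig,
    SourcePopulationModel,
    init_founders,
    run_scenario,
    sex_ratio_sweep,
    step_year,
)
from founderpop.forward_sim import logistic_target


def biallelic_source(n_loci=5, p=0.5):
    return SourcePopulationModel(
        haplotype_freqs=np.array([1.0]),
        allele_freqs={
            f"L{j}": pd.Series([p, 1 - p], index=[100, 102]) for j in range(n_loci)
        },
    )


class TestConfig:
    @pytest.mark.parametrize(
        "b, ratio, expected",
        [(40, (1, 3), (10, 30)), (20, (1, 1), (10, 10)), (20, (1, 6), (3, 17)),
         (40, (1, 9), (4, 36)), (60, (1, 9), (6, 54))],
    )
    def test_founder_sex_counts_round_the_ratio(self, b, ratio, expected):
        cfg = DemographicConfig(founder_size=b, sex_ratio=ratio)
        assert cfg.founder_sex_counts() == expected

    def test_degenerate_ratio_rejected(self):
        cfg = DemographicConfig(founder_size=10, sex_ratio=(1, 30))
        with pytest.raises(ValueError):
            cfg.founder_sex_counts()

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            DemographicConfig(founder_size=200, pre_bottleneck_size=100)
        with pytest.raises(ValueError):
            DemographicConfig(founder_size=20, growth_rate=0.99)
        with pytest.raises(ValueError):
            DemographicConfig(founder_size=20, maturation_age=5, lifespan=4)


class TestInitFounders:
    def test_counts_ages_and_sexes(self, yantai_model):
        cfg = DemographicConfig(founder_size=40, sex_ratio=(1, 3), seed=0)
        rng = np.random.default_rng(0)
        state = init_founders(yantai_model, cfg, rng)
        assert len(state) == 40
        assert state.sexes.sum() == 10  # females
        assert state.ages.min() >= 1 and state.ages.max() <= cfg.lifespan - 1

    def test_founder_allele_frequencies_unbiased(self):
        src = biallelic_source(n_loci=1, p=0.3)
        cfg = DemographicConfig(founder_size=50, pre_bottleneck_size=100, seed=0)
        rng = np.random.default_rng(123)
        freqs = []
        for _ in range(2000):
            state = init_founders(src, cfg, rng)
            freqs.append((state.geno[:, 0, :] == 0).mean())
        se = np.std(freqs, ddof=1) / np.sqrt(len(freqs))
        assert abs(np.mean(freqs) - 0.3) <= 3 * se


class TestStepYear:
    def test_logistic_target_arithmetic(self):
        assert logistic_target(40, 1.06, 5000) == 42

    def test_all_one_sex_goes_extinct_when_births_required(self, yantai_model):
        cfg = DemographicConfig(founder_size=10, sex_ratio=(1, 3), seed=1)
        rng = np.random.default_rng(1)
        state = init_founders(yantai_model, cfg, rng)
        state.sexes[:] = False  # force all male
        extinct = False
        for _ in range(cfg.lifespan + 1):
            state = step_year(state, cfg, rng)
            if state is None:
                extinct = True
                break
        assert extinct

    def test_survivors_age_and_die_at_lifespan(self, yantai_model):
        cfg = DemographicConfig(founder_size=30, seed=2)
        rng = np.random.default_rng(2)
        state = init_founders(yantai_model, cfg, rng)
        state = step_year(state, cfg, rng)
        assert state.ages.max() <= cfg.lifespan
        assert state.ages.min() == 0  # newborns arrived


class TestRunScenario:
    def test_year_zero_is_founder_state(self, yantai_model):
        cfg = DemographicConfig(founder_size=30, years=0, iterations=3, seed=3)
        traj = run_scenario(yantai_model, cfg)
        assert traj.na.shape == (3, 1)
        assert np.all(traj.census[:, 0] == 30)

    def test_allele_number_nonincreasing_every_iteration(self, yantai_model):
        cfg = DemographicConfig(
            founder_size=30, growth_rate=1.08, capacity=400,
            years=40, iterations=10, seed=4,
        )
        traj = run_scenario(yantai_model, cfg)
        diffs = np.diff(traj.na, axis=1)
        assert np.all(np.isnan(diffs) | (diffs <= 1e-9))

    def test_no_allele_outside_source_ever_appears(self, yantai_model):
        cfg = DemographicConfig(
            founder_size=30, growth_rate=1.08, capacity=300,
            years=30, iterations=3, seed=5,
        )
        _, finals = run_scenario(yantai_model, cfg, return_final_states=True)
        for state in finals:
            table = state.to_genotype_table()
            for locus in table.loci:
                observed = set(table.allele_counts(locus).index)
                assert observed <= set(yantai_model.allele_freqs[locus].index)

    def test_census_bounded_by_logistic_overshoot(self, scenario_grid):
        for (b, lam), traj in scenario_grid.items():
            bound = round(traj.config.capacity * (1 + (lam - 1) / 4))
            assert traj.census.max() <= bound

    def test_fixed_seed_reproducible(self, yantai_model):
        cfg = DemographicConfig(
            founder_size=25, capacity=200, years=15, iterations=4, seed=99
        )
        a = run_scenario(yantai_model, cfg)
        b = run_scenario(yantai_model, cfg)
        assert np.array_equal(a.census, b.census)
        assert np.allclose(a.na, b.na, equal_nan=True)

    def test_allele_frequency_martingale_with_equal_sexes(self):
        """Without selection or mutation, mean allele frequency is conserved."""
        src = biallelic_source(n_loci=4, p=0.5)
        cfg = DemographicConfig(
            founder_size=80, pre_bottleneck_size=100, capacity=120,
            sex_ratio=(1, 1), years=8, iterations=250, seed=6,
        )
        _, finals = run_scenario(src, cfg, return_final_states=True)
        freqs = [
            (state.geno == 0).mean() for state in finals
        ]
        se = np.std(freqs, ddof=1) / np.sqrt(len(freqs))
        assert abs(np.mean(freqs) - 0.5) <= 3 * se

    def test_wright_fisher_mode_keeps_census_constant(self):
        src = biallelic_source()
        cfg = DemographicConfig(
            founder_size=40, pre_bottleneck_size=40, capacity=40,
            growth_rate=1.05, years=10, iterations=2,
            overlapping=False, dioecious=False, seed=7,
        )
        traj = run_scenario(src, cfg)
        assert np.all(traj.census == 40)


class TestSexRatioSweep:
    def test_reports_each_ratio(self, yantai_model):
        cfg = DemographicConfig(
            founder_size=20, capacity=200, years=10, iterations=5, seed=8
        )
        out = sex_ratio_sweep(yantai_model, cfg, [(1, 1), (1, 3)])
        assert set(out) == {(1, 1), (1, 3)}
        for traj in out.values():
            assert 0.0 <= traj.extinction_fraction <= 1.0

    def test_zero_female_ratio_rejected(self, yantai_model):
        cfg = DemographicConfig(founder_size=10, capacity=100, years=5,
                                iterations=2, seed=9)
        with pytest.raises(ValueError):
            sex_ratio_sweep(yantai_model, cfg, [(1, 30)])
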