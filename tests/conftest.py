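"""Shared fixtures: synthetic source models, samples, and the scenario grid.

The scenario grid (4 founder sizes x 5 growth rates at 200 iterations) is
expensive (~6 min) and session-scoped; every test that needs simulated
trajectories shares it.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from founderpop import (
    DemographicConfig,
    GenotypeTable,
    HaplotypeDataset,
    make_source_model,
    run_scenario,
    sample_dataset,
)
from founderpop.synthetic import yantai_like_spec

FOUNDER_SIZES = (20, 40, 60, 80)
GROWTH_RATES = (1.02, 1.04, 1.06, 1.08, 1.10)
GRID_ITERATIONS = 200


@pytest.fixture(scope="session")
def yantai_model():
    """Synthetic source population matching the study's source summaries."""
    return make_source_model(yantai_like_spec(seed=7))


@pytest.fixture(scope="session")
def yantai_sample(yantai_model):
    """One sampled dataset (89 diploids) from the synthetic source."""
    return sample_dataset(yantai_model, 89, seed=11, population="yantai")


@pytest.fixture(scope="session")
def two_pop_sample(yantai_model):
    """Two independent samples of the same source merged into one table."""
    t_a, d_a = sample_dataset(yantai_model, 60, seed=21, population="A")
    t_b, d_b = sample_dataset(yantai_model, 60, seed=22, population="B")
    table = GenotypeTable(
        t_a.individuals + t_b.individuals,
        t_a.populations + t_b.populations,
        t_a.loci,
        np.concatenate([t_a.alleles, t_b.alleles]),
    )
    dataset = HaplotypeDataset(
        d_a.individuals + d_b.individuals,
        d_a.populations + d_b.populations,
        d_a.haplotypes + d_b.haplotypes,
        d_a.sequences + d_b.sequences,
    )
    return table, dataset


@pytest.fixture(scope="session")
def scenario_grid(yantai_model):
    """Forward-simulation grid over (B, lambda) at 200 iterations each."""
    grid = {}
    for b, lam in itertools.product(FOUNDER_SIZES, GROWTH_RATES):
        config = DemographicConfig(
            founder_size=b,
            growth_rate=lam,
            iterations=GRID_ITERATIONS,
            seed=1000 + b + int(lam * 100),
        )
        grid[(b, lam)] = run_scenario(yantai_model, config)
    return grid
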