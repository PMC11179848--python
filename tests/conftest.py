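"""Shared fixtures: scaled-down cohort configurations and tiny datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from purgekit.purging_model import DemographicTrajectory, SelectionClass
from purgekit.synthetic_data import (
    CohortConfig,
    CohortDataset,
    PopulationConfig,
    default_config,
    generate_cohort,
)


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """Desk-drawer cohort: tiny budgets and short contigs, full design shape."""
    cfg = default_config(scale=0.02)
    cfg.roh_min_length = 20_000
    cfg.roh_mean_extra_length = 40_000.0
    return cfg


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config, seed=42)


def build_dataset(
    genotypes,
    positions=None,
    contig_length=1_000_000,
    effect_class="synonymous",
    species=None,
    ref="A",
    alt="G",
    outgroups=("A", "A"),
    true_q=None,
) -> CohortDataset:
    """Hand-build a single-contig dataset from a genotype matrix."""
    G = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_ind = G.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 1000
    if species is None:
        species = ["popA"] * n_ind
    if isinstance(effect_class, str):
        effect_class = [effect_class] * n_sites
    sites = pd.DataFrame(
        {
            "contig": pd.Categorical(["chr1"] * n_sites, categories=["chr1"]),
            "pos": np.asarray(positions, dtype=np.int64),
            "ref": [ref] * n_sites if isinstance(ref, str) else list(ref),
            "alt": [alt] * n_sites if isinstance(alt, str) else list(alt),
            "effect_class": effect_class,
            "population": species[0],
            "true_q": np.zeros(n_sites) if true_q is None else np.asarray(true_q),
            "anc_truth": [ref] * n_sites if isinstance(ref, str) else list(ref),
            "outgroup1": [outgroups[0]] * n_sites
            if isinstance(outgroups[0], str)
            else list(outgroups[0]),
            "outgroup2": [outgroups[1]] * n_sites
            if isinstance(outgroups[1], str)
            else list(outgroups[1]),
        }
    )
    individuals = pd.DataFrame(
        {
            "id": [f"ind{k}" for k in range(n_ind)],
            "population": species,
            "species": species,
        }
    )
    contigs = pd.DataFrame({"name": ["chr1"], "length": [contig_length]})
    return CohortDataset(
        contigs=contigs, sites=sites, genotypes=G, individuals=individuals
    )


@pytest.fixture
def two_pop_trajectories():
    return {
        "bottlenecked": DemographicTrajectory([(200, 1), (50, 60)]),
        "constant": DemographicTrajectory([(200, 61)]),
    }


@pytest.fixture
def neutral_class():
    return SelectionClass(0.0, 0.5)
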