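"""Shared fixtures: one small simulated population reused across modules."""

import numpy as np
import pandas as pd
import pytest

from orchardgx.data import add_environment_column
from orchardgx.syndata import (
    SimConfig,
    TraitSpec,
    simulate_founder_genotypes,
    simulate_multienv_trial,
    simulate_population,
)


@pytest.fixture(scope="session")
def small_pop():
    cfg = SimConfig(
        n_accessions=120,
        n_crosses=6,
        progeny_per_cross=8,
        m_markers=600,
        n_chromosomes=3,
        environments=[("CHE", 2018), ("CHE", 2019), ("FRA", 2018), ("FRA", 2019)],
        seed=101,
    )
    return cfg, simulate_population(cfg)


@pytest.fixture(scope="session")
def founders_500():
    cfg = SimConfig(n_accessions=500, m_markers=2000, n_chromosomes=5, seed=202)
    return cfg, simulate_founder_genotypes(cfg)


@pytest.fixture(scope="session")
def polygenic_trial(small_pop):
    """Balanced 4-environment trial of a polygenic trait with ground truth."""
    cfg, pop = small_pop
    spec = TraitSpec(
        "poly",
        polygenic_variance_fraction=0.4,
        env_variance_fraction=0.2,
        gxe_variance_fraction=0.1,
        residual_variance_fraction=0.3,
    )
    rec, truth = simulate_multienv_trial(pop["study"], spec, cfg)
    return add_environment_column(rec), truth, spec
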