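from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ymarker.primer_engine import load_published_primers
from ymarker.synthetic_data import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def published_primers():
    return {row.primer_id: row for row in load_published_primers()}


SMALL_CONFIG = SimulationConfig(
    n_genes=3,
    strata=((0, 0.20),),
    n_x_haplotypes=3,
    intra_x_diversity=0.002,
    gene_length_codons=150,
    intron_length_bp=320,
    n_autosomal_genes=1,
    n_cultivars=2,
    n_samples_per_cultivar=4,
    phenotyping_error_rate=0.0,
    y_expressed_fraction=1.0,
    seed=7,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort (3 genes at dS 0.20, 150 codons) reused across tests."""
    return simulate_cohort(SMALL_CONFIG)


@pytest.fixture()
def rng():
    return np.random.default_rng(20251001)
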