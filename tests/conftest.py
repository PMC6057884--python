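"""Shared fixtures: small simulated panels and cohorts, generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from adprog.genomics import GenotypeMatrix
from adprog.synthcohort import SimulationConfig, simulate_genotypes


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def panmictic_panel():
    """One homogeneous population, independent SNPs (for relatedness tests)."""
    cfg = SimulationConfig(
        n_patients=120, n_snps=5000, n_subpops=1, fst=0.0,
        ld_block_size=1, seed=11, n_clinical=0,
    )
    G, truth = simulate_genotypes(cfg)
    return G, truth


@pytest.fixture(scope="session")
def structured_panel():
    """Two subpopulations at FST 0.1 with LD blocks (for FST / PCA tests)."""
    cfg = SimulationConfig(
        n_patients=500, n_snps=5000, n_subpops=2, fst=0.1, seed=13, n_clinical=0,
    )
    G, truth = simulate_genotypes(cfg)
    return G, truth


def random_censored(rng, n=30):
    """Small random censored survival dataset for oracle comparisons."""
    risks = rng.standard_normal(n)
    times = np.round(rng.exponential(10, n), 1) + 0.5
    events = rng.integers(0, 2, n)
    if events.sum() == 0:
        events[rng.integers(0, n)] = 1
    return risks, times, events


def toy_genotypes(dosages, snp_ids=None, patient_ids=None):
    d = np.asarray(dosages, dtype=float)
    snp_ids = snp_ids or [f"s{j}" for j in range(d.shape[1])]
    patient_ids = patient_ids or [f"p{i}" for i in range(d.shape[0])]
    return GenotypeMatrix(d, snp_ids, patient_ids)
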