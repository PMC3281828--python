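"""Shared fixtures: reduced-scale study runs and full-scale populations.

Expensive simulations are session-scoped and shared by several tests.
The reduced-scale locus (2,000 haplotypes, 10 kb, theta = 10) keeps the
calibration and power-ordering studies fast while preserving the rare-
variant MAF/LD structure; the full-scale fixtures use the default
configuration (10,000 haplotypes, 100 kb).
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from seqassoc import (
    CoalescentConfig,
    RiskClass,
    StudyConfig,
    run_study,
    simulate_population,
)

SMALL_COALESCENT = CoalescentConfig(n_hap=2000, locus_length_bp=10_000)


@pytest.fixture(scope="session")
def fullscale_populations():
    """30 haplotype populations at the default (100 kb, n=10,000) scale."""
    rng = np.random.default_rng(20260921)
    return [simulate_population(CoalescentConfig(), rng) for _ in range(30)]


@pytest.fixture(scope="session")
def null_calibration_study():
    """500 null-model replicates, N = 500, complete data, reduced locus."""
    config = StudyConfig(
        coalescent=SMALL_COALESCENT,
        n_risk=0,
        sample_sizes=(500,),
        call_rates=(1.0,),
        alphas=(0.05,),
        replicates=500,
        tests=("bcca", "camax", "casum", "wss"),
        m=199,
        n_populations=40,
        seed=41,
    )
    return run_study(config)


@pytest.fixture(scope="session")
def power_ordering_study():
    """300 replicates under a rare-risk model (MAF<0.01, OR 2), N = 1,000.

    n_risk = 5 keeps the risk set at ~5% of the variants in the average
    reduced-scale population, mirroring the full-scale design.
    """
    config = StudyConfig(
        coalescent=SMALL_COALESCENT,
        risk_classes=[RiskClass(0.0, 0.01, 2.0)],
        n_risk=5,
        sample_sizes=(1000,),
        call_rates=(1.0,),
        alphas=(0.05,),
        replicates=300,
        tests=("bcca", "camax", "casum", "cmc", "wss"),
        m=199,
        n_populations=30,
        seed=42,
    )
    return run_study(config)


# ---------------------------------------------------------------------------
# Exhaustive-permutation oracles (tiny datasets)
# ---------------------------------------------------------------------------

def exhaustive_label_assignments(n: int, n_cases: int) -> np.ndarray:
    """All C(n, n_cases) distinct 0/1 label vectors."""
    out = []
    for cases in itertools.combinations(range(n), n_cases):
        y = np.zeros(n, dtype=np.int8)
        y[list(cases)] = 1
        out.append(y)
    return np.array(out)
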