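"""Shared fixtures: small simulated breeding programs with known truth."""

import numpy as np
import pandas as pd
import pytest

from rrsgs import SimulationConfig, simulate_breeding_program, simulate_phenotypes


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_founders_per_species=12,
        n_snps=400,
        n_psp_families_per_species=12,
        offspring_per_family=8,
        n_hybrid_families_g1=6,
        n_hybrid_families_g2=6,
        n_parents_g2_per_species=4,
        seed=901,
    )


@pytest.fixture(scope="session")
def small_program(small_config):
    return simulate_breeding_program(small_config)


@pytest.fixture(scope="session")
def small_phenotypes(small_program):
    return simulate_phenotypes(small_program)


@pytest.fixture()
def rng():
    return np.random.default_rng(77)


def hudson_fst(geno_a: np.ndarray, geno_b: np.ndarray) -> float:
    """Pooled Hudson-type Fst estimator from two dosage matrices.

    Independent oracle used by the simulator tests: ratio-of-averages of
    per-SNP numerator (p1-p2)^2 - within-sample correction and denominator
    p1(1-p2) + p2(1-p1).
    """
    p1 = geno_a.mean(axis=0) / 2.0
    p2 = geno_b.mean(axis=0) / 2.0
    n1 = 2 * geno_a.shape[0]
    n2 = 2 * geno_b.shape[0]
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = den > 0
    return float(num[ok].sum() / den[ok].sum())
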