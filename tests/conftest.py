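"""Shared fixtures: small simulated datasets and hand-built genotype helpers."""

from __future__ import annotations

import numpy as np
import pytest

from admixcompare import GenotypeMatrix, QMatrix, SimConfig, simulate_dataset


def make_genotypes(alleles, locality_ids=None, marker_type="snp") -> GenotypeMatrix:
    """Build a GenotypeMatrix from a nested list (N, L, 2) of allele labels."""
    arr = np.asarray(alleles, dtype=np.int64)
    return GenotypeMatrix(
        alleles=arr,
        individual_ids=[f"i{j}" for j in range(arr.shape[0])],
        locus_ids=[f"l{j}" for j in range(arr.shape[1])],
        locality_ids=locality_ids,
        marker_type=marker_type,
    )


def random_qmatrix(rng, n, k) -> QMatrix:
    return QMatrix(rng.dirichlet(np.ones(k), size=n))


@pytest.fixture(scope="session")
def two_pop_dataset():
    """Well-differentiated two-population paired dataset with known truth."""
    cfg = SimConfig(
        K_true=2, n_individuals=60, n_snp_loci=300, n_microsat_loci=12,
        alpha_sim=0.05, F_k=(0.05, 0.05), n_localities=4, seed=1,
    )
    snp, msat, report, truth = simulate_dataset(cfg)
    return snp, msat, report, truth


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small single-population panel for fast I/O and sampler plumbing tests."""
    cfg = SimConfig(
        K_true=1, n_individuals=20, n_snp_loci=40, n_microsat_loci=6,
        n_localities=3, missing_rate=0.1, seed=7,
    )
    snp, msat, report, truth = simulate_dataset(cfg)
    return snp, msat, report, truth
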