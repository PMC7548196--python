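"""Canned study-condition experiments used by the analysis scripts and checks.

Each function simulates data with the package's generator under fixed study
conditions, runs the relevant pipeline stages, and returns summary numbers.
Problem sizes are scaled to desk hardware: clustering chains use hundreds of
sweeps (with the informed start this is well past apparent convergence at
these data sizes) rather than the tens of thousands conventional for real
data.
"""

from __future__ import annotations

import itertools

import numpy as np

from .admixture import McmcOptions, run_admixture_mcmc, replicate_runs, estimate_lambda
from .diversity import smlh, spatial_gradient
from .filtering import full_filter_chain
from .genotypes import QMatrix
from .kselect import evanno_delta_k, gelman_rubin, k_selection_table
from .qcompare import (
    align_qmatrices,
    coefficient_of_admixture,
    exhaustive_alignment,
    pairwise_ssc_matrix,
)
from .simulate import ContaminationPlan, SimConfig, make_dart_report, plant_low_maf, simulate_dataset

__all__ = [
    "planted_filter_experiment",
    "smlh_identity_experiment",
    "alignment_oracle_experiment",
    "ca_endpoint_experiment",
    "q_recovery_experiment",
    "delta_k_experiment",
    "marker_contrast_experiment",
    "evanno_worked_example",
    "gelman_rubin_experiment",
    "lambda_recovery_experiment",
    "cline_recovery_experiment",
]


def planted_filter_experiment(seed: int = 1) -> dict:
    """Plant one violation set per filter rule; check each step removes exactly it.

    Returns per-step booleans plus the overall count of mismatched loci.
    """
    cfg = SimConfig(K_true=2, n_individuals=60, n_snp_loci=300, alpha_sim=0.05,
                    F_k=(0.05, 0.05), n_localities=4, seed=seed)
    snp, *_ = simulate_dataset(cfg)
    common = np.flatnonzero(snp.minor_allele_frequency() >= 0.05)[:120]
    snp = snp.subset(loci=common)
    ids = list(snp.locus_ids)
    plan = ContaminationPlan(
        low_repavg=ids[0:6], unbalanced=ids[10:14], high_coverage=ids[20:23],
        contig_groups=[ids[30:32], ids[40:43]],
    )
    g = plant_low_maf(snp, ids[50:55], minor_copies=1)
    report = make_dart_report(g, plan, seed=seed + 1)
    _, audit = full_filter_chain(g, report)
    expected = {
        "rep_avg": sorted(plan.low_repavg),
        "read_balance": sorted(plan.unbalanced),
        "coverage": sorted(plan.high_coverage),
        "locus_callrate": [],
        "one_snp_per_contig": sorted(ids[31:32] + ids[41:43]),
        "maf": sorted(ids[50:55]),
    }
    result = {f"step_{k}_exact": audit.removed(k) == v for k, v in expected.items()}
    result["n_mismatched_loci"] = sum(
        len(set(audit.removed(k)) ^ set(v)) for k, v in expected.items()
    )
    return result


def smlh_identity_experiment(n_matrices: int = 100, seed: int = 2) -> float:
    """Max |mean sMLH - 1| over random complete-data genotype matrices."""
    rng = np.random.default_rng(seed)
    from .genotypes import GenotypeMatrix

    worst = 0.0
    done = 0
    while done < n_matrices:
        n, l = int(rng.integers(3, 40)), int(rng.integers(3, 60))
        alleles = rng.integers(0, 3, size=(n, l, 2))
        g = GenotypeMatrix(alleles, [f"i{j}" for j in range(n)],
                           [f"l{j}" for j in range(l)], marker_type="microsat")
        try:
            vals = smlh(g)
        except ValueError:
            continue
        worst = max(worst, abs(float(vals.mean()) - 1.0))
        done += 1
    return worst


def alignment_oracle_experiment(n_pairs: int = 200, seed: int = 3) -> dict:
    """Assignment-based alignment vs exhaustive permutation search, K <= 6."""
    rng = np.random.default_rng(seed)
    agree = 0
    worst_gap = 0.0
    for _ in range(n_pairs):
        k = int(rng.integers(2, 7))
        n = int(rng.integers(5, 25))
        q1 = QMatrix(rng.dirichlet(np.ones(k), size=n))
        q2 = QMatrix(rng.dirichlet(np.ones(k), size=n))
        gap = abs(align_qmatrices(q1, q2).ssc - exhaustive_alignment(q1, q2).ssc)
        worst_gap = max(worst_gap, gap)
        agree += gap < 1e-12
    return {"agreement_fraction": agree / n_pairs, "max_ssc_gap": worst_gap}


def ca_endpoint_experiment() -> float:
    """Max deviation of CA from its endpoints (pure -> 0, uniform -> 1), K=2..8."""
    worst = 0.0
    for k in range(2, 9):
        pure = np.zeros((1, k))
        pure[0, 0] = 1.0
        uniform = np.full((1, k), 1.0 / k)
        worst = max(worst, abs(coefficient_of_admixture(QMatrix(pure)).ca[0]))
        worst = max(worst, abs(coefficient_of_admixture(QMatrix(uniform)).ca[0] - 1.0))
    return worst


def q_recovery_experiment(seed: int = 5) -> float:
    """MAE between posterior-mean Q and simulator truth after alignment.

    Conditions: two populations, n=60, 300 SNPs, drift F=0.05, alpha=0.05.
    """
    cfg = SimConfig(K_true=2, n_individuals=60, n_snp_loci=300, alpha_sim=0.05,
                    F_k=(0.05, 0.05), n_localities=4, seed=seed)
    snp, *_, truth = simulate_dataset(cfg)
    opts = McmcOptions(burnin=400, iterations=400, record_interval=5, seed=seed + 1)
    run = run_admixture_mcmc(snp, 2, opts)
    aligned = align_qmatrices(truth.true_Q, run.Q).aligned_Q.values[:, :2]
    return float(np.abs(truth.true_Q.values - aligned).mean())


def delta_k_experiment(n_repetitions: int = 10, seed: int = 6) -> dict:
    """Evanno delta-K peak detection on three-population data.

    Each repetition simulates a fresh K_true=3 dataset (n=90, 600 SNPs — a
    deliberately small panel, still 25-50x below a typical genotyping-by-
    sequencing panel — F=0.05, alpha=0.05), runs 5 replicate chains at each
    K in 1..5, and asks whether delta-K peaks at K=3.
    """
    peaks = []
    for rep in range(n_repetitions):
        rep_seed = seed + 1000 * rep
        cfg = SimConfig(K_true=3, n_individuals=90, n_snp_loci=600,
                        alpha_sim=0.05, F_k=(0.05, 0.05, 0.05),
                        n_localities=4, seed=rep_seed)
        snp, *_ = simulate_dataset(cfg)
        opts = McmcOptions(burnin=250, iterations=300, record_interval=2,
                           seed=rep_seed + 1)
        runs = replicate_runs(snp, range(1, 6), n_replicates=5, opts=opts)
        table = k_selection_table(runs).set_index("K")
        peaks.append(int(table["delta_k"].dropna().idxmax()))
    return {
        "peaks": peaks,
        "peak_at_true_k_rate": sum(p == 3 for p in peaks) / len(peaks),
    }


def marker_contrast_experiment(n_repetitions: int = 10, seed: int = 7,
                               n_replicates: int = 3) -> dict:
    """SNP panel vs microsatellite panel on the same individuals and truth.

    2,000 SNPs against 15 eight-allele microsatellite loci (K_true=3,
    alpha=0.1, F=0.1, n=40). Per repetition: minimum intra-marker aligned SSC
    across replicate pairs and mean CA of the replicate Q-matrices, per
    marker; success means SNPs are both more repeatable (higher minimum SSC)
    and less admixed (lower mean CA).
    """
    rows = []
    for rep in range(n_repetitions):
        rep_seed = seed + 1000 * rep
        cfg = SimConfig(K_true=3, n_individuals=40, n_snp_loci=2000,
                        n_microsat_loci=15, alpha_sim=0.1, F_k=(0.1, 0.1, 0.1),
                        microsat_allele_count=8, n_localities=4, seed=rep_seed)
        snp, msat, *_ = simulate_dataset(cfg)
        out = {}
        for marker, geno in (("snp", snp), ("microsat", msat)):
            qs = [
                run_admixture_mcmc(
                    geno, 3,
                    McmcOptions(burnin=120, iterations=120, record_interval=3,
                                seed=rep_seed + 10 + r),
                ).Q
                for r in range(n_replicates)
            ]
            sim = pairwise_ssc_matrix(qs).to_numpy()
            pairs = list(itertools.combinations(range(n_replicates), 2))
            out[marker] = {
                "min_ssc": float(min(sim[i, j] for i, j in pairs)),
                "mean_ca": float(np.mean([coefficient_of_admixture(q).mean for q in qs])),
            }
        rows.append(out)
    successes = [
        r["snp"]["min_ssc"] > r["microsat"]["min_ssc"]
        and r["snp"]["mean_ca"] < r["microsat"]["mean_ca"]
        for r in rows
    ]
    return {
        "repetitions": rows,
        "success_rate": sum(successes) / len(successes),
        "snp_min_intra_ssc": float(np.mean([r["snp"]["min_ssc"] for r in rows])),
        "microsat_min_intra_ssc": float(np.mean([r["microsat"]["min_ssc"] for r in rows])),
        "snp_mean_ca": float(np.mean([r["snp"]["mean_ca"] for r in rows])),
        "microsat_mean_ca": float(np.mean([r["microsat"]["mean_ca"] for r in rows])),
    }


def evanno_worked_example() -> dict:
    """Delta-K on the textbook profile L=(-100,-80,-75,-74) with unit sd."""
    mean = {1: -100.0, 2: -80.0, 3: -75.0, 4: -74.0}
    sd = {k: 1.0 for k in mean}
    dk = evanno_delta_k(mean, sd)
    return {"delta_k_at_2": dk[2], "delta_k_at_3": dk[3]}


def gelman_rubin_experiment(seed: int = 8) -> dict:
    """GR on twin stationary chains (should be < 1.05) and separated ones (> 1.5)."""
    rng = np.random.default_rng(seed)
    twin = gelman_rubin(rng.normal(size=(2, 10_000)))
    apart = gelman_rubin(
        np.stack([rng.normal(0.0, 1.0, 1000), rng.normal(100.0, 1.0, 1000)])
    )
    return {"converged": float(twin), "separated": float(apart)}


def lambda_recovery_experiment(seed: int = 9) -> float:
    """Estimate lambda at K=1 on a uniform-prior panel (lambda_sim = 1)."""
    cfg = SimConfig(K_true=1, n_individuals=200, n_snp_loci=1000,
                    lambda_sim=1.0, n_localities=2, seed=seed)
    snp, *_ = simulate_dataset(cfg)
    opts = McmcOptions(burnin=100, iterations=200, record_interval=2, seed=seed + 1)
    return estimate_lambda(snp, opts, n_replicates=3)


def cline_recovery_experiment(seed: int = 10) -> float:
    """Latitude coefficient of sMLH on a simulated -0.08/degree founder cline."""
    cfg = SimConfig(K_true=1, n_individuals=90, n_snp_loci=500, n_localities=9,
                    gradient_slope=-0.08, seed=seed)
    snp, *_, truth = simulate_dataset(cfg)
    coords = truth.coordinates.set_index("locality")
    fit = spatial_gradient(
        smlh(snp),
        coords.loc[list(snp.locality_ids), "latitude"].to_numpy(float),
        coords.loc[list(snp.locality_ids), "longitude"].to_numpy(float),
    )
    return float(fit.beta_latitude)
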