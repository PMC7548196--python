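"""Sampler correctness: likelihood identities, recovery, determinism, calibration."""

import numpy as np
import pytest
from scipy.special import gammaln

from admixcompare import (
    McmcOptions,
    QMatrix,
    align_qmatrices,
    estimate_lambda,
    log_likelihood,
    replicate_runs,
    run_admixture_mcmc,
)
from admixcompare.genotypes import MISSING
from admixcompare.kselect import pr_x_given_k
from admixcompare.simulate import SimConfig, simulate_dataset
from conftest import make_genotypes

FAST = dict(burnin=300, iterations=300, record_interval=5)


class TestLogLikelihood:
    def test_single_heterozygote_hand_value(self):
        g = make_genotypes([[[0, 1]]])
        q = QMatrix(np.array([[1.0]]))
        p = np.array([[[0.5, 0.5]]])  # (K=1, L=1, J=2)
        assert log_likelihood(g, q, p) == pytest.approx(2 * np.log(0.5), abs=1e-4)

    def test_all_missing_gives_zero(self):
        g = make_genotypes(np.full((2, 3, 2), MISSING))
        assert log_likelihood(g, np.ones((2, 1)), np.full((1, 3, 1), 1.0)) == 0.0

    def test_perfectly_assigned_fixed_clusters(self):
        # each cluster fixed for its own allele; matching homozygotes -> ln 1 = 0
        g = make_genotypes([[[0, 0]], [[1, 1]]])
        q = QMatrix(np.array([[1.0, 0.0], [0.0, 1.0]]))
        p = np.array([[[1.0, 0.0]], [[0.0, 1.0]]])
        assert log_likelihood(g, q, p) == pytest.approx(0.0)

    def test_unsupported_allele_rejected(self):
        g = make_genotypes([[[0, 1]]])
        p = np.array([[[1.0, 0.0]]])  # allele 1 has probability 0
        with pytest.raises(ValueError, match="support"):
            log_likelihood(g, np.ones((1, 1)), p)


class TestRunAdmixture:
    def test_k1_gives_unit_column(self, tiny_dataset):
        snp, *_ = tiny_dataset
        run = run_admixture_mcmc(snp, 1, McmcOptions(burnin=20, iterations=20,
                                                     record_interval=2, seed=0))
        assert np.allclose(run.Q.values, 1.0)

    def test_same_seed_identical_output(self, tiny_dataset):
        snp, *_ = tiny_dataset
        opts = McmcOptions(burnin=30, iterations=30, record_interval=3, seed=42)
        r1 = run_admixture_mcmc(snp, 2, opts)
        r2 = run_admixture_mcmc(snp, 2, opts)
        assert np.array_equal(r1.Q.values, r2.Q.values)
        assert np.array_equal(r1.loglik_trace, r2.loglik_trace)

    def test_recovers_true_ancestries(self, two_pop_dataset):
        """Posterior-mean Q matches simulator truth (MAE < 0.05 aligned)."""
        snp, _, _, truth = two_pop_dataset
        run = run_admixture_mcmc(snp, 2, McmcOptions(seed=3, **FAST))
        res = align_qmatrices(truth.true_Q, run.Q)
        mae = np.abs(truth.true_Q.values - res.aligned_Q.values[:, :2]).mean()
        assert mae < 0.05

    def test_seed_changes_give_same_solution_up_to_labels(self, two_pop_dataset):
        snp, *_ = two_pop_dataset
        r1 = run_admixture_mcmc(snp, 2, McmcOptions(seed=1, **FAST))
        r2 = run_admixture_mcmc(snp, 2, McmcOptions(seed=2, **FAST))
        assert align_qmatrices(r1.Q, r2.Q).ssc > 0.9

    def test_recorded_state_invariants(self, tiny_dataset):
        snp, *_ = tiny_dataset
        opts = McmcOptions(burnin=40, iterations=60, record_interval=3, seed=5,
                           keep_q_draws=True)
        run = run_admixture_mcmc(snp, 3, opts)
        assert np.all(np.isfinite(run.loglik_trace))
        assert np.all(run.alpha_trace > 0)
        assert np.all(run.alpha_trace <= opts.alpha_prior_max)
        assert np.allclose(run.q_draws.sum(axis=2), 1.0, atol=1e-9)
        valid = np.arange(run.P.shape[2])[None, :] < run.n_alleles[:, None]
        sums = np.where(valid, run.P.mean(axis=0), 0.0).sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-6)

    def test_posterior_interval_coverage(self):
        """Central 90% posterior intervals cover true q for >= 80% of entries."""
        cfg = SimConfig(K_true=2, n_individuals=50, n_snp_loci=150,
                        alpha_sim=0.5, F_k=(0.1, 0.1), n_localities=2, seed=8)
        snp, *_, truth = simulate_dataset(cfg)
        opts = McmcOptions(burnin=300, iterations=500, record_interval=5,
                           seed=9, keep_q_draws=True)
        run = run_admixture_mcmc(snp, 2, opts)
        perm = align_qmatrices(truth.true_Q, run.Q).permutation[:2]
        draws = run.q_draws[:, :, perm]
        lo = np.quantile(draws, 0.05, axis=0)
        hi = np.quantile(draws, 0.95, axis=0)
        covered = (truth.true_Q.values >= lo) & (truth.true_Q.values <= hi)
        assert covered.mean() >= 0.80

    def test_k_larger_than_n_rejected(self, tiny_dataset):
        snp, *_ = tiny_dataset
        with pytest.raises(ValueError):
            run_admixture_mcmc(snp, snp.n_individuals + 1)


class TestEstimateLambda:
    @staticmethod
    def exact_posterior_mean(geno, lmax=10.0, npts=2000):
        """Independent oracle: at K=1 the model is conjugate, so the lambda
        posterior is exactly proportional to the Dirichlet-multinomial
        marginal likelihood; integrate it on a grid."""
        coded, n_alleles, _ = geno.dense_coding()
        L, jmax = geno.n_loci, int(n_alleles.max())
        counts = np.zeros((L, jmax))
        ind, loc, copy = np.nonzero(coded >= 0)
        np.add.at(counts, (loc, coded[ind, loc, copy]), 1.0)
        valid = np.arange(jmax)[None, :] < n_alleles[:, None]
        tot, J = counts.sum(axis=1), n_alleles
        lams = np.linspace(1e-3, lmax, npts)
        ll = np.array(
            [
                (gammaln(J * lam) - J * gammaln(lam)
                 + np.where(valid, gammaln(lam + counts), 0.0).sum(axis=1)
                 - gammaln(J * lam + tot)).sum()
                for lam in lams
            ]
        )
        w = np.exp(ll - ll.max())
        return float((w * lams).sum() / w.sum())

    def test_mcmc_matches_exact_conjugate_posterior(self):
        cfg = SimConfig(K_true=1, n_individuals=80, n_snp_loci=300,
                        n_localities=2, seed=13)
        snp, *_ = simulate_dataset(cfg)
        opts = McmcOptions(burnin=100, iterations=300, record_interval=2, seed=1)
        est = estimate_lambda(snp, opts, n_replicates=3)
        exact = self.exact_posterior_mean(snp)
        assert est == pytest.approx(exact, abs=0.05)

    def test_estimate_tracks_generating_lambda(self):
        """Uniform-frequency panels land near 1; rare-allele panels below 0.7."""
        ests = {}
        for lam_sim in (1.0, 0.3):
            cfg = SimConfig(K_true=1, n_individuals=200, n_snp_loci=1000,
                            lambda_sim=lam_sim, n_localities=2, seed=5)
            snp, *_ = simulate_dataset(cfg)
            opts = McmcOptions(burnin=100, iterations=200, record_interval=2, seed=9)
            ests[lam_sim] = estimate_lambda(snp, opts, n_replicates=3)
        assert 0.8 <= ests[1.0] <= 1.2
        assert ests[0.3] < 0.7
        assert ests[0.3] < ests[1.0]

    def test_needs_at_least_one_replicate(self, tiny_dataset):
        with pytest.raises(ValueError):
            estimate_lambda(tiny_dataset[0], n_replicates=0)


class TestReplicateRuns:
    def test_k1_grid_shape_and_trivial_q(self, tiny_dataset):
        snp, *_ = tiny_dataset
        opts = McmcOptions(burnin=20, iterations=20, record_interval=2, seed=0)
        runs = replicate_runs(snp, [1], n_replicates=3, opts=opts)
        assert set(runs) == {(1, 0), (1, 1), (1, 2)}
        assert all(np.allclose(r.Q.values, 1.0) for r in runs.values())

    def test_replicates_have_distinct_traces(self, tiny_dataset):
        snp, *_ = tiny_dataset
        opts = McmcOptions(burnin=20, iterations=40, record_interval=2, seed=0)
        runs = replicate_runs(snp, [2], n_replicates=4, opts=opts)
        traces = [tuple(r.loglik_trace) for r in runs.values()]
        assert len(set(traces)) == 4

    def test_true_k_fits_better_than_k1(self, two_pop_dataset):
        """Mean lnP(X|K) favours K=2 over K=1 on two-population data."""
        snp, *_ = two_pop_dataset
        opts = McmcOptions(burnin=100, iterations=100, record_interval=2, seed=31)
        runs = replicate_runs(snp, [1, 2], n_replicates=3, opts=opts)
        wins = sum(
            pr_x_given_k(runs[(2, r)].loglik_trace)
            > pr_x_given_k(runs[(1, r)].loglik_trace)
            for r in range(3)
        )
        assert wins == 3
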