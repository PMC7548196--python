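"""K-selection metrics, convergence diagnostics and the NJ cross-check."""

import numpy as np
import pytest

from admixcompare import (
    QMatrix,
    allele_sharing_distance,
    evanno_delta_k,
    gelman_rubin,
    neighbor_joining,
    parsimony_index,
    pr_x_given_k,
)
from conftest import make_genotypes


class TestGelmanRubin:
    def test_identical_chains_give_sub_unity_value(self):
        rng = np.random.default_rng(0)
        chain = rng.normal(size=200)
        n = chain.size
        expected = np.sqrt((n - 1) / n)  # B = 0 exactly
        assert gelman_rubin([chain, chain.copy()]) == pytest.approx(expected)

    def test_same_distribution_chains_converge(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(2, 10_000))
        assert gelman_rubin(chains) < 1.05

    def test_separated_chains_blow_up(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.0, 1.0, size=1000)
        b = rng.normal(100.0, 1.0, size=1000)
        assert gelman_rubin([a, b]) > 5.0

    def test_degenerate_constant_chains(self):
        with pytest.raises(ValueError):
            gelman_rubin([np.zeros(10), np.ones(10)])
        assert gelman_rubin([np.ones(10), np.ones(10)]) == pytest.approx(1.0)


class TestPrXGivenK:
    def test_constant_trace(self):
        assert pr_x_given_k([-50.0] * 10) == pytest.approx(-50.0)

    def test_mean_minus_half_variance(self):
        trace = np.tile([-102.0, -98.0], 50)  # mean -100, plug-in var 4
        assert pr_x_given_k(trace) == pytest.approx(-102.0)

    def test_never_exceeds_trace_mean(self):
        rng = np.random.default_rng(3)
        trace = rng.normal(-500, 20, size=100)
        assert pr_x_given_k(trace) <= trace.mean()

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            pr_x_given_k([])


class TestEvannoDeltaK:
    def test_linear_lnp_gives_zero(self):
        mean = {1: -100.0, 2: -90.0, 3: -80.0, 4: -70.0}
        sd = {k: 1.0 for k in mean}
        dk = evanno_delta_k(mean, sd)
        assert dk == {2: pytest.approx(0.0), 3: pytest.approx(0.0)}

    def test_worked_example(self):
        mean = {1: -100.0, 2: -80.0, 3: -75.0, 4: -74.0}
        sd = {k: 1.0 for k in mean}
        dk = evanno_delta_k(mean, sd)
        assert dk[2] == pytest.approx(15.0)
        assert dk[3] == pytest.approx(4.0)

    def test_doubling_sd_halves_delta_k(self):
        mean = {1: -100.0, 2: -80.0, 3: -75.0, 4: -74.0}
        dk1 = evanno_delta_k(mean, {k: 1.0 for k in mean})
        dk2 = evanno_delta_k(mean, {k: 2.0 for k in mean})
        for k in dk1:
            assert dk2[k] == pytest.approx(dk1[k] / 2.0)

    def test_zero_sd_warns_and_returns_inf(self):
        mean = {1: -100.0, 2: -80.0, 3: -75.0}
        sd = {1: 1.0, 2: 0.0, 3: 1.0}
        with pytest.warns(UserWarning):
            dk = evanno_delta_k(mean, sd)
        assert np.isinf(dk[2])

    def test_non_contiguous_range_rejected(self):
        with pytest.raises(ValueError):
            evanno_delta_k({1: -1.0, 3: -2.0, 4: -3.0}, {1: 1, 3: 1, 4: 1})


class TestParsimonyIndex:
    def test_identical_pure_runs_score_one(self):
        q = QMatrix(np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0], [1.0, 0, 0]]))
        assert parsimony_index([q, q, q]) == pytest.approx(1.0)

    def test_identical_uniform_runs_score_zero(self):
        q = QMatrix(np.full((5, 4), 0.25))
        assert parsimony_index([q, q]) == pytest.approx(0.0)

    def test_product_form(self):
        """Two runs with aligned SSC s and consensus mean CA c give s*(1-c)."""
        rng = np.random.default_rng(4)
        q1 = QMatrix(rng.dirichlet(np.ones(3), size=8))
        q2 = QMatrix(rng.dirichlet(np.ones(3), size=8))
        from admixcompare import align_qmatrices, coefficient_of_admixture

        s = align_qmatrices(q1, q2).ssc
        aligned = align_qmatrices(q1, q2).aligned_Q.values[:, :3]
        consensus = (q1.values + aligned) / 2
        consensus /= consensus.sum(axis=1, keepdims=True)
        ca = coefficient_of_admixture(QMatrix(consensus)).mean
        assert parsimony_index([q1, q2]) == pytest.approx(s * (1 - ca), abs=1e-9)

    def test_single_run_returns_parsimony_with_warning(self):
        q = QMatrix(np.array([[1.0, 0.0], [1.0, 0.0]]))
        with pytest.warns(UserWarning):
            assert parsimony_index([q]) == pytest.approx(1.0)


class TestAlleleSharingDistance:
    def test_identical_individuals_distance_zero(self):
        g = make_genotypes([[[0, 1], [1, 1]], [[0, 1], [1, 1]]])
        d = allele_sharing_distance(g)
        assert d[0, 1] == pytest.approx(0.0)

    def test_disjoint_alleles_distance_one(self):
        g = make_genotypes([[[0, 0], [2, 2]], [[1, 1], [3, 3]]], marker_type="microsat")
        assert allele_sharing_distance(g)[0, 1] == pytest.approx(1.0)

    def test_half_shared_single_locus(self):
        # (A,B) vs (A,C): one of two alleles shared -> d = 0.5
        g = make_genotypes([[[0, 1]], [[0, 2]]], marker_type="microsat")
        assert allele_sharing_distance(g)[0, 1] == pytest.approx(0.5)

    def test_het_vs_het_common_allele(self):
        # (A,B) vs (B,C): shared multiset {B} -> 0.5 -> d = 0.5
        g = make_genotypes([[[0, 1]], [[1, 2]]], marker_type="microsat")
        assert allele_sharing_distance(g)[0, 1] == pytest.approx(0.5)

    def test_symmetric_zero_diagonal(self, two_pop_dataset):
        snp, *_ = two_pop_dataset
        d = allele_sharing_distance(snp.subset(individuals=range(10)))
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)

    def test_no_cotyped_loci_is_an_error(self):
        g = make_genotypes([[[0, 1], [-9, -9]], [[-9, -9], [0, 1]]])
        with pytest.raises(ValueError, match="no typed loci"):
            allele_sharing_distance(g)


class TestNeighborJoining:
    @staticmethod
    def _additive_matrix():
        """Four taxa on the tree ((A:1,B:2):5,(C:3,D:4)) -> pairwise paths."""
        # path lengths: AB=3, AC=1+5+3=9, AD=1+5+4=10, BC=2+5+3=10, BD=11, CD=7
        d = np.array(
            [
                [0.0, 3.0, 9.0, 10.0],
                [3.0, 0.0, 10.0, 11.0],
                [9.0, 10.0, 0.0, 7.0],
                [10.0, 11.0, 7.0, 0.0],
            ]
        )
        return d, ["A", "B", "C", "D"]

    def test_additive_matrix_recovered_exactly(self):
        d, ids = self._additive_matrix()
        tree = neighbor_joining(d, ids)
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if i < j:
                    assert tree.find(a).distance(tree.find(b)) == pytest.approx(d[i, j])

    def test_equidistant_triplet_star(self):
        d = np.ones((3, 3)) - np.eye(3)
        tree = neighbor_joining(d, ["a", "b", "c"])
        lengths = sorted(t.length for t in tree.tips())
        assert np.allclose(lengths, 0.5)

    def test_taxon_order_invariance(self):
        d, ids = self._additive_matrix()
        perm = [2, 0, 3, 1]
        tree1 = neighbor_joining(d, ids)
        tree2 = neighbor_joining(d[np.ix_(perm, perm)], [ids[i] for i in perm])
        for a in ids:
            for b in ids:
                if a < b:
                    assert tree1.find(a).distance(tree1.find(b)) == pytest.approx(
                        tree2.find(a).distance(tree2.find(b))
                    )

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(np.zeros((2, 2)))

    def test_groups_simulated_populations(self, two_pop_dataset):
        """Pure individuals from two drifted populations form clean NJ blocks."""
        snp, _, _, truth = two_pop_dataset
        pure = truth.true_Q.values.max(axis=1) > 0.99
        idx = np.flatnonzero(pure)[:16]
        labels = truth.true_Q.values.argmax(axis=1)[idx]
        sub = snp.subset(individuals=idx)
        tree = neighbor_joining(allele_sharing_distance(sub), list(sub.individual_ids))
        # within-population patristic distances are smaller than between
        within, between = [], []
        for i in range(len(idx)):
            for j in range(i + 1, len(idx)):
                dist = tree.find(sub.individual_ids[i]).distance(
                    tree.find(sub.individual_ids[j])
                )
                (within if labels[i] == labels[j] else between).append(dist)
        assert np.mean(within) < np.mean(between)
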