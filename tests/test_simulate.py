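"""Generator correctness: known-truth structure, HWE, FST, missingness, planting."""

import numpy as np
import pytest
from scipy import stats

from admixcompare import (
    ContaminationPlan,
    SimConfig,
    inject_missing,
    make_dart_report,
    plant_low_maf,
    simulate_dataset,
)
from admixcompare.genotypes import MISSING


def weir_cockerham_fst(genotypes, labels):
    """Brute-force two-group Weir-Cockerham theta (ratio-of-sums over loci)."""
    a_sum = b_sum = c_sum = 0.0
    labels = np.asarray(labels)
    for l in range(genotypes.n_loci):
        al = genotypes.alleles[:, l, :]
        ns, ps, hs = [], [], []
        for grp in (0, 1):
            sub = al[labels == grp]
            sub = sub[(sub != MISSING).all(axis=1)]
            if len(sub) < 2:
                break
            ns.append(len(sub))
            ps.append((sub == 1).mean())
            hs.append((sub[:, 0] != sub[:, 1]).mean())
        else:
            n1, n2 = ns
            p1, p2 = ps
            h1, h2 = hs
            r = 2
            nbar = (n1 + n2) / 2
            nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
            pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
            s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
            hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
            a = nbar / nc * (
                s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
            )
            b = nbar / (nbar - 1) * (
                pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            a_sum += a
            b_sum += b
            c_sum += hbar / 2
    return a_sum / (a_sum + b_sum + c_sum)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"K_true": 0},
            {"n_individuals": -3},
            {"F_k": (0.0, 0.5), "K_true": 2},
            {"F_k": (1.0, 0.5), "K_true": 2},
            {"missing_rate": 1.0},
            {"n_localities": 100, "n_individuals": 10},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestSimulateDataset:
    def test_single_population_is_hardy_weinberg(self):
        """K=1: genotype counts at each locus consistent with HWE at pi."""
        cfg = SimConfig(K_true=1, n_individuals=500, n_snp_loci=300,
                        n_localities=5, seed=2)
        snp, *_ = simulate_dataset(cfg)
        ok = tested = 0
        for l in range(snp.n_loci):
            dosage = (snp.alleles[:, l, :] == 1).sum(axis=1)
            p = dosage.mean() / 2
            n = dosage.size
            obs = np.array([(dosage == 0).sum(), (dosage == 1).sum(), (dosage == 2).sum()])
            exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
            if (exp >= 1).all():
                tested += 1
                chi2 = ((obs - exp) ** 2 / exp).sum()
                if stats.chi2.sf(chi2, df=1) > 0.01:
                    ok += 1
        assert tested > 100
        assert ok / tested >= 0.95

    def test_small_alpha_yields_mostly_pure_ancestries(self):
        """Fraction of near-pure individuals matches the Dirichlet oracle.

        Sampling oracle for symmetric Dirichlet(0.01) in 3 parts gives
        P(max q > 0.99) ~= 0.913; with n=500 the binomial 99.7% band is
        about +/-0.04.
        """
        cfg = SimConfig(K_true=3, n_individuals=500, n_snp_loci=10,
                        alpha_sim=0.01, n_localities=5, seed=3)
        *_, truth = simulate_dataset(cfg)
        frac = (truth.true_Q.values.max(axis=1) > 0.99).mean()
        assert abs(frac - 0.913) < 0.05

    def test_fst_between_pure_groups_matches_drift_parameter(self):
        """WC FST between the two pure groups ~= F = 0.2 (F-model expectation)."""
        cfg = SimConfig(K_true=2, n_individuals=200, n_snp_loci=500,
                        alpha_sim=0.01, F_k=(0.2, 0.2), n_localities=4, seed=1)
        snp, *_, truth = simulate_dataset(cfg)
        pure = truth.true_Q.values.max(axis=1) > 0.99
        labels = truth.true_Q.values.argmax(axis=1)[pure]
        fst = weir_cockerham_fst(snp.subset(np.flatnonzero(pure)), labels)
        assert abs(fst - 0.2) < 0.05

    def test_truth_simplexes_and_row_sums(self, two_pop_dataset):
        *_, truth = two_pop_dataset
        assert np.allclose(truth.true_Q.values.sum(axis=1), 1.0, atol=1e-9)
        for marker in ("snp", "microsat"):
            assert np.allclose(truth.ancestral_freqs[marker].sum(axis=-1), 1.0, atol=1e-9)
            assert np.allclose(truth.population_freqs[marker].sum(axis=-1), 1.0, atol=1e-9)

    def test_weak_drift_keeps_population_freqs_near_ancestral(self):
        cfg = SimConfig(K_true=3, n_individuals=6, n_snp_loci=1000,
                        F_k=(1e-4,) * 3, n_localities=1, seed=4)
        *_, truth = simulate_dataset(cfg)
        gap = np.abs(truth.population_freqs["snp"] - truth.ancestral_freqs["snp"][None])
        assert gap.max() < 0.02

    def test_seed_determinism_and_sensitivity(self):
        cfg = SimConfig(seed=11)
        a1 = simulate_dataset(cfg)[0].alleles
        a2 = simulate_dataset(SimConfig(seed=11))[0].alleles
        a3 = simulate_dataset(SimConfig(seed=12))[0].alleles
        assert np.array_equal(a1, a2)
        assert not np.array_equal(a1, a3)

    def test_allele_count_bounds(self, two_pop_dataset):
        snp, msat, *_ = two_pop_dataset
        for l in range(snp.n_loci):
            assert len(snp.allele_frequencies(l)) <= 2
        for l in range(msat.n_loci):
            assert len(msat.allele_frequencies(l)) <= 8

    def test_founder_cline_reduces_northern_heterozygosity(self):
        cfg = SimConfig(K_true=1, n_individuals=80, n_snp_loci=400,
                        n_localities=8, gradient_slope=-0.08, seed=21)
        snp, *_, truth = simulate_dataset(cfg)
        het = 1.0 - np.isnan(snp.heterozygous())  # no missing here
        het = np.nan_to_num(snp.heterozygous()).mean(axis=1)
        south = het[[i for i, l in enumerate(snp.locality_ids) if l == "L00"]]
        north = het[[i for i, l in enumerate(snp.locality_ids) if l == "L07"]]
        assert south.mean() > north.mean()


class TestInjectMissing:
    def test_zero_rate_is_identity(self, tiny_dataset):
        snp, *_ = tiny_dataset
        out = inject_missing(snp, 0.0, seed=5)
        assert np.array_equal(out.alleles, snp.alleles)

    def test_half_rate_binomial_band(self):
        cfg = SimConfig(K_true=1, n_individuals=100, n_snp_loci=100,
                        n_localities=2, seed=6)
        snp, *_ = simulate_dataset(cfg)
        out = inject_missing(snp, 0.5, seed=8)
        frac = out.missing_calls().mean()
        assert 0.45 <= frac <= 0.55

    def test_dart_like_missing_rate(self):
        """7.6% target on 10,000 calls lands in the binomial 99% interval."""
        cfg = SimConfig(K_true=1, n_individuals=100, n_snp_loci=100,
                        n_localities=2, seed=9)
        snp, *_ = simulate_dataset(cfg)
        out = inject_missing(snp, 0.076, seed=10)
        assert 690 <= out.missing_calls().sum() <= 830

    def test_rate_one_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            inject_missing(tiny_dataset[0], 1.0, seed=0)


class TestDartReport:
    def test_clean_plan_has_clean_fields(self, two_pop_dataset):
        snp, *_ = two_pop_dataset
        rep = make_dart_report(snp, ContaminationPlan(), seed=0)
        assert (rep["rep_avg"] == 0.99).all()
        assert (rep["allele_read_proportion"] == 0.5).all()
        assert rep["contig_id"].is_unique

    def test_planted_low_repavg_identities(self, two_pop_dataset):
        snp, *_ = two_pop_dataset
        bad = snp.locus_ids[5:15]
        rep = make_dart_report(snp, ContaminationPlan(low_repavg=list(bad)), seed=0)
        low = set(rep.loc[rep["rep_avg"] < 0.95, "locus_id"])
        assert low == set(bad)

    def test_shared_contig_records(self, two_pop_dataset):
        snp, *_ = two_pop_dataset
        pair = [snp.locus_ids[0], snp.locus_ids[1]]
        rep = make_dart_report(snp, ContaminationPlan(contig_groups=[pair]), seed=0)
        sub = rep.set_index("locus_id").loc[pair]
        assert sub["contig_id"].nunique() == 1
        assert list(sub["rep_avg"]) == [0.99, 0.985]

    def test_non_snp_input_rejected(self, two_pop_dataset):
        _, msat, *_ = two_pop_dataset
        with pytest.raises(ValueError):
            make_dart_report(msat, ContaminationPlan())

    def test_plant_low_maf_sets_exact_frequency(self, two_pop_dataset):
        snp, *_ = two_pop_dataset
        target = [snp.locus_ids[3]]
        out = plant_low_maf(snp, target, minor_copies=3)
        maf = out.minor_allele_frequency()[3]
        assert maf == pytest.approx(3 / (2 * snp.n_individuals))
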