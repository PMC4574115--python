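"""Genotype-senDMP correlations, directional chi-squared, permutation null."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import senesig as sg

from conftest import make_beta


def make_genotypes(dosages, individuals=None):
    dosages = np.asarray(dosages, dtype=float)
    snp_ids = [f"rs{i}" for i in range(dosages.shape[0])]
    individuals = individuals or [f"i{j}" for j in range(dosages.shape[1])]
    snps = pd.DataFrame(
        {
            "chrom": "chr1", "pos": range(100, 100 + len(snp_ids)),
            "risk_allele": "A", "trait": "trait",
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )
    return sg.GenotypeMatrix(
        snps, pd.DataFrame(dosages, index=snps.index, columns=individuals)
    )


class TestCorrelations:
    def test_beta_proportional_to_dosage_gives_r_one(self):
        gm = make_genotypes([[0, 1, 2, 1, 0]])
        bm = make_beta(np.array([[0.0, 0.5, 1.0, 0.5, 0.0]]),
                       samples=gm.individual_ids)
        R = sg.genotype_dmp_correlations(gm, bm, bm.probe_ids)
        assert R.iloc[0, 0] == pytest.approx(1.0)

    def test_constant_dosage_is_missing(self):
        gm = make_genotypes([[1, 1, 1, 1]])
        bm = make_beta(np.array([[0.1, 0.2, 0.3, 0.4]]),
                       samples=gm.individual_ids)
        R = sg.genotype_dmp_correlations(gm, bm, bm.probe_ids)
        assert np.isnan(R.iloc[0, 0])

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(99)
        G = rng.integers(0, 3, (5, 20)).astype(float)
        B = rng.random((10, 20))
        gm = make_genotypes(G)
        bm = make_beta(B, samples=gm.individual_ids)
        R = sg.genotype_dmp_correlations(gm, bm, bm.probe_ids)
        for si in range(5):
            for pi in range(10):
                g, b = G[si], B[pi]
                cov = ((g - g.mean()) * (b - b.mean())).mean()
                r = cov / (g.std() * b.std())
                assert abs(R.iloc[si, pi] - r) < 1e-12

    def test_pairwise_complete_with_missing_dosage(self):
        G = np.array([[0.0, 1.0, 2.0, np.nan, 1.0]])
        B = np.array([[0.0, 0.25, 0.5, 0.9, 0.25]])
        gm = make_genotypes(G)
        bm = make_beta(B, samples=gm.individual_ids)
        R = sg.genotype_dmp_correlations(gm, bm, bm.probe_ids)
        assert R.iloc[0, 0] == pytest.approx(1.0)

    def test_too_few_individuals_is_an_error(self):
        gm = make_genotypes([[0, 1]])
        bm = make_beta(np.array([[0.1, 0.2]]), samples=gm.individual_ids)
        with pytest.raises(ValueError, match="shared individuals"):
            sg.genotype_dmp_correlations(gm, bm, bm.probe_ids)


class TestDirectionalChisq:
    def test_fully_concordant_hand_case(self):
        r = {f"h{i}": 0.5 for i in range(10)}
        r.update({f"l{i}": -0.5 for i in range(10)})
        dirs = {f"h{i}": "hyper" for i in range(10)}
        dirs.update({f"l{i}": "hypo" for i in range(10)})
        res = sg.directional_chisq(r, dirs)
        assert (res.a, res.b, res.c, res.d) == (10, 0, 0, 10)
        assert res.statistic == pytest.approx(20.0)
        assert res.sign == 1

    def test_balanced_bins_give_zero(self):
        r = {"h1": 0.5, "h2": -0.5, "l1": 0.5, "l2": -0.5}
        dirs = {"h1": "hyper", "h2": "hyper", "l1": "hypo", "l2": "hypo"}
        res = sg.directional_chisq(r, dirs)
        assert res.statistic == 0.0 and res.sign == 0

    def test_threshold_is_strict(self):
        r = {"h1": 0.15, "l1": -0.15}
        dirs = {"h1": "hyper", "l1": "hypo"}
        res = sg.directional_chisq(r, dirs)
        assert res.n_pass == 0
        assert res.flag == "no informative senDMPs"

    def test_statistic_bounded_and_saturates_iff_concordant(self):
        rng = np.random.default_rng(3)
        r = {f"p{i}": float(rng.uniform(-0.8, 0.8)) for i in range(50)}
        dirs = {f"p{i}": ("hyper" if i % 2 else "hypo") for i in range(50)}
        res = sg.directional_chisq(r, dirs)
        assert abs(res.statistic) <= res.n_pass
        conc = {f"p{i}": (0.5 if i % 2 else -0.5) for i in range(50)}
        res2 = sg.directional_chisq(conc, dirs)
        assert res2.statistic == res2.n_pass

    def test_invariant_under_simultaneous_relabel_and_flip(self):
        rng = np.random.default_rng(4)
        r = {f"p{i}": float(rng.uniform(-0.8, 0.8)) for i in range(30)}
        dirs = {f"p{i}": ("hyper" if rng.random() < 0.5 else "hypo")
                for i in range(30)}
        swapped = {k: ("hypo" if v == "hyper" else "hyper")
                   for k, v in dirs.items()}
        negated = {k: -v for k, v in r.items()}
        res = sg.directional_chisq(r, dirs)
        res_sym = sg.directional_chisq(negated, swapped)
        assert res.statistic == pytest.approx(res_sym.statistic)

    def test_negates_under_risk_allele_flip(self):
        # dosage -> 2 - dosage negates every correlation; no |r| crosses
        # the threshold, so the statistic flips sign exactly
        rng = np.random.default_rng(5)
        r = {f"p{i}": float(rng.choice([-0.6, -0.3, 0.3, 0.6])) for i in range(20)}
        dirs = {f"p{i}": ("hyper" if rng.random() < 0.5 else "hypo")
                for i in range(20)}
        res = sg.directional_chisq(r, dirs)
        res_flip = sg.directional_chisq({k: -v for k, v in r.items()}, dirs)
        assert res_flip.statistic == pytest.approx(-res.statistic)

    def test_independence_variant_runs(self):
        r = {"h1": 0.5, "h2": 0.6, "l1": -0.4, "l2": 0.5}
        dirs = {"h1": "hyper", "h2": "hyper", "l1": "hypo", "l2": "hypo"}
        res = sg.directional_chisq(r, dirs, variant="independence")
        assert np.isfinite(res.statistic)


class TestRanking:
    def test_orders_by_absolute_statistic(self):
        res = [
            sg.SNPAssociationResult("rs1", 5, 0, 0, 0, 5.0, 1, 0.3),
            sg.SNPAssociationResult("rs2", 0, 9, 0, 0, -9.0, -1, 0.5),
            sg.SNPAssociationResult("rs3", 2, 0, 0, 0, 2.0, 1, 0.2),
        ]
        ranked = sg.rank_snp_results(res)
        assert list(ranked.index) == ["rs2", "rs1", "rs3"]

    def test_ties_break_lexicographically(self):
        res = [
            sg.SNPAssociationResult("rsB", 5, 0, 0, 0, 5.0, 1, 0.3),
            sg.SNPAssociationResult("rsA", 0, 5, 0, 0, -5.0, -1, 0.3),
        ]
        ranked = sg.rank_snp_results(res)
        assert list(ranked.index) == ["rsA", "rsB"]

    def test_empty_input(self):
        assert sg.rank_snp_results([]).empty


@pytest.fixture(scope="module")
def small_cohort():
    params = sg.SimParams(
        n_probes=800, n_cohort_hyper=60, n_cohort_hypo=60,
        n_snps=40, causal_affected_fraction=1.0, include_tumors=False,
        seed=31,
    )
    beta, samples, genotypes, _, truth = sg.simulate_cohort(params)
    hyper, hypo = truth.signature_probes()
    sig = sg.SenescenceSignature(hyper, hypo, "agree")
    return beta, genotypes, sig, truth


class TestPermutationTest:
    @pytest.mark.parametrize("mode", ["resample_probes", "shuffle_directions"])
    def test_zero_statistic_gives_p_one(self, mode):
        # constant betas: every correlation is undefined -> statistic 0
        gm = make_genotypes(np.tile([0, 1, 2, 1, 0, 2], (2, 1)))
        bm = make_beta(np.full((20, 6), 0.5), samples=gm.individual_ids)
        sig = sg.SenescenceSignature(bm.probe_ids[:5], bm.probe_ids[5:10])
        out = sg.snp_permutation_test(
            gm, bm, sig, bm.probe_ids, n_perm=50, seed=1, mode=mode,
            min_minor_count=0,
        )
        assert (out["perm_p"] == 1.0).all()

    def test_reproducible_with_fixed_seed(self, small_cohort):
        beta, genotypes, sig, _ = small_cohort
        a = sg.snp_permutation_test(
            genotypes, beta, sig, beta.probe_ids, n_perm=100, seed=7
        )
        b = sg.snp_permutation_test(
            genotypes, beta, sig, beta.probe_ids, n_perm=100, seed=7
        )
        pd.testing.assert_frame_equal(a, b)

    def test_detects_planted_causal_snp(self, small_cohort):
        beta, genotypes, sig, truth = small_cohort
        out = sg.snp_permutation_test(
            genotypes, beta, sig, beta.probe_ids, n_perm=200, seed=7
        )
        causal = truth.snps.index[truth.snps["causal"]][0]
        assert out.at[causal, "perm_p"] <= 0.01
        others = out.loc[out.index != causal, "statistic"].abs()
        assert abs(out.at[causal, "statistic"]) >= others.max()

    def test_universe_must_cover_signature(self, small_cohort):
        beta, genotypes, sig, _ = small_cohort
        with pytest.raises(ValueError, match="universe"):
            sg.snp_permutation_test(
                genotypes, beta, sig, beta.probe_ids[:10], n_perm=10, seed=1
            )

    def test_null_is_uniform_without_burden_heterogeneity(self):
        """With no latent burden the signature probes are exchangeable with
        the universe and the resampling null is exact."""
        pvals = []
        for seed in (1, 2, 3):
            params = sg.SimParams(
                n_probes=1500, n_cohort_hyper=80, n_cohort_hypo=80,
                burden_range=(0.0, 0.0), n_causal_snps=0, n_snps=70,
                include_tumors=False, seed=seed,
            )
            beta, _, genotypes, _, truth = sg.simulate_cohort(params)
            hyper, hypo = truth.signature_probes()
            sig = sg.SenescenceSignature(hyper, hypo)
            out = sg.snp_permutation_test(
                genotypes, beta, sig, beta.probe_ids, n_perm=400, seed=seed + 50
            )
            pvals.extend(out["perm_p"].dropna().tolist())
        ks = stats.kstest(np.asarray(pvals), "uniform")
        assert ks.pvalue > 0.001
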