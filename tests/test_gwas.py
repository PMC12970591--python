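"""Association tests against closed forms and statsmodels; meta, lambda, clumping."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

import tsimpute as ts
from tsimpute.gwas import CHI2_1_MEDIAN, ivw_meta, ivw_meta_table, lambda_gc


class TestAssocLinear:
    def test_exact_linear_relationship(self):
        d = np.array([[0.0], [1.0], [2.0], [1.0]])
        y = 2.0 * d[:, 0]
        res = ts.assoc_linear(d, y)
        assert res["beta"][0] == pytest.approx(2.0, abs=1e-12)
        assert res["se"][0] == pytest.approx(0.0, abs=1e-10)

    def test_four_sample_worked_case(self):
        # dosages 0,1,1,2 and phenotype 1,2,3,4: closed-form simple regression
        d = np.array([0.0, 1.0, 1.0, 2.0])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        beta_hat = np.sum((d - d.mean()) * (y - y.mean())) / np.sum((d - d.mean()) ** 2)
        resid = y - y.mean() - beta_hat * (d - d.mean())
        sigma2 = (resid**2).sum() / (4 - 2)
        se_hat = np.sqrt(sigma2 / np.sum((d - d.mean()) ** 2))
        res = ts.assoc_linear(d[:, None], y)
        assert res["beta"][0] == pytest.approx(beta_hat, abs=1e-12)
        assert res["se"][0] == pytest.approx(se_hat, abs=1e-12)

    def test_matches_statsmodels_with_covariates(self):
        rng = np.random.default_rng(0)
        n = 80
        d = rng.binomial(2, 0.3, (n, 5)).astype(float)
        cov = rng.normal(size=(n, 2))
        y = 0.4 * d[:, 2] + cov @ np.array([0.5, -0.2]) + rng.normal(size=n)
        res = ts.assoc_linear(d, y, cov)
        for j in range(5):
            X = sm.add_constant(np.column_stack([cov, d[:, j]]))
            fit = sm.OLS(y, X).fit()
            assert res["beta"][j] == pytest.approx(fit.params[-1], abs=1e-10)
            assert res["se"][j] == pytest.approx(fit.bse[-1], abs=1e-10)
            assert res["p"][j] == pytest.approx(fit.pvalues[-1], abs=1e-10)

    def test_constant_dosage_skipped(self):
        d = np.column_stack([np.ones(10), np.arange(10, dtype=float) % 3])
        y = np.arange(10, dtype=float)
        res = ts.assoc_linear(d, y)
        assert res["skipped"][0] and not res["skipped"][1]

    def test_missing_phenotype_rejected(self):
        with pytest.raises(ValueError):
            ts.assoc_linear(np.ones((3, 1)), np.array([1.0, np.nan, 2.0]))


class TestAssocLogistic:
    def test_two_by_two_matches_log_odds_ratio(self):
        # dosage in {0,2}: logistic beta per allele equals log(OR)/2
        d = np.repeat([0.0, 0.0, 2.0, 2.0], [30, 10, 12, 28])[:, None]
        y = np.concatenate([np.zeros(30), np.ones(10), np.zeros(12), np.ones(28)])
        res = ts.assoc_logistic(d, y)
        odds_ratio = (28 / 12) / (10 / 30)
        assert res["beta"][0] == pytest.approx(np.log(odds_ratio) / 2, abs=1e-8)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(1)
        n = 120
        d = rng.binomial(2, 0.4, (n, 4)).astype(float)
        cov = rng.normal(size=(n, 1))
        eta = -0.3 + 0.5 * d[:, 1] + 0.4 * cov[:, 0]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        res = ts.assoc_logistic(d, y, cov)
        for j in range(4):
            X = sm.add_constant(np.column_stack([cov, d[:, j]]))
            fit = sm.Logit(y, X).fit(disp=0)
            assert res["beta"][j] == pytest.approx(fit.params[-1], abs=1e-6)
            assert res["se"][j] == pytest.approx(fit.bse[-1], abs=1e-6)

    def test_null_beta_near_zero(self):
        betas = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            d = rng.binomial(2, 0.3, (400, 1)).astype(float)
            y = (rng.random(400) < 0.5).astype(float)
            betas.append(ts.assoc_logistic(d, y)["beta"][0])
        assert abs(np.mean(betas)) < 0.1

    def test_separating_variant_flagged(self):
        d = np.concatenate([np.zeros(20), np.full(20, 2.0)])[:, None]
        y = np.concatenate([np.zeros(20), np.ones(20)])
        res = ts.assoc_logistic(d, y)
        assert res["skipped"][0]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ts.assoc_logistic(np.ones((4, 1)), np.zeros(4))


class TestIvwMeta:
    def test_equal_weights_average(self):
        beta, se, p = ivw_meta([(1.0, 1.0), (3.0, 1.0)])
        assert beta == pytest.approx(2.0, abs=1e-12)
        assert se == pytest.approx(1 / np.sqrt(2), abs=1e-12)

    def test_single_study_identity(self):
        beta, se, _ = ivw_meta([(0.7, 0.3)])
        assert (beta, se) == (pytest.approx(0.7), pytest.approx(0.3))

    def test_three_equal_betas_shrink_se(self):
        beta, se, _ = ivw_meta([(0.5, 0.2)] * 3)
        assert beta == pytest.approx(0.5, abs=1e-12)
        assert se == pytest.approx(0.2 / np.sqrt(3), abs=1e-12)

    def test_closed_form_weighting(self):
        studies = [(0.2, 0.1), (0.5, 0.3), (-0.1, 0.2)]
        w = np.array([s**-2 for _, s in studies])
        b = np.array([b for b, _ in studies])
        beta, se, p = ivw_meta(studies)
        assert beta == pytest.approx((w * b).sum() / w.sum(), abs=1e-12)
        assert se == pytest.approx(w.sum() ** -0.5, abs=1e-12)
        assert p == pytest.approx(2 * stats.norm.sf(abs(beta / se)), abs=1e-15)
        assert se <= min(s for _, s in studies)

    def test_infinite_se_studies_dropped(self):
        beta, se, _ = ivw_meta([(5.0, np.inf), (1.0, 0.5)])
        assert beta == pytest.approx(1.0)
        with pytest.raises(ValueError):
            ivw_meta([(1.0, np.inf)])


class TestLambdaGc:
    def test_median_chi2_identity(self):
        assert lambda_gc(chi2=np.full(11, CHI2_1_MEDIAN)) == pytest.approx(1.0, abs=1e-12)
        assert lambda_gc(chi2=np.full(11, 2 * CHI2_1_MEDIAN)) == pytest.approx(2.0, abs=1e-12)

    def test_uniform_pvalues_near_one(self):
        rng = np.random.default_rng(2)
        p = rng.random(100_000)
        assert lambda_gc(p_values=p) == pytest.approx(1.0, abs=0.02)


class TestClump:
    def make_results(self, pos, p, chrom=None):
        m = len(pos)
        return pd.DataFrame(
            {
                "chrom": chrom or ["1"] * m,
                "pos": pos,
                "id": [f"v{j}" for j in range(m)],
                "beta": np.ones(m),
                "se": np.ones(m),
                "p": p,
                "skipped": [False] * m,
            }
        )

    def test_no_significant_hits_empty(self):
        res = self.make_results([100, 200], [1e-4, 1e-3])
        rng = np.random.default_rng(3)
        leads = ts.clump(res, rng.binomial(2, 0.5, (50, 2)).astype(float))
        assert leads.empty

    def test_correlated_pair_collapses_to_best(self):
        rng = np.random.default_rng(4)
        g = rng.binomial(2, 0.4, (100, 1)).astype(float)
        g = np.column_stack([g, g])  # r^2 = 1, 1 kb apart
        res = self.make_results([1000, 2000], [1e-10, 1e-9])
        leads = ts.clump(res, g)
        assert list(leads["id"]) == ["v0"]

    def test_distant_independent_hits_both_lead(self):
        rng = np.random.default_rng(5)
        g = rng.binomial(2, 0.4, (100, 2)).astype(float)
        res = self.make_results([1_000_000, 3_000_000], [1e-10, 1e-9])
        leads = ts.clump(res, g)
        assert len(leads) == 2

    def test_leads_mutually_independent_by_own_rule(self):
        rng = np.random.default_rng(6)
        base = rng.binomial(2, 0.4, (200, 6)).astype(float)
        g = np.column_stack([base, base[:, :3] + rng.normal(0, 0.1, (200, 3))])
        pos = (np.arange(9) + 1) * 1000
        res = self.make_results(list(pos), list(np.full(9, 1e-9)))
        leads = ts.clump(res, g)
        cols = leads.index.to_numpy()
        sub = g[:, [list(pos).index(p) for p in leads["pos"]]]
        for i in range(len(leads)):
            for j in range(i + 1, len(leads)):
                close = abs(leads["pos"].iloc[i] - leads["pos"].iloc[j]) <= 1e6
                r2 = np.corrcoef(sub[:, i], sub[:, j])[0, 1] ** 2
                assert not (close and r2 > 0.01)


class TestCompareAndBatchOutcome:
    def test_single_cohort_meta_equals_mega(self):
        rng = np.random.default_rng(7)
        d = rng.binomial(2, 0.3, (100, 20)).astype(float)
        y = rng.normal(size=100)
        mega = ts.assoc_linear(d, y)
        meta = ivw_meta_table([mega])
        joined, summary = ts.compare_mega_meta(mega, meta)
        assert np.abs(joined["d_beta"]).max() < 1e-10

    def test_disjoint_variant_sets_error(self):
        a = ts.assoc_linear(np.random.default_rng(0).binomial(2, 0.3, (30, 3)).astype(float), np.zeros(30) + np.arange(30))
        b = a.copy()
        b["pos"] = b["pos"] + 1000
        with pytest.raises(ValueError):
            ts.compare_mega_meta(a, ivw_meta_table([b]))

    def test_random_labels_give_null_lambda(self):
        rng = np.random.default_rng(8)
        n, m = 200, 400
        hap = rng.random((2 * n, m))
        ds = ts.DosageDataset(
            dosages=hap[0::2] + hap[1::2],
            variants=pd.DataFrame(
                {"chrom": ["1"] * m, "pos": np.arange(1, m + 1), "ref": ["A"] * m, "alt": ["G"] * m}
            ),
            sample_ids=[f"s{i}" for i in range(n)],
            rsq=np.ones(m),
            af=hap.mean(axis=0),
            typed=np.zeros(m, dtype=bool),
            hap_dosages=hap,
            array_labels=rng.permutation(np.repeat(["a", "b"], n // 2)),
        )
        out = ts.batch_outcome_gwas(ds)
        assert abs(out["dosage"]["lambda_all"] - 1.0) < 0.15
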