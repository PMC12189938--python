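"""Kinship, mixed-model association, outlier selection and the overlap
randomization test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fiescan.containers import GenotypeTable
from fiescan.gwa import (count_overlaps, genomic_inflation, kinship_matrix,
                         lmm_assoc_scan, overlap_randomization_test,
                         select_fst_outlier_windows, select_gwa_outliers)


def random_gt(n, m, seed, maf_range=(0.1, 0.5)):
    rng = np.random.default_rng(seed)
    p = rng.uniform(*maf_range, m)
    d = rng.binomial(2, p, size=(n, m)).astype(float)
    loci = pd.DataFrame({"chrom": "LG1", "pos": np.arange(1, m + 1) * 1000,
                         "ref": "A", "alt": "T"})
    samples = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)]})
    return GenotypeTable(d, loci, samples)


class TestKinship:
    def test_duplicate_samples_share_diagonal_value(self):
        gt = random_gt(20, 300, seed=1)
        d = gt.dosages.copy()
        d[1] = d[0]
        gt2 = GenotypeTable(d, gt.loci, gt.samples)
        K = kinship_matrix(gt2)
        assert K[0, 1] == pytest.approx(K[0, 0], abs=1e-9)
        assert K[0, 1] == pytest.approx(K[1, 1], abs=1e-9)

    def test_symmetric_and_unit_trace_scale(self):
        gt = random_gt(40, 1000, seed=2)
        K = kinship_matrix(gt)
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        assert np.trace(K) / 40 == pytest.approx(1.0, abs=1e-9)

    def test_monomorphic_input_rejected(self):
        d = np.zeros((5, 4))
        loci = pd.DataFrame({"chrom": "c", "pos": [1, 2, 3, 4],
                             "ref": "A", "alt": "T"})
        gt = GenotypeTable(d, loci,
                           pd.DataFrame({"sample_id": list("abcde")}))
        with pytest.raises(ValueError):
            kinship_matrix(gt)


class TestLmmScan:
    def test_reduces_to_ols_without_random_effect(self):
        gt = random_gt(80, 60, seed=3)
        rng = np.random.default_rng(4)
        y = rng.normal(0, 1, 80)
        sex = rng.integers(0, 2, 80).astype(float)
        res = lmm_assoc_scan(gt, y, covariates=sex, K=None, maf_min=0.0,
                             max_missing=1.0)
        X0 = np.column_stack([np.ones(80), sex])
        for j in range(10):
            g = gt.dosages[:, j]
            X = np.column_stack([X0, g])
            beta, res_ss, *_ = np.linalg.lstsq(X, y, rcond=None)
            dof = 80 - 3
            sigma2 = res_ss[0] / dof
            XtX_inv = np.linalg.inv(X.T @ X)
            se = np.sqrt(sigma2 * XtX_inv[2, 2])
            assert res["beta"].iloc[j] == pytest.approx(beta[2], abs=1e-8)
            assert res["se"].iloc[j] == pytest.approx(se, abs=1e-8)

    def test_zero_kinship_matches_none(self):
        gt = random_gt(50, 40, seed=5)
        y = np.random.default_rng(6).normal(size=50)
        a = lmm_assoc_scan(gt, y, K=None, maf_min=0.0, max_missing=1.0)
        b = lmm_assoc_scan(gt, y, K=np.zeros((50, 50)), maf_min=0.0,
                           max_missing=1.0)
        np.testing.assert_allclose(a["beta"], b["beta"], atol=1e-8)

    def test_recovers_known_effect(self):
        gt = random_gt(200, 50, seed=7)
        rng = np.random.default_rng(8)
        g = gt.dosages[:, 0]
        y = 2.0 * g + rng.normal(0, 0.5, 200)
        res = lmm_assoc_scan(gt, y, K=None, maf_min=0.0, max_missing=1.0)
        assert abs(res["beta"].iloc[0] - 2.0) < 3 * res["se"].iloc[0]

    def test_null_scan_is_calibrated(self):
        gt = random_gt(120, 5000, seed=9)
        y = np.random.default_rng(10).normal(size=120)
        K = kinship_matrix(gt)
        res = lmm_assoc_scan(gt, y, K=K, maf_min=0.0, max_missing=1.0)
        lam = genomic_inflation(res["wald_p"])
        assert 0.9 <= lam <= 1.1
        # p-values roughly uniform
        ks = stats.kstest(res["wald_p"], "uniform").pvalue
        assert ks > 1e-4

    def test_singular_design_rejected(self):
        gt = random_gt(30, 10, seed=11)
        y = np.zeros(30)
        cov = np.ones((30, 1))   # duplicates the intercept
        with pytest.raises(ValueError, match="singular"):
            lmm_assoc_scan(gt, y, covariates=cov, K=None)


class TestGenomicInflation:
    def test_uniform_p_near_one(self):
        p = (np.arange(10_000) + 0.5) / 10_000
        assert genomic_inflation(p) == pytest.approx(1.0, abs=0.01)

    def test_halved_p_inflates(self):
        p = (np.arange(10_000) + 0.5) / 10_000
        assert genomic_inflation(p / 2) > 1.0


class TestOutlierSelection:
    def test_tail_selects_smallest_p(self):
        rng = np.random.default_rng(12)
        assoc = pd.DataFrame({"chrom": "c", "pos": np.arange(10_000),
                              "wald_p": rng.uniform(size=10_000)})
        sel, thr = select_gwa_outliers(assoc, tail=0.0005)
        assert len(sel) >= 5
        assert set(sel["pos"]) >= set(assoc.nsmallest(5, "wald_p")["pos"])

    def test_ties_at_threshold_included(self):
        assoc = pd.DataFrame({"chrom": "c", "pos": np.arange(100),
                              "wald_p": np.r_[[0.001] * 5, np.linspace(0.2, 1, 95)]})
        sel, thr = select_gwa_outliers(assoc, tail=0.01)
        assert len(sel) == 5     # all tied minimal values

    def test_tail_one_selects_everything(self):
        assoc = pd.DataFrame({"chrom": "c", "pos": np.arange(50),
                              "wald_p": np.random.default_rng(13).uniform(size=50)})
        sel, _ = select_gwa_outliers(assoc, tail=1.0)
        assert len(sel) == 50

    def test_top_windows_no_ties(self):
        w = pd.DataFrame({"chrom": "c", "start": np.arange(100) * 100 + 1,
                          "end": np.arange(100) * 100 + 101,
                          "fst_weighted": np.linspace(0, 0.99, 100)})
        sel = select_fst_outlier_windows(w, top=0.05)
        assert len(sel) == 5
        assert sel["fst_weighted"].min() >= np.quantile(w["fst_weighted"], 0.95)

    def test_undefined_windows_excluded(self):
        w = pd.DataFrame({"chrom": "c", "start": np.arange(40) * 100 + 1,
                          "end": np.arange(40) * 100 + 101,
                          "fst_weighted": np.r_[[np.nan] * 10,
                                                np.linspace(0, 1, 30)]})
        sel = select_fst_outlier_windows(w, top=0.1)
        assert len(sel) == 3
        assert not sel["fst_weighted"].isna().any()


class TestOverlapCounting:
    WINDOWS = pd.DataFrame({"chrom": ["c", "c"], "start": [1, 1001],
                            "end": [1001, 2001]})

    def test_many_snps_one_window_count_once(self):
        snps = pd.DataFrame({"chrom": "c", "pos": [10, 20, 30]})
        assert count_overlaps(snps, self.WINDOWS) == 1

    def test_half_open_boundary(self):
        snps = pd.DataFrame({"chrom": "c", "pos": [1001]})
        assert count_overlaps(snps, self.WINDOWS) == 1
        snps = pd.DataFrame({"chrom": "c", "pos": [2001]})
        assert count_overlaps(snps, self.WINDOWS) == 0

    def test_empty_set(self):
        assert count_overlaps(pd.DataFrame({"chrom": [], "pos": []}),
                              self.WINDOWS) == 0


class TestOverlapRandomization:
    def _loci(self, m=2000):
        return pd.DataFrame({"chrom": "c", "pos": np.arange(1, m + 1) * 10})

    def test_genome_covering_windows_give_p_near_one(self):
        loci = self._loci(500)
        win = pd.DataFrame({"chrom": ["c"], "start": [1], "end": [10_000_000]})
        res = overlap_randomization_test(loci, win, n_draw=50, B=200, seed=1,
                                         observed=1)
        assert res.p_emp == pytest.approx(1.0, abs=0.02)

    def test_maximal_enrichment_gives_minimal_p(self):
        loci = self._loci(2000)
        win = pd.DataFrame({"chrom": ["c"] * 3,
                            "start": [1, 5001, 9001],
                            "end": [101, 5101, 9101]})
        res = overlap_randomization_test(loci, win, n_draw=10, B=500, seed=2,
                                         observed=3)
        assert res.p_emp == pytest.approx(1 / 501, abs=1e-12)

    def test_null_mean_matches_hypergeometric_closed_form(self):
        # E[overlap] = sum_w (1 - C(M - m_w, n) / C(M, n))
        loci = self._loci(3000)
        starts = np.arange(1, 30_001, 3000)
        win = pd.DataFrame({"chrom": "c", "start": starts,
                            "end": starts + 500})
        m_w = [(loci["pos"].between(s, s + 499)).sum() for s in starts]
        M, n = len(loci), 100
        expect = sum(1 - stats.hypergeom.pmf(0, M, mw, n) for mw in m_w)
        res = overlap_randomization_test(loci, win, n_draw=n, B=3000, seed=3,
                                         observed=0)
        se = res.null_values.std(ddof=1) / np.sqrt(res.B)
        assert abs(res.null_values.mean() - expect) < 2 * se + 1e-6

    def test_draw_larger_than_pool_rejected(self):
        with pytest.raises(ValueError):
            overlap_randomization_test(self._loci(10), self.win_dummy(),
                                       n_draw=11, B=100, seed=1, observed=0)

    @staticmethod
    def win_dummy():
        return pd.DataFrame({"chrom": ["c"], "start": [1], "end": [2]})
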