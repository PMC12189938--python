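"""Fst windows, diversity/divergence ratios, PCA-based inversion genotyping,
ancestry painting and the Mann-Kendall trend test."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import wc_fst_oracle
from fiescan.containers import GenotypeTable
from fiescan.scan import (ancestry_paint, dxy_windows, fst_windows,
                          genotype_inversion, ld_prune, mann_kendall,
                          pca_genotypes, pi_windows, wc_fst_site)


def make_gt(dosages, positions=None, chrom="LG1", time_index=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 100
    loci = pd.DataFrame({"chrom": chrom, "pos": positions,
                         "ref": "A", "alt": "T"})
    samples = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)],
                            "time_index": time_index or [0] * n})
    return GenotypeTable(dosages, loci, samples)


class TestWcFstSite:
    def test_fixed_difference_gives_one(self):
        a, b, c, ok = wc_fst_site([0, 0, 2, 2], ["x", "x", "y", "y"])
        assert ok
        assert a / (a + b + c) == pytest.approx(1.0)

    def test_identical_compositions_nonpositive(self):
        d = [0, 1, 2, 0, 1, 2]
        a, b, c, ok = wc_fst_site(d, ["x"] * 3 + ["y"] * 3)
        assert ok
        assert a / (a + b + c) <= 0

    def test_monomorphic_site_skipped(self):
        a, b, c, ok = wc_fst_site([2, 2, 2, 2], ["x", "x", "y", "y"])
        assert not ok and (a, b, c) == (0.0, 0.0, 0.0)

    def test_group_all_missing_skipped(self):
        a, b, c, ok = wc_fst_site([0, 1, np.nan, np.nan], ["x", "x", "y", "y"])
        assert not ok

    def test_matches_independent_oracle_on_random_tables(self):
        rng = np.random.default_rng(10)
        for _ in range(300):
            n1, n2 = rng.integers(2, 8, 2)
            d = rng.integers(0, 3, n1 + n2).astype(float)
            if rng.random() < 0.3:
                d[rng.integers(0, len(d))] = np.nan
            labels = ["p1"] * n1 + ["p2"] * n2
            got = wc_fst_site(d, labels)
            want = wc_fst_oracle(d, labels)
            assert got[3] == want[3]
            if got[3]:
                np.testing.assert_allclose(got[:3], want[:3], atol=1e-12)


class TestFstWindows:
    def test_fixed_differences_fill_window_with_one(self):
        d = np.vstack([np.zeros((3, 4)), np.full((3, 4), 2.0)])
        gt = make_gt(d, positions=[10, 20, 30, 40])
        w = fst_windows(gt, ["x"] * 3 + ["y"] * 3, window_bp=100)
        assert len(w) == 1
        assert w["fst_weighted"].iloc[0] == pytest.approx(1.0)

    def test_empty_window_undefined(self):
        d = np.array([[0, 2], [1, 2], [2, 0], [0, 0]], dtype=float)
        gt = make_gt(d, positions=[5, 25_000])
        w = fst_windows(gt, ["x", "x", "y", "y"], window_bp=10_000)
        assert len(w) == 3
        assert w["n_sites"].tolist() == [1, 0, 1]
        assert np.isnan(w["fst_weighted"].iloc[1])

    def test_window_aggregation_equals_per_site_oracle(self):
        rng = np.random.default_rng(11)
        d = rng.integers(0, 3, size=(8, 6)).astype(float)
        labels = ["x"] * 4 + ["y"] * 4
        gt = make_gt(d, positions=[1, 2, 3, 10_001, 10_002, 10_003])
        w = fst_windows(gt, labels, window_bp=10_000)
        for wi, cols in ((0, range(3)), (1, range(3, 6))):
            comps = [wc_fst_oracle(d[:, j], labels) for j in cols]
            A = sum(c[0] for c in comps if c[3])
            T = sum(c[0] + c[1] + c[2] for c in comps if c[3])
            if T > 0:
                assert w["fst_weighted"].iloc[wi] == pytest.approx(A / T, abs=1e-12)


class TestPiDxy:
    def test_pi_hand_count(self):
        # one site 2 alt / 2 ref among 4 alleles + 9 invariant sites:
        # diffs 2*2 = 4, comparisons 10 * C(4,2) = 60
        d = np.zeros((2, 10))
        d[:, 0] = 1.0      # two hets -> 2 alt alleles among 4
        gt = make_gt(d)
        w = pi_windows(gt, ["g", "g"], "g", window_bp=10_000)
        assert w["pi"].iloc[0] == pytest.approx(4 / 60)

    def test_monomorphic_zero(self):
        gt = make_gt(np.zeros((3, 5)))
        assert pi_windows(gt, ["g"] * 3, "g")["pi"].iloc[0] == 0.0

    def test_missing_reduces_site_comparisons_only(self):
        d = np.zeros((3, 2))
        d[:, 0] = [0, 1, 1]       # 2 alt among 6
        d[2, 1] = np.nan          # invariant site with one missing diploid
        gt = make_gt(d)
        w = pi_windows(gt, ["g"] * 3, "g", window_bp=10_000)
        # site 1: diffs 2*4=8 over C(6,2)=15; site 2: 0 over C(4,2)=6
        assert w["n_comparisons"].iloc[0] == 15 + 6
        assert w["pi"].iloc[0] == pytest.approx(8 / 21)

    def test_dxy_hand_count(self):
        # groups fixed different at 1 of 10 sites: per-site between-group
        # comparisons 4*4; diffs 16 at the fixed site
        d = np.zeros((4, 10))
        d[2:, 0] = 2.0
        gt = make_gt(d)
        w = dxy_windows(gt, ["x", "x", "y", "y"], "x", "y", window_bp=10_000)
        assert w["dxy"].iloc[0] == pytest.approx(16 / 160)

    def test_dxy_equals_2pq_when_groups_match(self):
        # both groups at p = 0.5 -> per-site dxy = 2 p (1-p) = 0.5
        d = np.array([[0, 2], [2, 0], [1, 1], [1, 1]], dtype=float)
        gt = make_gt(d, positions=[10, 20])
        w = dxy_windows(gt, ["x", "x", "y", "y"], "x", "y", window_bp=100)
        assert w["dxy"].iloc[0] == pytest.approx(0.5)

    def test_allele_relabel_invariance(self):
        rng = np.random.default_rng(12)
        d = rng.integers(0, 3, size=(6, 8)).astype(float)
        gt1 = make_gt(d)
        gt2 = make_gt(2.0 - d)      # swap ref/alt at every site
        labels = ["x"] * 3 + ["y"] * 3
        for f in (lambda g: pi_windows(g, labels, "x")["pi"],
                  lambda g: dxy_windows(g, labels, "x", "y")["dxy"]):
            np.testing.assert_allclose(f(gt1), f(gt2), atol=1e-12)


class TestPca:
    def test_two_clonal_groups_separate_on_pc1(self):
        d = np.vstack([np.tile([0, 2, 0, 2, 0, 2], (5, 1)),
                       np.tile([2, 0, 2, 0, 2, 0], (5, 1))]).astype(float)
        gt = make_gt(d)
        scores, ev, kept = pca_genotypes(gt, n_components=3)
        assert ev[0] == pytest.approx(1.0, abs=1e-9)
        assert np.sign(scores[:5, 0]).std() == 0
        assert np.all(np.sign(scores[:5, 0]) != np.sign(scores[5:, 0]))

    def test_r2max_one_disables_pruning(self):
        rng = np.random.default_rng(13)
        gt = make_gt(rng.integers(0, 3, (10, 20)).astype(float))
        kept = ld_prune(gt, window=5, step=2, r2_max=1.0)
        assert len(kept) == 20

    def test_explained_variance_sums_below_one(self):
        rng = np.random.default_rng(14)
        gt = make_gt(rng.integers(0, 3, (12, 30)).astype(float))
        _, ev, _ = pca_genotypes(gt, n_components=5)
        assert ev.sum() <= 1.0 + 1e-9

    def test_pruning_removes_duplicated_loci(self):
        rng = np.random.default_rng(15)
        base = rng.integers(0, 3, (20, 5)).astype(float)
        dup = np.repeat(base, 2, axis=1)     # adjacent perfect-LD pairs
        gt = make_gt(dup)
        kept = ld_prune(gt, window=10, step=5, r2_max=0.5)
        assert len(kept) == 5


class TestInversionGenotyping:
    def _region_gt(self, n_per=8, m=20, seed=16):
        rng = np.random.default_rng(seed)
        blocks = [np.zeros((n_per, m)), np.ones((n_per, m)),
                  np.full((n_per, m), 2.0)]
        d = np.vstack(blocks)
        noise = rng.random(d.shape) < 0.02
        d[noise] = rng.integers(0, 3, noise.sum())
        return make_gt(d), n_per

    def test_three_archetypes_perfectly_assigned(self):
        gt, n_per = self._region_gt()
        calls = genotype_inversion(gt, ("LG1", 1, 10_000),
                                   ancestral_samples=[f"s{i}" for i in range(3)])
        geno = [c.genotype for c in calls]
        assert geno[:n_per] == ["ancestral-hom"] * n_per
        assert geno[n_per:2 * n_per] == ["heterozygous"] * n_per
        assert geno[2 * n_per:] == ["derived-hom"] * n_per
        assert not calls[0].low_confidence

    def test_het_cluster_centered_between_homs(self):
        gt, n_per = self._region_gt(seed=17)
        calls = genotype_inversion(gt, ("LG1", 1, 10_000))
        by = {}
        for c in calls:
            by.setdefault(c.genotype, []).append(c.axis_score)
        lo, mid, hi = sorted(np.mean(v) for v in by.values())
        assert np.mean(by["heterozygous"]) == pytest.approx(mid)

    def test_haplotype_frequency_counting(self):
        gt, n_per = self._region_gt()
        calls = genotype_inversion(gt, ("LG1", 1, 10_000),
                                   ancestral_samples=["s0"])
        n_anc_hom = sum(c.genotype == "ancestral-hom" for c in calls)
        n_het = sum(c.genotype == "heterozygous" for c in calls)
        freq = (2 * n_anc_hom + n_het) / (2 * len(calls))
        assert freq == pytest.approx(0.5)

    def test_small_region_rejected(self):
        gt, _ = self._region_gt()
        with pytest.raises(ValueError):
            genotype_inversion(gt, ("LG1", 1, 500))


class TestAncestryPaint:
    def _gt(self):
        # refs A: all 0; refs B: all 2; focal: one A-like, one F1-like
        d = np.array([[0, 0, 0, 0],
                      [0, 0, 0, 0],
                      [2, 2, 2, 2],
                      [2, 2, 2, 2],
                      [0, 0, 0, 0],
                      [1, 1, 1, 1]], dtype=float)
        return make_gt(d)

    def test_focal_identical_to_ref_all_a(self):
        out = ancestry_paint(self._gt(), ("LG1", 1, 1000), ["s0", "s1"],
                             ["s2", "s3"])
        assert (out.loc["s4"] == "A").all()

    def test_f1_sample_all_het(self):
        out = ancestry_paint(self._gt(), ("LG1", 1, 1000), ["s0", "s1"],
                             ["s2", "s3"])
        assert (out.loc["s5"] == "het").all()

    def test_fixity_one_requires_full_fixation(self):
        d = np.array([[0, 0], [0, 1], [2, 2], [2, 2], [1, 0], [1, 1]],
                     dtype=float)
        gt = make_gt(d)
        out = ancestry_paint(gt, ("LG1", 1, 1000), ["s0", "s1"], ["s2", "s3"],
                             fixity=1.0)
        assert out.shape[1] == 1   # only the fully fixed site survives


class TestMannKendall:
    def test_strictly_decreasing_n5_exact(self):
        r = mann_kendall([5, 4, 3, 2, 1])
        assert r.S == -10
        assert r.direction == "decreasing"
        assert r.method == "exact"
        assert r.p_one_sided == pytest.approx(1 / 120, abs=1e-12)

    def test_increasing_n3_exact(self):
        r = mann_kendall([1, 2, 3])
        assert r.S == 3
        assert r.p_one_sided == pytest.approx(1 / 6, abs=1e-12)

    def test_reversal_negates_s(self):
        rng = np.random.default_rng(18)
        x = rng.normal(size=9)
        assert mann_kendall(x).S == -mann_kendall(x[::-1]).S

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_exact_null_matches_full_enumeration(self, n):
        # brute-force the distribution of S over all n! orderings
        vals = list(range(n))
        ss = []
        for perm in itertools.permutations(vals):
            arr = np.array(perm)
            s = sum(np.sign(arr[j] - arr[i])
                    for i in range(n) for j in range(i + 1, n))
            ss.append(s)
        ss = np.array(ss)
        x = np.random.default_rng(n).normal(size=n)
        r = mann_kendall(x)
        brute_one = (np.mean(ss >= r.S) if r.S >= 0 else np.mean(ss <= r.S))
        assert r.p_one_sided == pytest.approx(brute_one, abs=1e-12)

    def test_ties_exact_small_n(self):
        r = mann_kendall([1, 1, 2, 3])
        assert r.method == "exact"
        # enumerate the 12 distinct orderings of {1,1,2,3}
        from itertools import permutations

        ss = []
        for perm in set(permutations((1, 1, 2, 3))):
            arr = np.array(perm)
            ss.append(sum(np.sign(arr[j] - arr[i])
                          for i in range(4) for j in range(i + 1, 4)))
        ss = np.array(ss)
        assert r.p_one_sided == pytest.approx(np.mean(ss >= r.S), abs=1e-12)

    def test_all_equal_is_null(self):
        r = mann_kendall([2.0, 2.0, 2.0, 2.0])
        assert r.S == 0 and r.p_one_sided == 1.0

    def test_large_n_normal_approximation(self):
        rng = np.random.default_rng(19)
        x = np.arange(30) + rng.normal(0, 5, 30)
        r = mann_kendall(x)
        assert r.method == "normal"
        assert r.p_one_sided < 0.05
        assert abs(r.S) <= 30 * 29 / 2
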