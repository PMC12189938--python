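"""Generators: seasonal otolith profiles, VBGF cohorts, Wright-Fisher drift
and polygenic size-selective mortality."""

import numpy as np
import pandas as pd
import pytest

from fiescan.aging import detect_minima, smooth_profile
from fiescan.simulate import (SelectionConfig, SimConfig, simulate_growth_cohort,
                              simulate_otolith_profile, simulate_polygenic_selection,
                              simulate_wright_fisher, vbgf)
from fiescan.vcfio import read_vcf, write_sample_metadata, write_vcf


class TestOtolithProfiles:
    def test_age_zero_has_no_seasonal_minima(self):
        prof, truth = simulate_otolith_profile(0, 400, 5, 0.0, seed=1)
        assert truth["minima_radii"].size == 0
        assert detect_minima(prof.distances, truth["clean_mg"]).size == 0

    @pytest.mark.parametrize("age", [1, 3, 5, 7])
    def test_noise_free_signal_carries_exactly_age_minima(self, age):
        prof, truth = simulate_otolith_profile(age, 500 + 200 * age, 8, 0.0, seed=2)
        for clean in (truth["clean_mg"], truth["clean_p"]):
            sm = smooth_profile(prof.distances, clean, 0.08)
            found = detect_minima(prof.distances, sm, min_separation=20.0,
                                  min_prominence=0.1)
            assert len(found) == age
            # each within one grid step of the true annulus radius
            assert np.all(np.abs(found - truth["minima_radii"]) <= 8.0 + 1e-9)
        assert np.all(np.diff(truth["minima_radii"]) > 0)

    def test_same_seed_reproduces_profile(self):
        a, _ = simulate_otolith_profile(4, 1000, 8, 0.2, seed=7)
        b, _ = simulate_otolith_profile(4, 1000, 8, 0.2, seed=7)
        np.testing.assert_array_equal(a.mg_ca, b.mg_ca)
        np.testing.assert_array_equal(a.p_ca, b.p_ca)

    def test_radius_too_small_for_age_errors(self):
        with pytest.raises(ValueError):
            simulate_otolith_profile(10, 50, 8, 0.1, seed=1)


class TestGrowthCohort:
    def test_zero_noise_radii_equal_group_vbgf(self):
        obs, _ = simulate_growth_cohort([(3.0, 0.4, 0.0)], 5, 0.0, 0.0, seed=3)
        expect = vbgf(3.0, 0.4, 0.0, obs["ta"].to_numpy())
        np.testing.assert_allclose(obs["La"].to_numpy(), expect, rtol=1e-12)

    def test_closed_form_radius_at_age_two(self):
        # L_inf=3, k=0.4, t0=0 -> L(2) = 3 (1 - e^-0.8)
        obs, _ = simulate_growth_cohort([(3.0, 0.4, 0.0)], 3, 0.0, 0.0, seed=4)
        got = obs.loc[obs["ta"] == 2, "La"].iloc[0]
        assert got == pytest.approx(3.0 * (1 - np.exp(-0.8)), abs=1e-9)
        assert got == pytest.approx(1.6521, abs=5e-4)

    def test_group_ordering_preserved_in_mean_radii(self):
        obs, _ = simulate_growth_cohort(
            [(3.0, 0.35, 0.0), (1.8, 0.35, 0.0)], 20, 0.02, 0.01, seed=5,
            age_range=(4, 6))
        top = obs.groupby("group_id").apply(
            lambda d: d.loc[d["ta"] == 4, "La"].mean(), include_groups=False)
        assert top["group0"] > top["group1"]

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            simulate_growth_cohort([(3.0, 0.4, 0.0)], 3, -0.1, 0.0, seed=1)


class TestWrightFisher:
    CFG = SimConfig(n_diploid=300, n_sample_times=3, sample_size=10, burn_in=20)

    def test_same_seed_identical(self):
        a = simulate_wright_fisher(self.CFG, 50, seed=9)
        b = simulate_wright_fisher(self.CFG, 50, seed=9)
        np.testing.assert_array_equal(a.freqs, b.freqs)
        np.testing.assert_array_equal(a.genotypes.dosages, b.genotypes.dosages)

    def test_fixed_and_lost_loci_stay_absorbed(self):
        cfg = SimConfig(n_diploid=20, n_sample_times=2, sample_size=5,
                        burn_in=200)
        wf = simulate_wright_fisher(cfg, 300, seed=10)
        f = wf.freqs
        hit0 = np.argmax(f == 0.0, axis=0)
        hit1 = np.argmax(f == 1.0, axis=0)
        for lo, t0 in enumerate(hit0):
            if f[t0, lo] == 0.0:
                assert np.all(f[t0:, lo] == 0.0)
        for lo, t1 in enumerate(hit1):
            if f[t1, lo] == 1.0:
                assert np.all(f[t1:, lo] == 1.0)

    def test_one_generation_drift_magnitude_matches_binomial_moment(self):
        # E|dp| = sqrt(p(1-p)/2N) * sqrt(2/pi) for one binomial generation
        cfg = SimConfig(n_diploid=2500, n_sample_times=2, sample_size=5,
                        burn_in=0)
        wf = simulate_wright_fisher(cfg, 1000, seed=11)
        p0 = wf.freqs[0]
        dp = np.abs(wf.freqs[1] - p0)
        expect = np.sqrt(p0 * (1 - p0) / 5000) * np.sqrt(2 / np.pi)
        assert np.mean(dp) == pytest.approx(np.mean(expect), rel=0.10)

    def test_heterozygosity_decays_at_one_over_two_n(self):
        # mean H_t ~ H_0 (1 - 1/2N)^t over replicates
        N, t, reps, loci = 100, 50, 500, 40
        rng = np.random.default_rng(12)
        ratios = []
        for _ in range(reps):
            p = np.full(loci, 0.5)
            for _ in range(t):
                p = rng.binomial(2 * N, p) / (2 * N)
            ratios.append(np.mean(2 * p * (1 - p)) / 0.5)
        expect = (1 - 1 / (2 * N)) ** t
        se = np.std(ratios) / np.sqrt(reps)
        assert abs(np.mean(ratios) - expect) < 3 * se + 1e-3

    def test_sample_size_exceeding_population_errors(self):
        with pytest.raises(ValueError):
            SimConfig(n_diploid=10, sample_size=11)

    def test_vcf_roundtrip_is_lossless(self, tmp_path):
        wf = simulate_wright_fisher(self.CFG, 40, seed=13)
        gt = wf.genotypes
        write_vcf(gt, tmp_path / "g.vcf")
        write_sample_metadata(gt.samples, tmp_path / "m.csv")
        back = read_vcf(tmp_path / "g.vcf",
                        samples=pd.read_csv(tmp_path / "m.csv"))
        np.testing.assert_array_equal(gt.dosages, back.dosages)
        pd.testing.assert_frame_equal(
            gt.loci.astype({"pos": int}), back.loci.astype({"pos": int}))


class TestPolygenicSelection:
    def test_zero_harvest_reduces_to_neutral_wf_bitwise(self):
        cfg = SimConfig(n_diploid=200, n_sample_times=3, sample_size=8, burn_in=5)
        sel = SelectionConfig(harvest_fraction=0.0, n_causal_loci=5)
        a = simulate_polygenic_selection(cfg, sel, 60, seed=20)
        b = simulate_wright_fisher(cfg, 60, seed=20)
        np.testing.assert_array_equal(a.freqs, b.freqs)
        np.testing.assert_array_equal(a.genotypes.dosages, b.genotypes.dosages)
        assert "trait" in a.genotypes.samples.columns

    def test_single_strong_locus_moves_with_selection(self):
        # conditional on the locus segregating when harvest starts, the
        # total frequency change matches the selection direction
        cfg = SimConfig(n_diploid=200, n_sample_times=2, sample_interval=20,
                        sample_size=10, burn_in=0)
        sel = SelectionConfig(n_causal_loci=1, effect_sizes=[2.0],
                              env_sd=0.5, harvest_fraction=0.4,
                              harvest_steepness=4.0)
        good = 0
        total = 0
        for seed in range(100):
            res = simulate_polygenic_selection(cfg, sel, 30, seed=seed)
            j = res.truth.causal_loci[0]
            p_start, p_end = res.freqs[0, j], res.freqs[-1, j]
            if not 0.15 <= p_start <= 0.85:
                continue
            total += 1
            # positive effect increases the trait; harvest removes large
            # traits, so the allele should decline
            good += (p_end - p_start) < 0
        assert total >= 30
        assert good / total >= 0.95

    def test_noncausal_loci_drift_without_direction(self):
        cfg = SimConfig(n_diploid=300, n_sample_times=2, sample_interval=5,
                        sample_size=10, burn_in=0)
        sel = SelectionConfig(n_causal_loci=2)
        deltas = []
        for seed in range(40):
            res = simulate_polygenic_selection(cfg, sel, 100, seed=seed)
            neutral = np.setdiff1d(np.arange(100), res.truth.causal_loci)
            deltas.append(np.mean(res.freqs[-1, neutral] - res.freqs[0, neutral]))
        se = np.std(deltas) / np.sqrt(len(deltas))
        assert abs(np.mean(deltas)) < 3 * se + 1e-3

    def test_total_removal_raises_with_diagnostic(self):
        # harvest_fraction must be < 1, but near-1 removal in a tiny
        # population wipes out some replicate and must raise, not hang
        cfg = SimConfig(n_diploid=30, n_sample_times=2, sample_size=5, burn_in=0)
        sel = SelectionConfig(harvest_fraction=0.999, harvest_steepness=0.01,
                              n_causal_loci=5)
        raised = False
        for seed in range(20):
            try:
                simulate_polygenic_selection(cfg, sel, 10, seed=seed)
            except RuntimeError as e:
                assert "removed" in str(e)
                raised = True
                break
        assert raised
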