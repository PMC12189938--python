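# fiescan

Phenotype-to-genome analysis of fisheries-induced evolution, as a tested,
reusable pipeline over synthetic data with known ground truth.

Size-selective fishing removes large, fast-growing fish. If growth is
heritable, decades of such harvest should (i) shift growth phenotypes —
fish reaching smaller asymptotic sizes L∞ faster (larger k) — and
(ii) drive directional allele-frequency change at growth loci that stands
out from genetic drift. Testing this in an archived collection takes a
chain of methods, all implemented here:

- **chemical aging** — fish age read by counting annual winter minima in
  otolith Mg/Ca and P/Ca profiles (loess-style smoothing + prominence-based
  minima detection + a two-element consensus rule);
- **hierarchical growth modelling** — a three-level Bayesian von
  Bertalanffy model, L_a = L∞(1 − e^(−k(t_a − t0))), annuli within fish
  within catch-year groups, fitted by vectorized adaptive MCMC with R̂/ESS
  diagnostics; growth performance index Φ = log₁₀k + 2log₁₀L∞;
  biological-intercept back-calculation; Le Cren condition; Bartlett test;
- **temporal covariance** — the covariance across loci of allele-frequency
  changes in disjoint-endpoint interval pairs (lag-2/lag-3; lag-1 is
  excluded by design), with block bootstrap CIs and a focal-subset
  permutation null;
- **genome scan** — Weir–Cockerham weighted Fst (Σa/Σ(a+b+c)) in
  nonoverlapping windows, pixy-style π and d_xy with invariant sites in the
  denominators, genotype PCA with LD pruning, inversion genotyping by local
  PCA + 3-means, ancestry painting, and an exact small-sample Mann-Kendall
  trend test;
- **GWA + overlap** — a kinship-random-effect linear mixed model on Φ
  (eigendecomposition, profiled variance ratio, Wald tests), extreme-tail
  outlier selection, top-Fst-window selection, and a randomization test for
  the number of outlier windows hit by outlier SNPs;
- **synthetic data** — generators for all inputs (seasonal element
  profiles, VBGF cohorts, Wright–Fisher drift with temporal sampling, and
  polygenic size-selective mortality) that return the ground truth every
  benchmark is scored against.

## Worked example

The numbered scripts under `analysis/` run a complete synthetic study into
`results/study/`: a population of 2,500 diploids under 40%/generation
size-selective harvest on a 20-locus trait, sampled 5 times (30 diploids
each), plus a 5-catch-year otolith cohort whose true group L∞ declines 53%
across the series.

```bash
python analysis/01_simulate_study.py
python analysis/02_age_otoliths.py
python analysis/03_fit_growth.py
python analysis/04_temporal_covariance.py
python analysis/05_genome_scan.py
python analysis/06_gwa_overlap.py
```

prints, stage by stage (seed 20260919):

```
exact-age recovery: 96.00%
consensus flags: {'agreed': 50}

median R-hat: 1.0026
group posterior-median L_inf (otolith mm):
  group0: 3.093  [2.962, 3.233]
  ...
  group4: 1.405  [1.355, 1.456]
fitted decline in group L_inf across the series: 54.6%

causal-subset lag-2 autocovariance +0.00230, permutation p = 0.000999 (B = 1000)

genome-wide weighted Fst (first vs last time point): -0.00071
Mann-Kendall on mean causal allele frequency: S = 10, two-sided p = 0.017 (exact)

genomic inflation lambda: 0.951
GWA outliers (1% tail): 14
observed outlier-window overlap: 4 (null mean 0.63), p_emp = 0.003399 over B = 5000 draws
```

Reading these numbers: the chemical reader recovers 48/50 ages exactly and
flags the rest rather than guessing; the growth model recovers the built-in
L∞ decline (54.6% fitted vs 53% true, group0 truth 3.0, group4 truth 1.41)
with converged chains; the causal-locus covariance sits far outside its
permutation null while the genome-wide Fst stays indistinguishable from
panmixia (the drift background selection must be detected against); the
favored alleles rise monotonically (exact Mann-Kendall p = 0.017); and the
GWA outliers land in the top-Fst windows ~6× more often than random SNP
sets do.

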