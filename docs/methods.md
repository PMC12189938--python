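# Methods

`fiescan` implements a phenotype-to-genome analysis of fisheries-induced
evolution (FIE): size-selective harvest removes large, fast-growing fish,
so the heritable component of growth should shift downward over decades,
and the loci underlying growth should show directional allele-frequency
change distinguishable from drift.  The package provides every analysis
stage — otolith-based aging and growth modelling on the phenotype side,
temporal population genomics on the genotype side, and the tests that join
them — together with synthetic-data generators carrying full ground truth,
so that each stage's statistical behaviour (recovery, calibration, power)
is measurable.

## Synthetic data (`fiescan.simulate`)

**Otolith element profiles.** Otolith Mg/Ca and P/Ca dip each winter, so a
core-to-edge element transect carries one local minimum per completed year
of life.  The generator places a sinusoidal seasonal signal (period one
year, winters at t = m − ¼ for a spring hatch) onto a uniform radial grid
and adds white noise.  Time maps to radius through a monotone von
Bertalanffy (VBGF) radius-at-age curve — by default a generic curve with
coefficient 0.2/yr normalised so the catch date lands on the measured edge
radius, or the fish's own (L∞, k, t0) when supplied, which makes annulus
radii exactly consistent with the growth model that later consumes them.
Truth (age, annulus radii, clean signals) is returned with every profile.
A real transect differs from this emulation in ways that matter: element
baselines drift with ontogeny, winters vary in depth and timing, and the
instrument convolves the signal over the laser spot.  Passing the aging
benchmarks here shows the reader's smoothing/peak logic is correct and
noise-robust, not that any particular field protocol reaches 90% accuracy.

**Growth cohorts.** Fish are nested in catch-year groups; individual
(L∞, k) are log-normally dispersed around group values with a
coefficient of variation `indiv_sd` (default scenarios use 5%), t0 is
group-level, and radii at integer ages get Gaussian observation noise.

**Wright–Fisher drift.** 2N allele copies are binomially resampled each
generation (N = 2500 diploids by default, matching the 5000-genome
neutral control of the study design; 30-Mb coordinate space; mutation and
recombination rates are carried in the config for provenance and optional
coalescent cross-checks, but loci are unlinked and no new mutations arise
during the short simulated era).  Initial frequencies are drawn from the
neutral site-frequency spectrum, density ∝ 1/p truncated to
[1/2N, 1 − 1/2N], an equivalent stationary-diversity stand-in for a
coalescent founding.  After a 100-generation burn-in, 20 diploids are
sampled without replacement (hypergeometric allele counts, random pairing
into genotypes) at each of 5 consecutive generations.

**Polygenic size-selective mortality.** From the first sample generation,
each individual's trait is Σ effects·dosage + N(0, env_sd); removal
probability rises logistically in the trait with the population-wide
removal rate held exactly at `harvest_fraction` by recalibrating the
logistic midpoint each generation; survivors mate at random.  Causal loci
(default 20, additive effects ±0.8 trait units with random sign against
env_sd = 1) are tracked individual-based; unlinked neutral loci advance by
their exact marginal law (hypergeometric survivor subsample, then binomial
reproduction), which is what makes N = 2500 × 10,000 loci × 50 replicates
tractable on one CPU.  The default intensity — 40% removal per generation
through a steep, gear-selectivity-like ogive (slope 4 per trait unit) —
represents heavy industrial exploitation and produces the detectable
directional change the selection-side benchmarks quantify.  With
`harvest_fraction = 0` the function delegates to the neutral kernel with
the same seed, so the null reduction is bit-for-bit exact.

## Chemical aging (`fiescan.aging`)

Each element series is smoothed by local quadratic regression with tricube
weights (`span` = fraction of points per window, default 0.1); minima with
prominence ≥ `min_prominence` are counted, keeping the deeper of any pair
closer than `min_separation`.  Defaults: prominence 25% of the smoothed
series' interquartile range — genuine annual minima are full seasonal
swings (prominence ≈ the IQR itself) while smoothed-noise wiggles stay
below a quarter of it at 20% noise — and separation half the narrowest
expected inter-annulus gap under a VBGF prior (k = 0.35/yr to age 10),
because annuli crowd toward the edge in older fish.  Mg and P counts that
agree give the age; a one-count surplus in one element for a first-quarter
catch is resolved by dropping that element's terminal minimum if it lies
within 10% of the edge (the short post-winter margin confuses the
detector in exactly those fish); anything else is flagged `needs_review`
rather than guessed.  Consensus radii are taken from the P profile
(configurable).  Known limitation: with uniform radial sampling, points
per year fall with age; once an annual increment spans ≲ 2 smoothing
windows the minimum is flattened away, which is why the demo pipeline
samples at 5 µm and reads with span 0.05.

## Hierarchical growth model (`fiescan.growth`)

Radii at annuli follow L_a = L∞(1 − e^(−k(t_a − t0))) with three levels:
measurements in fish, fish in catch-year groups.  Group L∞ and k carry
Gamma(2, mean-matched) priors — mean L∞ = 1.5 × max observed radius, mean
k = 0.3/yr — t0 ~ N(0, 1) at group level only, individual log L∞ and
log k are Normal around the group's logs with Half-Normal(0.5) hyper-SDs
(log-scale sampling enforces positivity), and observation error is
Gaussian with a conjugate inverse-gamma variance.  The sampler is adaptive
Metropolis-within-Gibbs, vectorized across fish and groups, with two
constant-direction ridge proposals — (log L∞, +δ; log k, −δ) per fish,
and (t0, +δ; member log k, +δ/mean-age) per group — swept three times per
iteration; these walk the likelihood ridges that make naive random walks
mix slowly (the triad's ESS rises ~6× for ~1.5× cost).  Convergence is
summarized by R̂ (the larger of the rank-normalized and classic split
forms, so rank saturation cannot mask gross non-convergence) and ESS.
Presets: `"full"` = 3 chains × 100,000 iterations, 10,000 burn-in;
`"test"` = 3 × 10,000 / 1,000, which recovers 5 × 20-fish cohorts to
within a few percent in ~15 s.

Derived quantities: Φ = log₁₀k + 2log₁₀L∞ (base 10 per the
growth-performance convention); biological-intercept back-calculation
L_a = L_c + (O_a − O_c)(L_c − L0)/(O_c − O0) with L0 = 4.3, O0 = 0.01;
Le Cren's relative condition K_n from a pooled log–log length–weight fit;
Bartlett's test for variance homogeneity of first-annulus radii.

## Temporal covariance (`fiescan.temporal`)

For time points T1..Tn the lag-ℓ autocovariance is the covariance across
loci of Δp over (T_i → T_{i+ℓ}) with Δp over (T_{i+1} → T_{i+1+ℓ}).
Lag ≥ 2 is enforced: consecutive intervals share a sampled endpoint whose
sampling noise enters both changes with opposite sign structure, creating
spurious covariance under the null — the reason the analysis design this
package supports abandoned lag-1.  Note a subtler property that the
benchmarks make explicit: even with disjoint sampled endpoints the paired
intervals overlap in *time* by ℓ−1 generations, so the neutral expectation
is not exactly zero but Σ_shared E[p(1−p)]/2N (≈ 1.5 × 10⁻⁵ at the default
conditions, which the simulation reproduces to within Monte-Carlo error).
Observed values must therefore be judged against the simulated neutral
*distribution* — whose per-replicate SD is ~2× that offset — not against a
point null at zero; the package's envelope benchmark does exactly that.

Uncertainty: percentile block bootstrap over contiguous blocks of loci in
genome order (default 1000 loci/block, 5000 resamples), computed from
per-block sufficient statistics.  Significance of a focal subset (e.g.
GWA outliers): the subset's mean lag-ℓ autocovariance versus B random
equally sized subsets of all loci, p = (1 + #{null ≥ obs})/(B + 1).  When
a lag admits several interval pairs the statistic is their mean — one
scalar per test; equivalent for calibration and power to permuting each
pair separately.  Raw (uncorrected) covariances are reported; the
permutation and simulation nulls carry the same sampling noise.

## Genome scan (`fiescan.scan`)

Per-site Weir–Cockerham (1984) components (a, b, c) come from genotype
counts (observed heterozygosity enters c); windowed Fst is the weighted
ratio of sums Σa/Σ(a+b+c) over 20-kb tiles from position 1, half-open —
never the mean of per-site ratios — with negative estimates reported as
computed.  π and d_xy are differences-over-comparisons ratios whose
denominators count genotyped allele pairs site by site, so invariant sites
belong in the input and missing data shrink only their own site's
comparisons; windows default to 50 kb.  PCA runs on mean-imputed centred
dosages after optional region exclusion and sliding-window r² pruning.
Inversion genotyping clusters first-axis local-PCA scores with k-means
(k = 3; the middle cluster is heterozygous, orientation fixed by reference
samples or by calling the larger extreme cluster ancestral; fewer than
three occupied clusters flags the call set).  Ancestry painting labels
focal genotypes at sites with reference-group frequency difference ≥ 0.8
and missingness ≤ 0.2.  The Mann-Kendall S statistic gets an exact null —
Mahonian inversion-count distribution for tie-free series (n ≤ 10),
multiset-permutation enumeration conditioned on the tie pattern (n ≤ 8) —
and otherwise a normal approximation with tie-corrected variance and
continuity correction; one-sided p is taken in the direction of S (a
strictly monotone n = 5 series gives exactly 1/120).

## Association and overlap (`fiescan.gwa`)

Kinship K = ZZᵀ/m over column-standardized, mean-imputed dosages.  The
scan fits y = μ + sex + gβ + u + e with u ~ N(0, σ²_g K) via one
eigendecomposition of K; the variance ratio is profiled on the
covariate-only null model and held fixed across SNPs (per-SNP re-profiling
is a flag — ranks and tails, which downstream steps consume, are barely
affected, and the fixed-ratio scan is vectorized over all SNPs at once).
Wald p = 2Φ̄(|β/SE|).  With the random effect disabled the scan equals OLS
to machine precision, which is one of the oracle benchmarks.  Filters
default to MAF ≥ 0.05 and missingness ≤ 0.1; λ_GC is reported.  Outliers
are all loci with p at or below the empirical tail quantile (default
0.05%, ties included); Fst outlier windows are the top 5% of defined
windows.  The overlap statistic counts distinct outlier windows containing
≥ 1 outlier SNP; its null redraws equally many SNPs from all tested loci
(default B = 5000), p = (1 + #{null ≥ obs})/(B + 1), and its null mean
matches the hypergeometric closed form Σ_w (1 − C(M−m_w, n)/C(M, n)).

## Pipeline and drivers

`fiescan.pipeline.run_pipeline` executes the stages in dependency order on
one synthetic world, with a single global seed fanned out to per-stage
independent substreams (so toggling one stage never changes another's
randomness) and a JSON run report echoing parameters, input hashes and key
outputs.  The numbered scripts under `analysis/` run the same stages one
at a time as a narrated study.  In the synthetic world the selection
simulator's individual trait plays the role of Φ as the association
phenotype; the profile → age → growth → Φ branch demonstrates the
phenotype pipeline on the same cohort and recovers the built-in ~53%
decline in group L∞.

## Benchmark problem sizes and design choices at desk scale

The benchmark experiments (`fiescan.experiments`, reported by
`scripts/acceptance.py`) use: 20 cohorts of 5 × 20 fish for growth
recovery; 200 profiles (ages 1–7, 20% noise) for aging; 100 neutral
replicates of 5,000 loci for the drift envelope; 200 null repetitions at
B = 99 for permutation calibration; 50 replicates each for the two power
experiments (2,000 loci for the covariance route; 150 samples × 10,000
SNPs for the GWA route).  Two desk-scale adaptations in the GWA power
experiment are deliberate: Fst windows of 5 kb and a 1% tail.  With
unlinked loci at ~1 SNP per 3 kb there is no LD to lift a whole 20-kb
window, so a causal site's differentiation would be diluted by ~6 neutral
sites per window; the 5-kb window is the desk-scale analog of "the window
containing the selected haplotype", and the 1% tail yields an outlier set
whose causal fraction at 3,500 tested SNPs matches the intent of a 0.05%
tail at 680k SNPs.  Library defaults keep the full-scale conventions
(20-kb windows, 0.05% tail).  The focal-subset power benchmark uses lag-3,
the longest disjoint-endpoint pair available with five time points, where
accumulated selection signal is largest relative to binomial sampling
noise.

## Numerical conventions and degenerate inputs

Empirical p-values use (1 + x)/(B + 1) and never reach zero.  For the
overlap test the statistic is a small integer, so ties between observed
and null counts make the empirical p mildly conservative — null rejection
runs a little below the nominal 5% rather than above it.  Monomorphic
sites are skipped (flagged) in Fst; windows with no variance are reported
undefined, not zero.  Dosages are {0, 1, 2} with NaN for missing; loci with
missing frequencies at the involved time points are dropped per statistic,
not globally.  All generators and tests are bit-reproducible under a fixed
seed; derived seeds stay below 2³¹.  Known limitations: no linkage (hence
no haplotype structure, no LD decay, no inversion-boundary discovery), no
new mutations during the simulated era, no sampling-noise bias correction
on covariances, no alternative growth functions, and the aging reader's
fixed-span smoother under-resolves late annuli of old, fast-`k` fish when
the radial sampling is coarse.
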