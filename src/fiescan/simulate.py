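"""Synthetic-data generators with known ground truth.

Three families of inputs are emulated, mirroring the study design of a
temporally sampled, size-selectively harvested fish population:

* otolith element profiles (Mg/Ca, P/Ca vs. distance from core) carrying one
  seasonal minimum per completed winter, so the true age is built in;
* growth cohorts — otolith radii at annual annuli following a von
  Bertalanffy growth function (VBGF) with three levels of hierarchy
  (annulus within fish within catch-year group);
* temporal genotype matrices under neutral Wright-Fisher drift, or under
  polygenic size-selective mortality, sampled at a series of generations the
  way archived collections sample a wild population.

Initial allele frequencies are drawn from the neutral site-frequency
spectrum (density proportional to 1/p, truncated to [1/2N, 1-1/2N]) rather
than from a backward-in-time coalescent, which keeps the generator
self-contained while matching the stationary-diversity intent.  Loci are
unlinked; the recombination rate is carried in the config only for optional
coalescent cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import GenotypeTable

__all__ = [
    "SimConfig",
    "SelectionConfig",
    "TruthRecord",
    "WrightFisherResult",
    "SelectionResult",
    "simulate_otolith_profile",
    "simulate_growth_cohort",
    "simulate_wright_fisher",
    "simulate_polygenic_selection",
]

#: year labels used when five time points are simulated (the archived
#: collection spans 1996-2019 at roughly equal spacing)
_DEFAULT_YEARS = ["1996", "2002", "2008", "2014", "2019"]


@dataclass
class SimConfig:
    """Population and sampling parameters for the forward simulations.

    Defaults follow the neutral-control simulation of the study system:
    2500 diploids (5000 genomes), 30-Mb sequence, mutation rate 3.5e-9 and
    recombination rate 3.11e-8 per bp per generation, 100 burn-in
    generations, then 20 diploids sampled at each of 5 consecutive
    generations.
    """

    n_diploid: int = 2500
    seq_length: int = 30_000_000
    mu: float = 3.5e-9
    rec: float = 3.11e-8
    burn_in: int = 100
    n_sample_times: int = 5
    sample_size: int = 20
    sample_interval: int = 1
    n_replicates: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_diploid", "seq_length", "burn_in", "n_sample_times",
                     "sample_size", "sample_interval", "n_replicates"):
            if getattr(self, name) <= 0 and name != "burn_in":
                raise ValueError(f"{name} must be > 0")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.mu < 0 or self.rec < 0:
            raise ValueError("mu and rec must be >= 0")
        if self.sample_size > self.n_diploid:
            raise ValueError("sample_size cannot exceed n_diploid")

    @property
    def sample_generations(self) -> np.ndarray:
        """Generation indices (0-based; generation 0 is the founding state)
        at which diploids are sampled."""
        return self.burn_in + self.sample_interval * np.arange(self.n_sample_times)


@dataclass
class SelectionConfig:
    """Polygenic size-selective mortality.

    Defaults emulate intense size-selective fishing on a polygenic growth
    trait: 20 causal loci of additive effect 0.8 trait units per allele with
    random sign, 40% of the population removed per generation, with removal
    probability rising logistically in the trait at slope 4 per trait unit —
    a steep, gear-selectivity-like ogive.
    """

    n_causal_loci: int = 20
    effect_sizes: np.ndarray | None = None
    effect_size_magnitude: float = 0.8
    env_sd: float = 1.0
    harvest_fraction: float = 0.4
    harvest_steepness: float = 4.0

    def __post_init__(self) -> None:
        if not 0 <= self.harvest_fraction < 1:
            raise ValueError("harvest_fraction must be in [0, 1)")
        if self.n_causal_loci <= 0:
            raise ValueError("n_causal_loci must be > 0")
        if self.env_sd < 0:
            raise ValueError("env_sd must be >= 0")
        if self.effect_sizes is not None:
            self.effect_sizes = np.asarray(self.effect_sizes, dtype=float)
            if len(self.effect_sizes) != self.n_causal_loci:
                raise ValueError("effect_sizes length must equal n_causal_loci")


@dataclass
class TruthRecord:
    """Ground truth accompanying a simulated dataset."""

    ages: dict | None = None
    growth_params: dict | None = None
    causal_loci: np.ndarray | None = None
    effect_sizes: np.ndarray | None = None
    freqs: np.ndarray | None = None          # per-generation allele frequencies
    sample_generations: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# otolith profiles
# ---------------------------------------------------------------------------

def _radius_of_time(t, t_catch, edge_radius, kr=0.2):
    # monotone otolith growth: VBGF-shaped radius-at-age normalised so the
    # catch time maps onto the measured edge radius
    return edge_radius * (1.0 - np.exp(-kr * t)) / (1.0 - np.exp(-kr * t_catch))


def _time_of_radius(r, t_catch, edge_radius, kr=0.2):
    x = r / edge_radius * (1.0 - np.exp(-kr * t_catch))
    return -np.log(1.0 - x) / kr


def simulate_otolith_profile(age: int, edge_radius: float, step: float,
                             noise_sd: float, seed: int | None = None, *,
                             catch_quarter: int = 3, amplitude: float = 1.0,
                             mg_baseline: float = 2.5, p_baseline: float = 3.5,
                             kr: float = 0.2, growth_params: tuple | None = None):
    """Simulate a core-to-edge element-ratio profile with known seasonal minima.

    The fish hatches in spring (t = 0); winters fall at t = m - 1/4 years
    (m = 1, 2, ...), each leaving a local minimum in both Mg/Ca and P/Ca.
    A fish of age ``age`` caught in ``catch_quarter`` has experienced
    exactly ``age`` winters.  Element values are sampled on a uniform radial
    grid of spacing ``step`` with additive white noise of SD ``noise_sd``.

    The seasonal phase is mapped onto radius through a VBGF radius-at-age
    curve.  By default a generic curve with coefficient ``kr`` is
    normalised so the catch time lands on ``edge_radius``; passing
    ``growth_params`` = (L_inf, k, t0) in the profile's radius units uses
    the fish's own growth curve instead (``edge_radius`` is then also taken
    from that curve), so annulus radii are consistent with the cohort's
    growth model.

    Returns
    -------
    (OtolithProfile, truth)
        truth holds ``minima_radii`` (µm, one per winter), the catch time in
        years, and the noise-free signals.
    """
    from .aging import OtolithProfile

    if age < 0:
        raise ValueError("age must be >= 0")
    if step <= 0:
        raise ValueError("step must be > 0")
    if not 1 <= catch_quarter <= 4:
        raise ValueError("catch_quarter must be in 1..4")
    if growth_params is None and edge_radius <= age * step:
        raise ValueError("edge_radius too small for the requested age at this step size")

    rng = np.random.default_rng(seed)
    if age == 0:
        t_catch = 0.7 * catch_quarter / 4.0
    else:
        t_catch = age - 0.25 + (catch_quarter - 0.5) / 4.0

    if growth_params is not None:
        linf, kg, t0 = growth_params
        edge_radius = float(linf * (1.0 - np.exp(-kg * (t_catch - t0))))
        if edge_radius <= age * step:
            raise ValueError("growth curve yields too small an otolith for "
                             "the requested age at this step size")

        def time_of(r):
            return t0 - np.log(1.0 - r / linf) / kg

        def radius_of(t):
            return linf * (1.0 - np.exp(-kg * (np.asarray(t, float) - t0)))
    else:
        def time_of(r):
            return _time_of_radius(r, t_catch, edge_radius, kr)

        def radius_of(t):
            return _radius_of_time(t, t_catch, edge_radius, kr)

    distances = np.arange(step, edge_radius + step / 2, step)
    distances = distances[distances <= edge_radius]
    t = time_of(distances)
    seasonal = -np.cos(2 * np.pi * (t + 0.25))  # minima at t = m - 1/4
    clean_mg = mg_baseline + amplitude * seasonal
    clean_p = p_baseline + amplitude * seasonal
    mg = clean_mg + rng.normal(0.0, noise_sd, size=clean_mg.shape)
    p = clean_p + rng.normal(0.0, noise_sd, size=clean_p.shape)

    t_minima = np.arange(1, age + 1) - 0.25
    minima_radii = radius_of(t_minima)
    profile = OtolithProfile(
        fish_id=f"sim-{seed}", distances=distances, mg_ca=mg, p_ca=p,
        edge_radius=float(edge_radius), catch_quarter=catch_quarter,
    )
    truth = {
        "age": age,
        "minima_radii": minima_radii,
        "t_catch": t_catch,
        "clean_mg": clean_mg,
        "clean_p": clean_p,
    }
    return profile, truth


# ---------------------------------------------------------------------------
# growth cohorts
# ---------------------------------------------------------------------------

def vbgf(linf, k, t0, t):
    """Von Bertalanffy length at age: L(t) = L_inf (1 - exp(-k (t - t0)))."""
    return linf * (1.0 - np.exp(-k * (np.asarray(t, dtype=float) - t0)))


def simulate_growth_cohort(group_params: Sequence[tuple], n_per_group: int,
                           indiv_sd: float, obs_sd: float,
                           seed: int | None = None, *,
                           age_range: tuple = (3, 7)):
    """Simulate annulus radii for fish nested in catch-year groups.

    Individual (L_inf, k) are log-normally dispersed around each group's
    values with coefficient of variation ``indiv_sd`` (a fraction); t0 is a
    group-level parameter.  Each fish contributes radii at integer ages
    1..age plus Gaussian observation noise of SD ``obs_sd``.

    Returns (observations DataFrame, TruthRecord).
    """
    if indiv_sd < 0 or obs_sd < 0:
        raise ValueError("indiv_sd and obs_sd must be >= 0")
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    for linf, k, _t0 in group_params:
        if linf <= 0 or k <= 0:
            raise ValueError("group L_inf and k must be > 0")

    rng = np.random.default_rng(seed)
    rows = []
    fish_truth = {}
    for g, (linf_g, k_g, t0_g) in enumerate(group_params):
        for i in range(n_per_group):
            fish_id = f"g{g}_f{i}"
            age = int(rng.integers(age_range[0], age_range[1] + 1))
            linf_i = linf_g * np.exp(rng.normal(0.0, indiv_sd)) if indiv_sd > 0 else linf_g
            k_i = k_g * np.exp(rng.normal(0.0, indiv_sd)) if indiv_sd > 0 else k_g
            ages = np.arange(1, age + 1)
            radii = vbgf(linf_i, k_i, t0_g, ages)
            obs = radii + rng.normal(0.0, obs_sd, size=radii.shape) if obs_sd > 0 else radii
            for ta, la in zip(ages, obs):
                rows.append((fish_id, f"group{g}", int(ta), float(la)))
            fish_truth[fish_id] = {
                "group": f"group{g}", "age": age,
                "linf": float(linf_i), "k": float(k_i), "t0": float(t0_g),
            }
    obs_df = pd.DataFrame(rows, columns=["fish_id", "group_id", "ta", "La"])
    truth = TruthRecord(
        ages={f: v["age"] for f, v in fish_truth.items()},
        growth_params={
            "groups": {f"group{g}": {"linf": gp[0], "k": gp[1], "t0": gp[2]}
                       for g, gp in enumerate(group_params)},
            "fish": fish_truth,
        },
    )
    return obs_df, truth


# ---------------------------------------------------------------------------
# Wright-Fisher and polygenic selection
# ---------------------------------------------------------------------------

def _initial_frequencies(rng, n_loci, n_diploid):
    """Draw from the neutral SFS, density ~ 1/p on [1/2N, 1 - 1/2N]."""
    pmin = 1.0 / (2 * n_diploid)
    pmax = 1.0 - pmin
    u = rng.random(n_loci)
    return pmin * (pmax / pmin) ** u


def _locus_frame(rng, n_loci, seq_length, chrom="LG1"):
    pos = np.unique(rng.integers(1, seq_length + 1, size=n_loci))
    while len(pos) < n_loci:   # redraw collisions (rare for sparse loci)
        extra = rng.integers(1, seq_length + 1, size=n_loci - len(pos))
        pos = np.unique(np.concatenate([pos, extra]))
    bases = np.array(list("ACGT"))
    ref = rng.integers(0, 4, n_loci)
    alt = (ref + rng.integers(1, 4, n_loci)) % 4
    return pd.DataFrame({"chrom": chrom, "pos": pos, "ref": bases[ref], "alt": bases[alt]})


def _sample_diploids_from_counts(rng, counts, n_diploid, sample_size):
    """Exact without-replacement diploid sample given per-locus allele counts.

    Draws the sampled allele count hypergeometrically, then pairs alleles at
    random into diploids.
    """
    n_loci = counts.shape[0]
    n_alleles = 2 * sample_size
    k = rng.hypergeometric(counts, 2 * n_diploid - counts, n_alleles)
    # place k alt alleles uniformly among the 2*sample_size allele slots
    ranks = np.argsort(rng.random((n_loci, n_alleles)), axis=1)
    alt = ranks < k[:, None]
    dos = alt[:, 0::2].astype(float) + alt[:, 1::2].astype(float)
    return dos.T  # samples x loci


def _samples_frame(sample_labels, time_indices, rng):
    sexes = rng.choice(["F", "M"], size=len(sample_labels))
    return pd.DataFrame({
        "sample_id": sample_labels,
        "time_index": time_indices,
        "year_label": [_year_label(t, max(time_indices) + 1) for t in time_indices],
        "sex": sexes,
    })


def _year_label(t_index, n_times):
    if n_times == len(_DEFAULT_YEARS):
        return _DEFAULT_YEARS[t_index]
    return f"t{t_index}"


@dataclass
class WrightFisherResult:
    freqs: np.ndarray                  # (n_generations + 1, n_loci) truth
    genotypes: GenotypeTable           # all time points stacked
    truth: TruthRecord


@dataclass
class SelectionResult:
    freqs: np.ndarray
    genotypes: GenotypeTable           # carries per-sample 'trait' column
    truth: TruthRecord


def simulate_wright_fisher(config: SimConfig, n_loci: int,
                           seed: int | None = None) -> WrightFisherResult:
    """Neutral multinomial Wright-Fisher drift with temporal sampling.

    2N allele copies are binomially resampled each generation; after
    ``burn_in`` generations, ``sample_size`` diploids are drawn without
    replacement at each sample time.  Fixed or lost loci stay fixed or lost.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = np.random.default_rng(seed)
    N = config.n_diploid
    twoN = 2 * N
    sample_gens = config.sample_generations
    n_gen = int(sample_gens[-1])

    p0 = _initial_frequencies(rng, n_loci, N)
    counts = np.round(p0 * twoN).astype(np.int64)
    counts = np.clip(counts, 1, twoN - 1)
    freqs = np.empty((n_gen + 1, n_loci))
    freqs[0] = counts / twoN
    loci = _locus_frame(rng, n_loci, config.seq_length)

    sample_set = set(int(g) for g in sample_gens)
    dosage_blocks, labels, times = [], [], []
    if 0 in sample_set:
        dosage_blocks.append(_sample_diploids_from_counts(rng, counts, N, config.sample_size))
    for g in range(1, n_gen + 1):
        counts = rng.binomial(twoN, counts / twoN)
        freqs[g] = counts / twoN
        if g in sample_set:
            dosage_blocks.append(_sample_diploids_from_counts(rng, counts, N, config.sample_size))
    for t_idx, g in enumerate(sample_gens):
        labels += [f"t{t_idx}_s{i}" for i in range(config.sample_size)]
        times += [t_idx] * config.sample_size
    samples = _samples_frame(labels, times, rng)
    gt = GenotypeTable(np.vstack(dosage_blocks), loci, samples)
    truth = TruthRecord(freqs=freqs, sample_generations=np.asarray(sample_gens))
    return WrightFisherResult(freqs=freqs, genotypes=gt, truth=truth)


def _harvest_threshold(z, steepness, harvest_fraction):
    """Location c such that mean logistic removal probability equals the
    target harvest fraction."""
    lo, hi = z.min() - 20.0 / max(steepness, 1e-9), z.max() + 20.0 / max(steepness, 1e-9)
    for _ in range(80):
        c = 0.5 * (lo + hi)
        removed = np.mean(1.0 / (1.0 + np.exp(-steepness * (z - c))))
        if removed > harvest_fraction:
            lo = c
        else:
            hi = c
    return 0.5 * (lo + hi)


def simulate_polygenic_selection(config: SimConfig, sel: SelectionConfig,
                                 n_loci: int, seed: int | None = None) -> SelectionResult:
    """Wright-Fisher dynamics with polygenic size-selective mortality.

    Burn-in generations are neutral.  From the first sample generation on,
    each individual's trait is the additive sum of causal-locus effects plus
    Gaussian environmental noise; removal probability rises logistically in
    the trait (large fish are harvested) with the population-wide removal
    rate held at ``harvest_fraction``; survivors mate at random.  Causal
    loci are tracked individual-based; unlinked neutral loci advance by
    their exact marginal law (hypergeometric survivor subsampling followed
    by binomial reproduction).

    With ``harvest_fraction == 0`` the dynamics delegate to
    :func:`simulate_wright_fisher` with the same seed, so the null reduction
    is bit-for-bit exact.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if sel.n_causal_loci > n_loci:
        raise ValueError("n_causal_loci cannot exceed n_loci")

    if sel.harvest_fraction == 0:
        wf = simulate_wright_fisher(config, n_loci, seed)
        rng = np.random.default_rng(np.random.SeedSequence([seed or 0, 7]))
        causal = np.sort(rng.choice(n_loci, sel.n_causal_loci, replace=False))
        beta = _effect_sizes(sel, rng)
        gt = wf.genotypes
        z = gt.dosages[:, causal] @ beta + rng.normal(0, sel.env_sd, gt.n_samples)
        gt.samples["trait"] = z
        truth = TruthRecord(causal_loci=causal, effect_sizes=beta,
                            freqs=wf.freqs, sample_generations=wf.truth.sample_generations)
        return SelectionResult(freqs=wf.freqs, genotypes=gt, truth=truth)

    rng = np.random.default_rng(seed)
    N = config.n_diploid
    twoN = 2 * N
    sample_gens = config.sample_generations
    n_gen = int(sample_gens[-1])

    p0 = _initial_frequencies(rng, n_loci, N)
    counts = np.clip(np.round(p0 * twoN).astype(np.int64), 1, twoN - 1)
    loci = _locus_frame(rng, n_loci, config.seq_length)
    causal = np.sort(rng.choice(n_loci, sel.n_causal_loci, replace=False))
    beta = _effect_sizes(sel, rng)
    neutral = np.setdiff1d(np.arange(n_loci), causal)

    freqs = np.empty((n_gen + 1, n_loci))
    freqs[0] = counts / twoN

    # neutral burn-in on allele counts
    for g in range(1, config.burn_in + 1):
        counts = rng.binomial(twoN, counts / twoN)
        freqs[g] = counts / twoN

    # instantiate causal genotypes at the onset of harvest
    C = rng.binomial(2, np.broadcast_to(counts[causal] / twoN, (N, len(causal)))).astype(np.int8)
    ncounts = counts[neutral].copy()

    sample_set = {int(g): t for t, g in enumerate(sample_gens)}
    blocks, traits_out, labels, times = [], [], [], []

    def record_sample(t_idx, z):
        idx = rng.choice(N, config.sample_size, replace=False)
        dos = np.empty((config.sample_size, n_loci))
        dos[:, causal] = C[idx]
        dos[:, neutral] = _sample_diploids_from_counts(rng, ncounts, N, config.sample_size)
        blocks.append(dos)
        traits_out.append(z[idx])
        labels.extend(f"t{t_idx}_s{i}" for i in range(config.sample_size))
        times.extend([t_idx] * config.sample_size)

    for g in range(config.burn_in, n_gen + 1):
        freqs[g, causal] = C.mean(axis=0) / 2.0
        freqs[g, neutral] = ncounts / twoN
        z = C @ beta + rng.normal(0.0, sel.env_sd, N)
        if g in sample_set:
            record_sample(sample_set[g], z)
        if g == n_gen:
            break
        c = _harvest_threshold(z, sel.harvest_steepness, sel.harvest_fraction)
        p_remove = 1.0 / (1.0 + np.exp(-sel.harvest_steepness * (z - c)))
        survive = rng.random(N) >= p_remove
        if not survive.any():
            raise RuntimeError(
                f"all individuals removed at generation {g} "
                f"(harvest_fraction={sel.harvest_fraction}, trait sd={z.std():.3f})")
        surv_idx = np.flatnonzero(survive)
        n_s = len(surv_idx)
        pa = surv_idx[rng.integers(0, n_s, N)]
        pb = surv_idx[rng.integers(0, n_s, N)]
        C = (rng.binomial(1, C[pa] / 2.0) + rng.binomial(1, C[pb] / 2.0)).astype(np.int8)
        k_surv = rng.hypergeometric(ncounts, twoN - ncounts, 2 * n_s)
        ncounts = rng.binomial(twoN, k_surv / (2 * n_s))

    samples = _samples_frame(labels, times, rng)
    samples["trait"] = np.concatenate(traits_out)
    gt = GenotypeTable(np.vstack(blocks), loci, samples)
    truth = TruthRecord(causal_loci=causal, effect_sizes=beta, freqs=freqs,
                        sample_generations=np.asarray(sample_gens))
    return SelectionResult(freqs=freqs, genotypes=gt, truth=truth)


def _effect_sizes(sel: SelectionConfig, rng) -> np.ndarray:
    if sel.effect_sizes is not None:
        return np.asarray(sel.effect_sizes, dtype=float)
    signs = rng.choice([-1.0, 1.0], size=sel.n_causal_loci)
    return signs * sel.effect_size_magnitude
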