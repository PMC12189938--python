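"""Temporal allele-frequency covariance statistics.

The central statistic is the covariance, across loci, of allele-frequency
changes in two time intervals.  Under pure drift, changes in intervals that
share no sampled endpoint are uncorrelated, so the covariance is centred on
zero; consistent directional (selected) change makes it positive.  Interval
pairs offset by one sampling step with disjoint endpoints are the "lag-2"
and "lag-3" autocovariances; lag-1 (consecutive intervals) is deliberately
not implemented because the shared sampled endpoint injects spurious
positive covariance through sampling noise, which is why the analysis this
package supports switched to lag >= 2.  Uncertainty comes from a block
bootstrap over contiguous blocks of loci, and significance of a focal locus
subset (e.g. GWA outliers) from a permutation null of equally sized random
subsets.

Raw covariances are reported without a sampling-noise bias correction; the
permutation and simulation nulls carry the same sampling noise and so
absorb it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FreqMatrix, GenotypeTable

__all__ = [
    "CovStat",
    "PermResult",
    "allele_frequencies",
    "temporal_cov",
    "lag_autocovariances",
    "block_bootstrap_ci",
    "subset_permutation_test",
]


@dataclass
class CovStat:
    pair: str
    lag: int
    value: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_loci: int = 0


@dataclass
class PermResult:
    observed: float
    null_values: np.ndarray
    p_emp: float
    B: int
    seed: int | None = None


def allele_frequencies(gt: GenotypeTable, time_col: str = "time_index") -> FreqMatrix:
    """Per-time-point alternate-allele frequencies p = sum(dosage) / (2 n).

    Loci are put in genome order (chrom, pos) so that downstream subset
    draws keyed by locus order are reproducible regardless of input column
    order.  A locus with no calls in a time group gets nan there.
    """
    order = np.lexsort((gt.loci["pos"].to_numpy(), gt.loci["chrom"].to_numpy()))
    gt = gt.subset_loci(order)
    times = sorted(pd.unique(gt.samples[time_col]))
    p = np.full((len(times), gt.n_loci), np.nan)
    n = np.zeros((len(times), gt.n_loci))
    for ti, t in enumerate(times):
        rows = gt.dosages[(gt.samples[time_col] == t).to_numpy()]
        if rows.shape[0] == 0:
            raise ValueError(f"time group {t!r} is empty")
        nn = np.sum(~np.isnan(rows), axis=0)
        with np.errstate(invalid="ignore"):
            p[ti] = np.nansum(rows, axis=0) / (2.0 * nn)
        p[ti, nn == 0] = np.nan
        n[ti] = nn
    return FreqMatrix(p=p, n=n, times=list(times), loci=gt.loci)


def _deltas(freqs: FreqMatrix, interval):
    i, j = interval
    return freqs.p[j] - freqs.p[i]


def temporal_cov(freqs: FreqMatrix, interval_a, interval_b) -> float:
    """Sample covariance across loci (denominator n-1) of the frequency
    changes in two intervals, over loci with all four frequencies defined."""
    for iv in (interval_a, interval_b):
        for t in iv:
            if not 0 <= t < freqs.n_times:
                raise ValueError(f"time index {t} out of range")
    da = _deltas(freqs, interval_a)
    db = _deltas(freqs, interval_b)
    ok = ~(np.isnan(da) | np.isnan(db))
    if ok.sum() < 2:
        raise ValueError("fewer than 2 loci with both changes defined")
    return float(np.cov(da[ok], db[ok])[0, 1])


def _interval_label(freqs: FreqMatrix, interval) -> str:
    i, j = interval
    return f"Δ{freqs.times[i]}–{freqs.times[j]}"


def lag_pairs(n_times: int, lag: int):
    """Interval pairs (T_i -> T_{i+lag}) x (T_{i+1} -> T_{i+1+lag}).

    Requires lag >= 2 so the paired intervals share no sampled endpoint.
    """
    if lag < 2:
        raise ValueError("lag must be >= 2: consecutive intervals share a "
                         "sampled endpoint and inherit its noise")
    if n_times < lag + 2:
        raise ValueError("need at least lag + 2 time points")
    return [(((i, i + lag)), ((i + 1, i + 1 + lag))) for i in range(n_times - lag - 1)]


def lag_autocovariances(freqs: FreqMatrix, lag: int) -> list[CovStat]:
    """All lag-``lag`` autocovariances of frequency changes."""
    out = []
    for iv_a, iv_b in lag_pairs(freqs.n_times, lag):
        da = _deltas(freqs, iv_a)
        db = _deltas(freqs, iv_b)
        ok = ~(np.isnan(da) | np.isnan(db))
        value = temporal_cov(freqs, iv_a, iv_b)
        out.append(CovStat(
            pair=f"{_interval_label(freqs, iv_a)} × {_interval_label(freqs, iv_b)}",
            lag=lag, value=value, n_loci=int(ok.sum())))
    return out


def block_bootstrap_ci(freqs: FreqMatrix, interval_a, interval_b,
                       block_size: int = 1000, B: int = 5000,
                       alpha: float = 0.05, seed: int | None = None) -> CovStat:
    """Percentile CI for the covariance from a block bootstrap over loci.

    Loci (already in genome order) are cut into contiguous blocks of
    ``block_size``; blocks are resampled with replacement B times.  A single
    block yields the degenerate CI equal to the point value.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    da = _deltas(freqs, interval_a)
    db = _deltas(freqs, interval_b)
    ok = ~(np.isnan(da) | np.isnan(db))
    if ok.sum() < 2:
        raise ValueError("fewer than 2 loci with both changes defined")
    value = float(np.cov(da[ok], db[ok])[0, 1])

    block_id = np.arange(freqs.n_loci) // block_size
    blocks = np.unique(block_id[ok])
    if len(blocks) == 0:
        raise ValueError("no complete blocks")
    # per-block sufficient statistics over complete loci
    da_ok, db_ok, bid = da[ok], db[ok], block_id[ok]
    nb = np.bincount(bid, minlength=block_id.max() + 1)[blocks].astype(float)
    sa = np.bincount(bid, weights=da_ok, minlength=block_id.max() + 1)[blocks]
    sb = np.bincount(bid, weights=db_ok, minlength=block_id.max() + 1)[blocks]
    sab = np.bincount(bid, weights=da_ok * db_ok, minlength=block_id.max() + 1)[blocks]

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(blocks), size=(B, len(blocks)))
    n_star = nb[idx].sum(axis=1)
    sa_star = sa[idx].sum(axis=1)
    sb_star = sb[idx].sum(axis=1)
    sab_star = sab[idx].sum(axis=1)
    cov_star = (sab_star - sa_star * sb_star / n_star) / (n_star - 1)
    lo, hi = np.percentile(cov_star, [100 * alpha / 2, 100 * (1 - alpha / 2)])

    i, j = interval_a
    pair = (f"{_interval_label(freqs, interval_a)} × "
            f"{_interval_label(freqs, interval_b)}")
    return CovStat(pair=pair, lag=abs(interval_b[0] - i), value=value,
                   ci_low=float(lo), ci_high=float(hi), n_loci=int(ok.sum()))


def _mean_lag_cov(p, n_times, lag, cols):
    """Mean lag autocovariance over the interval pairs, on locus columns
    ``cols`` (2-D allowed: rows are independent subsets)."""
    vals = []
    for iv_a, iv_b in lag_pairs(n_times, lag):
        da = p[iv_a[1]][cols] - p[iv_a[0]][cols]
        db = p[iv_b[1]][cols] - p[iv_b[0]][cols]
        m = cols.shape[-1]
        mu_a = da.mean(axis=-1, keepdims=True)
        mu_b = db.mean(axis=-1, keepdims=True)
        vals.append(((da - mu_a) * (db - mu_b)).sum(axis=-1) / (m - 1))
    return np.mean(vals, axis=0)


def subset_permutation_test(freqs: FreqMatrix, focal_loci, lag: int,
                            B: int = 1000, seed: int | None = None) -> PermResult:
    """Permutation null for the lag autocovariance of a focal locus subset.

    The observed statistic is the mean of the lag-``lag`` autocovariances
    computed on the focal loci; the null re-computes it on B random subsets
    of equal size drawn without replacement from all loci.  The one-sided
    empirical p-value (1 + #{null >= observed}) / (B + 1) never reaches
    zero.  Loci with any missing frequency at the involved time points are
    excluded (from focal and null draws alike).
    """
    focal = np.asarray(focal_loci)
    if focal.dtype == bool:
        focal = np.flatnonzero(focal)
    if len(focal) < 2:
        raise ValueError("need at least 2 focal loci")
    if np.any(focal < 0) or np.any(focal >= freqs.n_loci):
        bad = focal[(focal < 0) | (focal >= freqs.n_loci)]
        raise ValueError(f"focal loci outside the table: {bad.tolist()}")

    complete = ~np.isnan(freqs.p).any(axis=0)
    focal_ok = focal[complete[focal]]
    if len(focal_ok) < 2:
        raise ValueError("fewer than 2 focal loci with complete frequencies")
    pool = np.flatnonzero(complete)
    k = len(focal_ok)

    observed = float(_mean_lag_cov(freqs.p, freqs.n_times, lag, focal_ok))
    rng = np.random.default_rng(seed)
    draws = np.empty((B, k), dtype=int)
    for b in range(B):
        draws[b] = rng.choice(pool, size=k, replace=False)
    null = np.asarray(_mean_lag_cov(freqs.p, freqs.n_times, lag, draws))
    p_emp = (1.0 + np.sum(null >= observed)) / (B + 1.0)
    return PermResult(observed=observed, null_values=null, p_emp=float(p_emp),
                      B=B, seed=seed)
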