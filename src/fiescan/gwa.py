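"""Mixed-model association scan and the outlier-overlap randomization test.

The association model is the standard univariate linear mixed model

    y = mu + covariates + g * beta + u + e,
    u ~ N(0, sg^2 K),  e ~ N(0, se^2 I),

with the kinship matrix K (genome-wide relatedness from standardized
dosages) absorbing population structure as a random effect.  Fitting uses
one eigendecomposition of K; the variance ratio is profiled on the
covariate-only null model by default and held fixed across SNPs (per-SNP
re-estimation is available behind a flag), after which each SNP reduces to
weighted least squares in the rotated basis and a Wald test on beta.

Downstream, the scan's extreme tail (default the 0.05% smallest p-values)
is intersected with the top Fst windows of a temporal genome scan, and the
count of outlier windows containing at least one outlier SNP is compared to
a null built by redrawing equally many SNPs at random from all tested loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import GenotypeTable

__all__ = [
    "AssocResult",
    "OverlapResult",
    "kinship_matrix",
    "lmm_assoc_scan",
    "genomic_inflation",
    "select_gwa_outliers",
    "select_fst_outlier_windows",
    "count_overlaps",
    "overlap_randomization_test",
]


@dataclass
class OverlapResult:
    observed: int
    null_values: np.ndarray
    p_emp: float
    B: int
    n_snps_drawn: int
    seed: int | None = None


def kinship_matrix(gt: GenotypeTable, maf_min: float = 0.01) -> np.ndarray:
    """K = Z Z^T / m over column-standardized, mean-imputed dosages.

    Monomorphic (or sub-MAF) loci are dropped; an all-monomorphic input
    errors.  trace(K)/n is ~1 by construction.
    """
    X = gt.dosages.copy()
    mu = np.nanmean(X, axis=0)
    p = mu / 2.0
    maf = np.minimum(p, 1 - p)
    keep = maf >= maf_min
    if not keep.any():
        raise ValueError("no polymorphic loci above the MAF threshold")
    X = X[:, keep]
    mu = mu[keep]
    inds = np.where(np.isnan(X))
    X[inds] = np.take(mu, inds[1])
    X -= mu
    sd = X.std(axis=0)
    ok = sd > 0
    X = X[:, ok] / sd[ok]
    K = X @ X.T / X.shape[1]
    return K


def _reml_neg_loglik(log_delta, S, yt, Xt):
    """Profiled (ML) negative log-likelihood of the null model in the
    eigenbasis; delta = se^2 / sg^2."""
    delta = np.exp(log_delta)
    w = 1.0 / (S + delta)
    Xw = Xt * w[:, None]
    XtWX = Xt.T @ Xw
    beta = np.linalg.solve(XtWX, Xw.T @ yt)
    r = yt - Xt @ beta
    n = len(yt)
    sg2 = np.sum(w * r * r) / n
    ll = -0.5 * (n * np.log(2 * np.pi * sg2) - np.log(w).sum() + n)
    return -ll


def lmm_assoc_scan(gt: GenotypeTable, phenotype, covariates=None,
                   K: np.ndarray | None = None, maf_min: float = 0.05,
                   max_missing: float = 0.1,
                   per_snp_ratio: bool = False) -> pd.DataFrame:
    """Per-SNP association of a quantitative phenotype under the LMM.

    Returns a DataFrame (chrom, pos, beta, se, wald_p, maf, n_used) over
    SNPs passing the MAF and missingness filters.  With ``K=None`` (or a
    zero matrix) the fit reduces to ordinary least squares.
    """
    y = np.asarray(phenotype, dtype=float)
    n = gt.n_samples
    if len(y) != n:
        raise ValueError("phenotype length must match sample count")
    X = np.ones((n, 1))
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.hstack([X, C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular covariate design")

    p_hat = np.nanmean(gt.dosages, axis=0) / 2.0
    maf = np.minimum(p_hat, 1 - p_hat)
    missing = np.isnan(gt.dosages).mean(axis=0)
    keep = (maf >= maf_min) & (missing <= max_missing)
    loci = gt.loci.reset_index(drop=True).loc[keep, ["chrom", "pos"]].reset_index(drop=True)
    G = gt.dosages[:, keep].copy()
    n_used = np.sum(~np.isnan(G), axis=0)
    mu = np.nanmean(G, axis=0)
    inds = np.where(np.isnan(G))
    G[inds] = np.take(mu, inds[1])

    use_mm = K is not None and np.any(K)
    if use_mm:
        K = np.asarray(K, dtype=float)
        S, U = np.linalg.eigh(K)
        if S.min() < -1e-8 * max(1.0, S.max()):
            import warnings

            warnings.warn("kinship matrix not PSD; clamping negative eigenvalues")
        S = np.clip(S, 0.0, None)
        yt = U.T @ y
        Xt = U.T @ X
        Gt = U.T @ G
        res = optimize.minimize_scalar(
            _reml_neg_loglik, bounds=(-10.0, 10.0), args=(S, yt, Xt),
            method="bounded", options={"xatol": 1e-6})
        log_delta0 = float(res.x)
    else:
        S = np.zeros(n)
        yt, Xt, Gt = y, X, G
        log_delta0 = 0.0   # equal weights -> OLS

    def _scan_fixed(log_delta):
        w = 1.0 / (S + np.exp(log_delta)) if use_mm else np.ones(n)
        sw = np.sqrt(w)
        Xw = Xt * sw[:, None]
        yw = yt * sw
        Gw = Gt * sw[:, None]
        Q, _ = np.linalg.qr(Xw)
        y_r = yw - Q @ (Q.T @ yw)
        G_r = Gw - Q @ (Q.T @ Gw)
        gg = np.einsum("ij,ij->j", G_r, G_r)
        gy = G_r.T @ y_r
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = gy / gg
            dof = n - X.shape[1] - 1
            sse = (y_r @ y_r) - beta * gy
            sigma2 = sse / dof
            se = np.sqrt(sigma2 / gg)
        return beta, se

    if per_snp_ratio and use_mm:
        beta = np.empty(Gt.shape[1])
        se = np.empty(Gt.shape[1])
        for j in range(Gt.shape[1]):
            Xj = np.hstack([Xt, Gt[:, j:j + 1]])
            r = optimize.minimize_scalar(
                _reml_neg_loglik, bounds=(-10.0, 10.0), args=(S, yt, Xj),
                method="bounded", options={"xatol": 1e-4})
            bj, sj = _scan_single(float(r.x), S, yt, Xt, Gt[:, j], n, X.shape[1])
            beta[j], se[j] = bj, sj
    else:
        beta, se = _scan_fixed(log_delta0)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    wald_p = 2.0 * stats.norm.sf(np.abs(z))
    out = loci.copy()
    out["beta"] = beta
    out["se"] = se
    out["wald_p"] = np.clip(wald_p, np.finfo(float).tiny, 1.0)
    out["maf"] = maf[keep]
    out["n_used"] = n_used
    return out


def _scan_single(log_delta, S, yt, Xt, g, n, p_cov):
    w = 1.0 / (S + np.exp(log_delta))
    sw = np.sqrt(w)
    Xw = Xt * sw[:, None]
    yw = yt * sw
    gw = g * sw
    Q, _ = np.linalg.qr(Xw)
    y_r = yw - Q @ (Q.T @ yw)
    g_r = gw - Q @ (Q.T @ gw)
    gg = g_r @ g_r
    beta = (g_r @ y_r) / gg
    sse = y_r @ y_r - beta * (g_r @ y_r)
    sigma2 = sse / (n - p_cov - 1)
    return beta, np.sqrt(sigma2 / gg)


def genomic_inflation(pvalues) -> float:
    """Lambda_GC = median observed chi-square / expected median (0.4549)."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) < 100:
        raise ValueError("need at least 100 tests")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


def select_gwa_outliers(assoc: pd.DataFrame, tail: float = 0.0005):
    """Loci in the extreme lower tail of the p-value distribution.

    All loci with p <= the empirical ``tail`` quantile are returned (ties at
    the threshold included), with the threshold used.
    """
    if not 0 < tail <= 1:
        raise ValueError("tail must be in (0, 1]")
    if len(assoc) == 0:
        raise ValueError("empty association table")
    thr = float(np.quantile(assoc["wald_p"].to_numpy(), tail))
    sel = assoc[assoc["wald_p"] <= thr].copy()
    return sel, thr


def select_fst_outlier_windows(windows: pd.DataFrame, top: float = 0.05) -> pd.DataFrame:
    """Defined windows with weighted Fst at or above the (1 - top) quantile."""
    defined = windows.dropna(subset=["fst_weighted"])
    if len(defined) < 20:
        raise ValueError("need at least 20 defined windows")
    thr = np.quantile(defined["fst_weighted"].to_numpy(), 1.0 - top)
    return defined[defined["fst_weighted"] >= thr].copy()


def _window_id_of_loci(loci: pd.DataFrame, window_set: pd.DataFrame) -> np.ndarray:
    """Index of the containing outlier window per locus (-1 if none);
    windows are half-open [start, end)."""
    wid = np.full(len(loci), -1, dtype=int)
    for w, (_, win) in enumerate(window_set.iterrows()):
        hit = ((loci["chrom"] == win["chrom"]) & (loci["pos"] >= win["start"])
               & (loci["pos"] < win["end"])).to_numpy()
        wid[hit] = w
    return wid


def count_overlaps(snp_loci: pd.DataFrame, window_set: pd.DataFrame) -> int:
    """Distinct windows containing at least one SNP of the set."""
    wid = _window_id_of_loci(snp_loci, window_set)
    return int(len(np.unique(wid[wid >= 0])))


def overlap_randomization_test(all_loci: pd.DataFrame, window_set: pd.DataFrame,
                               n_draw: int, B: int = 5000,
                               seed: int | None = None,
                               observed: int | None = None) -> OverlapResult:
    """Null distribution of the outlier-window overlap count.

    ``n_draw`` loci are drawn without replacement from ``all_loci`` B times;
    each draw is scored by :func:`count_overlaps`.  ``observed`` defaults to
    nan-free computation by the caller; p_emp = (1 + #{null >= observed}) /
    (B + 1).
    """
    if n_draw > len(all_loci):
        raise ValueError("n_draw exceeds the number of tested loci")
    if B < 100:
        import warnings

        warnings.warn("B < 100 gives a coarse null")
    wid = _window_id_of_loci(all_loci, window_set)
    rng = np.random.default_rng(seed)
    null = np.empty(B, dtype=int)
    m = len(all_loci)
    for b in range(B):
        draw = rng.choice(m, size=n_draw, replace=False)
        w = wid[draw]
        null[b] = len(np.unique(w[w >= 0]))
    if observed is None:
        raise ValueError("observed overlap count is required")
    p_emp = (1.0 + np.sum(null >= observed)) / (B + 1.0)
    return OverlapResult(observed=int(observed), null_values=null,
                         p_emp=float(p_emp), B=B, n_snps_drawn=n_draw, seed=seed)


@dataclass
class AssocResult:
    """Bundle of a scan with its derived outlier set (convenience for the
    pipeline driver)."""

    assoc: pd.DataFrame
    outliers: pd.DataFrame
    threshold: float
    lambda_gc: float
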