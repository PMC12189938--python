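"""Windowed differentiation and diversity scans, PCA, inversion genotyping
and trend testing.

Differentiation uses Weir & Cockerham's (1984) variance-component estimator
of Fst from diploid genotype counts; windows report the "weighted" (ratio of
sums) form sum(a) / sum(a + b + c), never the mean of per-site ratios.
Diversity (pi) and absolute divergence (dxy) follow the
differences-over-comparisons convention with invariant sites in the
denominator, so missing genotypes shrink a site's comparisons without
biasing the ratio.  Inversion genotypes come from clustering samples on the
first principal axis of the inverted region (three clusters: two homozygote
classes flanking the heterozygotes), and haplotype-frequency time series are
tested for monotone change with an exact small-sample Mann-Kendall test.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeTable

__all__ = [
    "InversionCall",
    "TrendTestResult",
    "wc_fst_site",
    "fst_windows",
    "pi_windows",
    "dxy_windows",
    "pca_genotypes",
    "ld_prune",
    "genotype_inversion",
    "ancestry_paint",
    "mann_kendall",
]


@dataclass
class TrendTestResult:
    S: int
    n: int
    p_one_sided: float
    p_two_sided: float
    direction: str       # "increasing" | "decreasing" | "none"
    method: str          # "exact" | "normal"


# ---------------------------------------------------------------------------
# Weir-Cockerham Fst
# ---------------------------------------------------------------------------

def _group_counts(dosages, labels):
    """Per-group (n_i diploids, p_i alt frequency, h_i observed het freq)."""
    groups = pd.unique(np.asarray(labels))
    n, p, h = [], [], []
    for g in groups:
        d = dosages[np.asarray(labels) == g]
        d = d[~np.isnan(d)]
        if len(d) == 0:
            return None
        n.append(len(d))
        p.append(d.sum() / (2 * len(d)))
        h.append(np.mean(d == 1))
    return np.array(n, float), np.array(p), np.array(h)


def wc_fst_site(dosages, labels):
    """Weir & Cockerham (1984) variance components (a, b, c) for one site.

    Returns (a, b, c, defined_flag).  Sites monomorphic across all groups,
    or with a group entirely missing, are skipped: components 0 and flag
    False.
    """
    dosages = np.asarray(dosages, dtype=float)
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    res = _group_counts(dosages, labels)
    if res is None:
        return 0.0, 0.0, 0.0, False
    n, p, h = res
    r = len(n)
    nbar = n.mean()
    pbar = np.sum(n * p) / (r * nbar)
    if pbar <= 0 or pbar >= 1:
        return 0.0, 0.0, 0.0, False
    nc = (r * nbar - np.sum(n * n) / (r * nbar)) / (r - 1)
    s2 = np.sum(n * (p - pbar) ** 2) / ((r - 1) * nbar)
    hbar = np.sum(n * h) / (r * nbar)

    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return float(a), float(b), float(c), True


def _window_edges(positions, window_bp):
    """Half-open windows [start, start + window) tiled from position 1."""
    last = int(positions.max())
    starts = np.arange(1, last + 1, window_bp)
    return starts


def fst_windows(gt: GenotypeTable, labels, window_bp: int = 20_000) -> pd.DataFrame:
    """Weighted Fst = sum(a) / sum(a+b+c) in nonoverlapping windows.

    Windows with zero total variance are reported with Fst nan (undefined).
    Negative estimates are reported as computed, never clamped.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    labels = np.asarray(labels)
    rows = []
    loci = gt.loci.reset_index(drop=True)
    for chrom, sub in loci.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        comp = np.array([wc_fst_site(gt.dosages[:, j], labels)[:3] for j in idx])
        starts = _window_edges(pos, window_bp)
        wi = (pos - 1) // window_bp
        for w, start in enumerate(starts):
            in_w = wi == w
            n_sites = int(in_w.sum())
            A, Bc, C = comp[in_w].sum(axis=0) if n_sites else (0.0, 0.0, 0.0)
            tot = A + Bc + C
            fst = A / tot if tot > 0 else np.nan
            rows.append((chrom, int(start), int(start + window_bp), n_sites,
                         fst, A, Bc, C))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites",
                                       "fst_weighted", "sum_a", "sum_b", "sum_c"])


# ---------------------------------------------------------------------------
# pi and dxy (differences over comparisons, invariant sites included)
# ---------------------------------------------------------------------------

def _allele_counts(gt: GenotypeTable, mask):
    d = gt.dosages[mask]
    nn = np.sum(~np.isnan(d), axis=0)
    alt = np.nansum(d, axis=0)
    return 2 * nn, alt        # genotyped alleles, alt alleles


def pi_windows(gt: GenotypeTable, labels, group, window_bp: int = 50_000) -> pd.DataFrame:
    """Within-group nucleotide diversity per window.

    ``gt`` must include invariant genotyped sites for absolute values;
    pi_window = sum over sites of pairwise differences / sum of pairwise
    comparisons among genotyped alleles.
    """
    labels = np.asarray(labels)
    mask = labels == group
    n_al, alt = _allele_counts(gt, mask)
    diffs = alt * (n_al - alt)
    comps = n_al * (n_al - 1) / 2.0
    return _ratio_windows(gt.loci, diffs, comps, window_bp, "pi")


def dxy_windows(gt: GenotypeTable, labels, group_x, group_y,
                window_bp: int = 50_000) -> pd.DataFrame:
    """Between-group divergence per window: between-group allele pair
    differences over between-group comparisons."""
    labels = np.asarray(labels)
    nx, ax = _allele_counts(gt, labels == group_x)
    ny, ay = _allele_counts(gt, labels == group_y)
    diffs = ax * (ny - ay) + (nx - ax) * ay
    comps = nx * ny
    return _ratio_windows(gt.loci, diffs.astype(float), comps.astype(float),
                          window_bp, "dxy")


def _ratio_windows(loci, diffs, comps, window_bp, name):
    rows = []
    loci = loci.reset_index(drop=True)
    for chrom, sub in loci.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        starts = _window_edges(pos, window_bp)
        wi = (pos - 1) // window_bp
        for w, start in enumerate(starts):
            in_w = wi == w
            d = diffs[idx[in_w]].sum()
            c = comps[idx[in_w]].sum()
            val = d / c if c > 0 else np.nan
            rows.append((chrom, int(start), int(start + window_bp),
                         int(in_w.sum()), val, d, c))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites",
                                       name, "n_diffs", "n_comparisons"])


# ---------------------------------------------------------------------------
# PCA, LD pruning, inversion genotyping, ancestry painting
# ---------------------------------------------------------------------------

def _imputed_centered(dosages, standardize=False):
    X = dosages.copy()
    mu = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(mu, inds[1])
    X -= mu
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X /= sd
    return X


def ld_prune(gt: GenotypeTable, window: int = 50, step: int = 10,
             r2_max: float = 0.2) -> np.ndarray:
    """Indices of loci kept after sliding-window r^2 pruning.

    Within each window of ``window`` loci (advancing by ``step``), one locus
    of each pair with squared correlation > ``r2_max`` is removed (the later
    one in genome order).
    """
    if r2_max >= 1.0:
        return np.arange(gt.n_loci)
    X = _imputed_centered(gt.dosages)
    keep = np.ones(gt.n_loci, dtype=bool)
    for start in range(0, gt.n_loci, step):
        idx = np.arange(start, min(start + window, gt.n_loci))
        idx = idx[keep[idx]]
        if len(idx) < 2:
            continue
        sub = X[:, idx]
        sd = sub.std(axis=0)
        sd[sd == 0] = np.inf
        R = (sub.T @ sub) / len(sub) / np.outer(sd, sd)
        r2 = R ** 2
        for i in range(len(idx)):
            if not keep[idx[i]]:
                continue
            drop = np.flatnonzero(r2[i, i + 1:] > r2_max) + i + 1
            keep[idx[drop]] = False
    return np.flatnonzero(keep)


def pca_genotypes(gt: GenotypeTable, ld_prune_params: dict | None = None,
                  exclude_regions: list | None = None, n_components: int = 10,
                  standardize: bool = False):
    """PCA of mean-imputed, centered dosages.

    ``exclude_regions`` is a list of (chrom, start, end) half-open intervals
    removed before pruning (inversions, typically).  Returns (scores,
    explained variance fractions, kept locus indices).
    """
    keep = np.ones(gt.n_loci, dtype=bool)
    if exclude_regions:
        chrom = gt.loci["chrom"].to_numpy()
        pos = gt.loci["pos"].to_numpy()
        for c, s, e in exclude_regions:
            keep &= ~((chrom == c) & (pos >= s) & (pos < e))
    sub = gt.subset_loci(keep)
    kept = np.flatnonzero(keep)
    if ld_prune_params is not None:
        pruned = ld_prune(sub, **ld_prune_params)
        sub = sub.subset_loci(pruned)
        kept = kept[pruned]
    if sub.n_loci < 2 or sub.n_samples < 2:
        raise ValueError("fewer than 2 loci (or samples) left for PCA")
    from sklearn.decomposition import PCA

    X = _imputed_centered(sub.dosages, standardize=standardize)
    k = min(n_components, min(X.shape) - 1)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_ratio_, kept


@dataclass
class InversionCall:
    sample_id: str
    region: str
    genotype: str            # "ancestral-hom" | "heterozygous" | "derived-hom"
    axis_score: float
    low_confidence: bool = False


def genotype_inversion(gt: GenotypeTable, region, *, ancestral_samples=None,
                       seed: int = 0) -> list[InversionCall]:
    """Assign inversion genotypes by clustering first-axis local-PCA scores.

    ``region`` is (chrom, start, end), half-open.  Samples fall into three
    clusters along the first principal axis of the region's genotypes; the
    middle cluster is heterozygous and the extremes are the two homozygote
    classes.  Orientation (which extreme is ancestral) is fixed by
    ``ancestral_samples`` when given, else the larger cluster is called
    ancestral.  Fewer than three occupied clusters flags the call set
    low-confidence.
    """
    chrom, start, end = region
    mask = ((gt.loci["chrom"] == chrom) & (gt.loci["pos"] >= start)
            & (gt.loci["pos"] < end)).to_numpy()
    if mask.sum() < 10:
        raise ValueError("region contains fewer than 10 loci")
    sub = gt.subset_loci(mask)
    scores, _, _ = pca_genotypes(sub, n_components=1)
    axis = scores[:, 0]

    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=3, n_init=10, random_state=seed).fit(axis[:, None])
    centers = km.cluster_centers_.ravel()
    order = np.argsort(centers)
    rank_of = np.empty(3, dtype=int)
    rank_of[order] = np.arange(3)
    ranks = rank_of[km.labels_]          # 0 = low extreme, 1 = middle, 2 = high

    occupied = len(np.unique(km.labels_))
    low_conf = occupied < 3

    ids = gt.samples["sample_id"].astype(str).to_numpy()
    if ancestral_samples is not None:
        anc_mask = np.isin(ids, list(ancestral_samples))
        anc_rank = (0 if np.mean(ranks[anc_mask]) < 1 else 2) if anc_mask.any() else 0
    else:
        anc_rank = 0 if np.sum(ranks == 0) >= np.sum(ranks == 2) else 2
    names = {1: "heterozygous"}
    names[anc_rank] = "ancestral-hom"
    names[2 - anc_rank] = "derived-hom"

    label = f"{chrom}:{start}-{end}"
    return [InversionCall(sample_id=ids[i], region=label,
                          genotype=names[int(ranks[i])],
                          axis_score=float(axis[i]), low_confidence=low_conf)
            for i in range(len(ids))]


def ancestry_paint(gt: GenotypeTable, region, ref_group_a, ref_group_b,
                   fixity: float = 0.8, max_missing: float = 0.2) -> pd.DataFrame:
    """Paint focal samples at diagnostic sites within a region.

    Diagnostic sites have an allele-frequency difference >= ``fixity``
    between the two reference sample groups and missingness <= ``max_missing``
    among the references.  Each sample x site cell is labelled ``A``, ``B``,
    ``het`` or ``missing`` according to which reference allele the genotype
    carries.
    """
    if len(ref_group_a) == 0 or len(ref_group_b) == 0:
        raise ValueError("both reference groups must be non-empty")
    chrom, start, end = region
    mask = ((gt.loci["chrom"] == chrom) & (gt.loci["pos"] >= start)
            & (gt.loci["pos"] < end)).to_numpy()
    sub = gt.subset_loci(mask)
    ids = sub.samples["sample_id"].astype(str).to_numpy()
    ia = np.isin(ids, list(ref_group_a))
    ib = np.isin(ids, list(ref_group_b))

    def freq_miss(m):
        d = sub.dosages[m]
        nn = np.sum(~np.isnan(d), axis=0)
        with np.errstate(invalid="ignore"):
            p = np.nansum(d, axis=0) / (2 * nn)
        miss = 1 - nn / m.sum()
        return p, miss

    pa, ma = freq_miss(ia)
    pb, mb = freq_miss(ib)
    with np.errstate(invalid="ignore"):
        diag = (np.abs(pa - pb) >= fixity) & (ma <= max_missing) & (mb <= max_missing)
    diag &= ~np.isnan(pa) & ~np.isnan(pb)
    if diag.sum() == 0:
        raise ValueError("no diagnostic sites in region")

    d = sub.dosages[:, diag]
    a_allele_is_alt = pa[diag] > pb[diag]     # which allele marks ancestry A
    lab = np.full(d.shape, "missing", dtype=object)
    alt_like = np.where(a_allele_is_alt, "A", "B")
    ref_like = np.where(a_allele_is_alt, "B", "A")
    lab[d == 2] = np.broadcast_to(alt_like, d.shape)[d == 2]
    lab[d == 0] = np.broadcast_to(ref_like, d.shape)[d == 0]
    lab[d == 1] = "het"
    out = pd.DataFrame(lab, index=ids,
                       columns=sub.loci.loc[diag, "pos"].astype(int))
    return out


# ---------------------------------------------------------------------------
# Mann-Kendall trend test
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _mahonian_row(n: int) -> np.ndarray:
    """Counts of permutations of 1..n by inversion number (Mahonian)."""
    row = np.array([1], dtype=float)
    for m in range(2, n + 1):
        new = np.convolve(row, np.ones(m))
        row = new
    return row


def _exact_p_no_ties(S: int, n: int):
    """Exact one-/two-sided p for S with distinct values, via the inversion
    distribution: S = n(n-1)/2 - 2*inversions."""
    row = _mahonian_row(n)
    total = row.sum()
    maxs = n * (n - 1) // 2
    inv = np.arange(len(row))
    s_vals = maxs - 2 * inv
    p_ge = row[s_vals >= S].sum() / total
    p_le = row[s_vals <= S].sum() / total
    return p_ge, p_le


def _exact_p_ties(x: np.ndarray):
    """Exact null of S conditioned on the observed tie pattern, by multiset
    permutation enumeration (n <= 8)."""
    from itertools import permutations

    n = len(x)
    seen = {}
    for perm in set(permutations(tuple(x))):
        arr = np.array(perm)
        s = int(np.sign(arr[None, :] - arr[:, None])[np.triu_indices(n, 1)].sum())
        seen[perm] = s
    svals = np.array(list(seen.values()))
    return svals


def mann_kendall(series, *, n_exact: int = 10) -> TrendTestResult:
    """Mann-Kendall test for monotonic trend.

    S = sum over i<j of sign(x_j - x_i).  The null distribution of S is
    exact for small series (full enumeration; with ties, conditional on the
    observed tie pattern, n <= 8), otherwise a normal approximation with
    tie-corrected variance and continuity correction.  The one-sided p is
    taken in the direction of the observed S.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 values")
    sgn = np.sign(x[None, :] - x[:, None])
    S = int(sgn[np.triu_indices(n, 1)].sum())
    direction = "increasing" if S > 0 else "decreasing" if S < 0 else "none"
    if S == 0 and np.all(x == x[0]):
        return TrendTestResult(S=0, n=n, p_one_sided=1.0, p_two_sided=1.0,
                               direction="none", method="exact")

    has_ties = len(np.unique(x)) < n
    if not has_ties and n <= n_exact:
        p_ge, p_le = _exact_p_no_ties(S, n)
        p_one = p_ge if S >= 0 else p_le
        p_two = min(1.0, 2 * min(p_ge, p_le))
        method = "exact"
    elif has_ties and n <= 8:
        svals = _exact_p_ties(x)
        p_ge = np.mean(svals >= S)
        p_le = np.mean(svals <= S)
        p_one = p_ge if S >= 0 else p_le
        p_two = min(1.0, 2 * min(p_ge, p_le))
        method = "exact"
    else:
        _, counts = np.unique(x, return_counts=True)
        var = (n * (n - 1) * (2 * n + 5)
               - np.sum(counts * (counts - 1) * (2 * counts + 5))) / 18.0
        if var == 0:
            return TrendTestResult(S=S, n=n, p_one_sided=1.0, p_two_sided=1.0,
                                   direction=direction, method="normal")
        z = (S - np.sign(S)) / np.sqrt(var)
        p_one = float(stats.norm.sf(abs(z)))
        p_two = min(1.0, 2 * p_one)
        method = "normal"
    return TrendTestResult(S=S, n=n, p_one_sided=float(p_one),
                           p_two_sided=float(p_two), direction=direction,
                           method=method)
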