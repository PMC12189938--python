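import numpy as np
import pandas as pd
import pytest

from fiescan.containers import GenotypeTable


@pytest.fixture
def small_genotypes():
    """3 time points x 4 samples, 6 loci on one chromosome, with missing."""
    rng = np.random.default_rng(11)
    d = rng.integers(0, 3, size=(12, 6)).astype(float)
    d[0, 0] = np.nan
    d[5, 3] = np.nan
    loci = pd.DataFrame({
        "chrom": "LG1",
        "pos": [100, 2_000, 15_000, 30_000, 44_000, 59_000],
        "ref": list("ACGTAC"),
        "alt": list("GTACGT"),
    })
    samples = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(12)],
        "time_index": np.repeat([0, 1, 2], 4),
        "year_label": np.repeat(["1996", "2008", "2019"], 4),
        "sex": ["F", "M"] * 6,
    })
    return GenotypeTable(d, loci, samples)


@pytest.fixture
def two_pop_table():
    """Deterministic 2-population dosage fixture for Fst checks."""
    d = np.array([
        [0, 1, 2, 0, 1],
        [0, 0, 2, 1, 1],
        [1, 0, 2, 0, 0],
        [2, 2, 0, 1, 1],
        [2, 1, 0, 2, 1],
        [1, 2, 0, 2, 2],
    ], dtype=float)
    labels = np.array(["a"] * 3 + ["b"] * 3)
    return d, labels


def wc_fst_oracle(dosages, labels):
    """Literal scalar transcription of the 1984 two-level variance
    components from genotype counts; independent of the library path."""
    labels = np.asarray(labels)
    pops = sorted(set(labels))
    r = len(pops)
    n_i, p_i, h_i = [], [], []
    for pop in pops:
        d = np.asarray(dosages, float)[labels == pop]
        d = d[~np.isnan(d)]
        if len(d) == 0:
            return 0.0, 0.0, 0.0, False
        n_i.append(float(len(d)))
        p_i.append(float(sum(d)) / (2 * len(d)))
        h_i.append(float(np.sum(d == 1)) / len(d))
    nbar = sum(n_i) / r
    pbar = sum(n * p for n, p in zip(n_i, p_i)) / (r * nbar)
    if pbar == 0 or pbar == 1:
        return 0.0, 0.0, 0.0, False
    nc = (r * nbar - sum(n * n for n in n_i) / (r * nbar)) / (r - 1)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(n_i, h_i)) / (r * nbar)
    a = (nbar / nc) * (s2 - 1.0 / (nbar - 1)
                       * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c, True
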