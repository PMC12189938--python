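"""Shared in-memory containers for the pipeline.

Genotypes are held as a dense diploid dosage matrix (samples x loci) with
``numpy.nan`` marking missing calls, alongside pandas frames of locus and
sample metadata.  Allele frequencies per sampling time live in
:class:`FreqMatrix`.  Both are deliberately thin: every statistic in the
package operates on the raw arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeTable", "FreqMatrix"]


@dataclass
class GenotypeTable:
    """Diploid dosages with locus and sample metadata.

    Parameters
    ----------
    dosages
        Float array of shape (n_samples, n_loci) with values in {0, 1, 2}
        or ``nan`` for missing genotypes (alternate-allele counts).
    loci
        DataFrame with columns ``chrom``, ``pos`` (1-based), ``ref``, ``alt``.
        Positions must be sorted within each chromosome.
    samples
        DataFrame with at least ``sample_id``; typically also ``time_index``,
        ``year_label`` and ``sex``.
    """

    dosages: np.ndarray
    loci: pd.DataFrame = field(repr=False)
    samples: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x loci)")
        if self.dosages.shape[0] != len(self.samples):
            raise ValueError("sample metadata length mismatch")
        if self.dosages.shape[1] != len(self.loci):
            raise ValueError("locus metadata length mismatch")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and (np.any(vals < 0) | np.any(vals > 2) | np.any(vals != np.round(vals))):
            raise ValueError("dosages must be in {0, 1, 2} or nan")
        for _, sub in self.loci.groupby("chrom", sort=False):
            if not np.all(np.diff(sub["pos"].to_numpy()) >= 0):
                raise ValueError("locus positions must be sorted within chromosome")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    def subset_samples(self, mask) -> "GenotypeTable":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypeTable(
            self.dosages[idx],
            self.loci.reset_index(drop=True),
            self.samples.iloc[idx].reset_index(drop=True),
        )

    def subset_loci(self, mask) -> "GenotypeTable":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypeTable(
            self.dosages[:, idx],
            self.loci.iloc[idx].reset_index(drop=True),
            self.samples.reset_index(drop=True),
        )


@dataclass
class FreqMatrix:
    """Alternate-allele frequencies per time point per locus.

    ``p[t, l]`` is defined only where ``n[t, l] > 0`` (non-missing diploid
    count); elsewhere it is ``nan``.  ``times`` carries the ordered time
    labels, ``loci`` the locus metadata in genome order.
    """

    p: np.ndarray
    n: np.ndarray
    times: list
    loci: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if self.p.shape != self.n.shape:
            raise ValueError("p and n shape mismatch")
        if self.p.shape[0] != len(self.times):
            raise ValueError("time label length mismatch")
        ok = ~np.isnan(self.p)
        if np.any((self.p[ok] < 0) | (self.p[ok] > 1)):
            raise ValueError("frequencies must lie in [0, 1]")

    @property
    def n_times(self) -> int:
        return self.p.shape[0]

    @property
    def n_loci(self) -> int:
        return self.p.shape[1]
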