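"""Reading and writing the pipeline's on-disk formats.

Genotypes travel as minimal VCF 4.2 (GT-only FORMAT, ``./.`` for missing),
sample metadata and otolith profiles as CSV, and simulation truth as JSON.
VCF parsing uses cyvcf2; writing emits the minimal text directly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeTable

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(gt: GenotypeTable, path) -> None:
    """Write a GenotypeTable as minimal VCF 4.2 (biallelic SNPs, GT only)."""
    path = Path(path)
    samples = gt.samples["sample_id"].astype(str).tolist()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(gt.loci["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        chroms = gt.loci["chrom"].to_numpy()
        poss = gt.loci["pos"].to_numpy()
        refs = gt.loci["ref"].to_numpy()
        alts = gt.loci["alt"].to_numpy()
        dos = gt.dosages
        for j in range(gt.n_loci):
            col = dos[:, j]
            gts = "\t".join("./." if np.isnan(d) else _GT_CODE[int(d)] for d in col)
            fh.write(f"{chroms[j]}\t{int(poss[j])}\t.\t{refs[j]}\t{alts[j]}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path, samples: pd.DataFrame | None = None) -> GenotypeTable:
    """Read a VCF into a GenotypeTable.

    Multiallelic records raise; sample metadata is joined by ``sample_id``
    when provided (rows reordered to VCF sample order), otherwise a bare
    metadata frame is constructed.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    names = list(vcf.samples)
    rows = []
    meta = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(f"multiallelic record at {rec.CHROM}:{rec.POS}")
        g = rec.gt_types.astype(float)  # 0,1,2, 3=missing under gts012
        g[g == 3] = np.nan
        rows.append(g)
        meta.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
    vcf.close()
    loci = pd.DataFrame(meta, columns=["chrom", "pos", "ref", "alt"])
    dosages = np.array(rows, dtype=float).T if rows else np.empty((len(names), 0))
    if samples is None:
        samples = pd.DataFrame({"sample_id": names})
    else:
        missing = set(names) - set(samples["sample_id"].astype(str))
        if missing:
            raise ValueError(f"samples in VCF absent from metadata: {sorted(missing)}")
        samples = samples.set_index(samples["sample_id"].astype(str)).loc[names].reset_index(drop=True)
    return GenotypeTable(dosages, loci, samples)


def write_sample_metadata(samples: pd.DataFrame, path) -> None:
    cols = [c for c in ["sample_id", "time_index", "year_label", "sex"] if c in samples.columns]
    samples[cols].to_csv(path, index=False)


def read_sample_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_profile_csv(profile, path) -> None:
    """Write an otolith element profile (distance_um, mg_ca, p_ca)."""
    pd.DataFrame(
        {"distance_um": profile.distances, "mg_ca": profile.mg_ca, "p_ca": profile.p_ca}
    ).to_csv(path, index=False)


def read_profile_csv(path, fish_id: str | None = None, edge_radius: float | None = None,
                     catch_quarter: int = 3):
    from .aging import OtolithProfile

    df = pd.read_csv(path)
    d = df["distance_um"].to_numpy(float)
    if edge_radius is None:
        edge_radius = float(d[-1])
    return OtolithProfile(
        fish_id=fish_id or Path(path).stem,
        distances=d,
        mg_ca=df["mg_ca"].to_numpy(float),
        p_ca=df["p_ca"].to_numpy(float),
        edge_radius=edge_radius,
        catch_quarter=catch_quarter,
    )


class _NumpyJSON(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_truth_json(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, cls=_NumpyJSON, indent=1)


def read_truth_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
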