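"""End-to-end synthetic study orchestration.

``run_pipeline`` executes the enabled stages in dependency order on one
seeded synthetic world: genotypes under polygenic size-selective mortality
(or neutral drift), otolith profiles and annuli for a growth cohort, then
chemical aging, hierarchical growth fitting, temporal covariance, the
windowed Fst scan and the GWA-overlap chain.  Each stage writes its tables
under the output directory and contributes to a machine-readable
:class:`RunReport`.  A single global seed fans out to per-stage independent
substreams, so toggling one stage does not change another's randomness.

In the synthetic world the selection simulator's individual trait plays the
role of the growth performance index as the association phenotype; the
growth stages demonstrate the phenotype branch (profiles -> ages -> Phi) on
the same fish identifiers.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import aging, growth, gwa, scan, simulate, temporal, vcfio

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "validate_inputs"]

_STAGES = ("simulate", "age", "growth", "covariance", "scan", "gwa_overlap")


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in _STAGES})
    # simulate
    n_loci: int = 2000
    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    selection: simulate.SelectionConfig | None = field(default_factory=simulate.SelectionConfig)
    n_fish_per_group: int = 10
    group_params: list = field(default_factory=lambda: [
        (3.0, 0.25, -0.1), (2.6, 0.30, -0.1), (2.2, 0.35, -0.1),
        (1.9, 0.40, -0.1), (1.6, 0.50, -0.1)])
    profile_step_um: float = 5.0
    profile_noise_sd: float = 0.15
    cohort_age_range: tuple = (3, 6)
    # age reading (keyword overrides for aging.AgingParams; the narrower
    # span suits the 5-um sampling of these small otoliths)
    aging_params: dict = field(default_factory=lambda: {"span": 0.05})
    # growth
    mcmc_preset: str = "test"
    # covariance
    lags: tuple = (2, 3)
    bootstrap_B: int = 1000
    perm_B: int = 1000
    # scan / overlap
    fst_window_bp: int = 20_000
    gwa_tail: float = 0.005
    fst_top: float = 0.05
    overlap_B: int = 1000

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        import dataclasses

        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "out_dir" not in d:
            raise ValueError("missing config keys: ['out_dir']")
        d = dict(d)
        if isinstance(d.get("sim"), dict):
            d["sim"] = simulate.SimConfig(**d["sim"])
        if isinstance(d.get("selection"), dict):
            d["selection"] = simulate.SelectionConfig(**d["selection"])
        cfg = cls(**d)
        bad = set(cfg.stages) - set(_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        return cfg


@dataclass
class RunReport:
    seed: int
    stages: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        s = json.dumps({"seed": self.seed, "stages": self.stages},
                       cls=vcfio._NumpyJSON, indent=1)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, s: str) -> "RunReport":
        d = json.loads(s)
        return cls(seed=d["seed"], stages=d["stages"])


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig | dict) -> RunReport:
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_seed = {s: np.random.SeedSequence([config.seed, i]).generate_state(1)[0] % (2 ** 31)
                  for i, s in enumerate(_STAGES)}
    report = RunReport(seed=config.seed)
    enabled = {s: config.stages.get(s, False) for s in _STAGES}

    def stage_record(name, t0, inputs, params, outputs):
        report.stages[name] = {
            "status": "ok",
            "wall_time_s": round(time.time() - t0, 3),
            "input_hashes": {k: _sha256(v) for k, v in inputs.items()},
            "params": params,
            "outputs": outputs,
        }

    # dependency checks
    if enabled["age"] and not enabled["simulate"] and not (out / "profiles").exists():
        raise ValueError("stage 'age' needs profiles from 'simulate'")
    if enabled["growth"] and not enabled["age"] and not (out / "ages.csv").exists():
        raise ValueError("stage 'growth' needs ages from 'age'")
    if enabled["gwa_overlap"]:
        if not enabled["simulate"] and not (out / "genotypes.vcf").exists():
            raise ValueError("stage 'gwa_overlap' needs genotypes from 'simulate'")
        if not enabled["scan"] and not (out / "fst_windows.tsv").exists():
            raise ValueError("stage 'gwa_overlap' needs Fst windows from 'scan'")
    if (enabled["covariance"] or enabled["scan"]) and not enabled["simulate"] \
            and not (out / "genotypes.vcf").exists():
        raise ValueError("covariance/scan stages need genotypes from 'simulate'")

    truth = None
    if enabled["simulate"]:
        t0 = time.time()
        rng_seed = int(stage_seed["simulate"])
        if config.selection is not None:
            res = simulate.simulate_polygenic_selection(
                config.sim, config.selection, config.n_loci, seed=rng_seed)
        else:
            res = simulate.simulate_wright_fisher(config.sim, config.n_loci, seed=rng_seed)
        vcfio.write_vcf(res.genotypes, out / "genotypes.vcf")
        vcfio.write_sample_metadata(res.genotypes.samples, out / "samples.csv")
        res.genotypes.samples.to_csv(out / "samples_full.csv", index=False)
        truth = res.truth
        vcfio.write_truth_json({
            "causal_loci": getattr(truth, "causal_loci", None),
            "effect_sizes": getattr(truth, "effect_sizes", None),
            "sample_generations": truth.sample_generations,
        }, out / "truth.json")

        prof_dir = out / "profiles"
        prof_dir.mkdir(exist_ok=True)
        obs, gtruth = simulate.simulate_growth_cohort(
            config.group_params, config.n_fish_per_group, 0.05, 0.02,
            seed=rng_seed + 1, age_range=tuple(config.cohort_age_range))
        obs.to_csv(out / "annuli_true.csv", index=False)
        prof_rng = np.random.default_rng(rng_seed + 2)
        prof_meta = []
        for fish_id, info in gtruth.growth_params["fish"].items():
            age = info["age"]
            profile, ptruth = simulate.simulate_otolith_profile(
                age, 0.0, config.profile_step_um, config.profile_noise_sd,
                seed=int(prof_rng.integers(2 ** 31)),
                growth_params=(info["linf"] * 1000, info["k"], info["t0"]))
            profile.fish_id = fish_id
            vcfio.write_profile_csv(profile, prof_dir / f"{fish_id}.csv")
            prof_meta.append((fish_id, info["group"], age, profile.edge_radius,
                              profile.catch_quarter))
        pd.DataFrame(prof_meta, columns=["fish_id", "group_id", "true_age",
                                         "edge_radius", "catch_quarter"]
                     ).to_csv(out / "profile_meta.csv", index=False)
        stage_record("simulate", t0, {}, {
            "n_loci": config.n_loci, "seed": rng_seed,
            "selection": None if config.selection is None else asdict(
                config.selection) | {"effect_sizes": None},
        }, {"vcf": str(out / "genotypes.vcf"), "n_profiles": len(prof_meta)})

    if enabled["age"]:
        t0 = time.time()
        meta = pd.read_csv(out / "profile_meta.csv")
        aparams = aging.AgingParams(**config.aging_params)
        rows = []
        for _, m in meta.iterrows():
            prof = vcfio.read_profile_csv(out / "profiles" / f"{m.fish_id}.csv",
                                          fish_id=m.fish_id,
                                          edge_radius=m.edge_radius,
                                          catch_quarter=int(m.catch_quarter))
            res = aging.estimate_age(prof, aparams)
            radii = ";".join(f"{r:.1f}" for r in res.minima_radii)
            rows.append((m.fish_id, m.group_id, res.age, res.consensus_flag, radii))
        ages = pd.DataFrame(rows, columns=["fish_id", "group_id", "age", "flag", "radii_um"])
        ages.to_csv(out / "ages.csv", index=False)
        acc = float(np.mean(ages["age"].to_numpy() == meta["true_age"].to_numpy()))
        stage_record("age", t0, {"profile_meta": out / "profile_meta.csv"},
                     {}, {"ages_csv": str(out / "ages.csv"), "exact_age_rate": acc})

    if enabled["growth"]:
        t0 = time.time()
        ages = pd.read_csv(out / "ages.csv")
        rows = []
        for _, r in ages.iterrows():
            if not isinstance(r.radii_um, str) or not r.radii_um:
                continue
            for ta, la in enumerate(str(r.radii_um).split(";"), start=1):
                rows.append((r.fish_id, r.group_id, ta, float(la) / 1000.0))
        obs = pd.DataFrame(rows, columns=["fish_id", "group_id", "ta", "La"])
        post = growth.fit_hierarchical_vbgf(obs, config.mcmc_preset,
                                            seed=int(stage_seed["growth"]))
        post.summary().to_csv(out / "growth_posterior.csv", index=False)
        linf_f = post.fish_median("linf_fish")
        k_f = post.fish_median("k_fish")
        phi = growth.growth_performance_index(linf_f, k_f)
        pd.DataFrame({"fish_id": post.fish_ids, "phi": phi}).to_csv(
            out / "phi.csv", index=False)
        with open(out / "growth_diagnostics.json", "w") as fh:
            json.dump({"rhat": post.rhat, "ess": post.ess}, fh, indent=1)
        stage_record("growth", t0, {"ages": out / "ages.csv"},
                     {"preset": config.mcmc_preset},
                     {"median_rhat": float(np.median(list(post.rhat.values()))),
                      "phi_csv": str(out / "phi.csv")})

    gt = None
    if enabled["covariance"] or enabled["scan"] or enabled["gwa_overlap"]:
        samples = pd.read_csv(out / "samples_full.csv")
        gt = vcfio.read_vcf(out / "genotypes.vcf", samples=samples)
        if truth is None and (out / "truth.json").exists():
            t = vcfio.read_truth_json(out / "truth.json")
            truth = simulate.TruthRecord(
                causal_loci=None if t.get("causal_loci") is None
                else np.asarray(t["causal_loci"]),
                effect_sizes=None if t.get("effect_sizes") is None
                else np.asarray(t["effect_sizes"]),
                sample_generations=np.asarray(t["sample_generations"]))

    if enabled["covariance"]:
        t0 = time.time()
        freqs = temporal.allele_frequencies(gt)
        rows = []
        for lag in config.lags:
            for cs in temporal.lag_autocovariances(freqs, lag):
                rows.append((cs.pair, cs.lag, cs.value, cs.n_loci))
        cov_df = pd.DataFrame(rows, columns=["pair", "lag", "value", "n_loci"])
        cov_df.to_csv(out / "covariances.csv", index=False)
        perm = None
        if truth is not None and truth.causal_loci is not None:
            order = np.lexsort((gt.loci["pos"].to_numpy(), gt.loci["chrom"].to_numpy()))
            focal = np.flatnonzero(np.isin(order, truth.causal_loci))
            perm = temporal.subset_permutation_test(
                freqs, focal, lag=2, B=config.perm_B,
                seed=int(stage_seed["covariance"]))
            with open(out / "covariance_permutation.json", "w") as fh:
                json.dump({"observed": perm.observed, "B": perm.B,
                           "p_emp": perm.p_emp}, fh, indent=1)
        stage_record("covariance", t0, {"vcf": out / "genotypes.vcf"},
                     {"lags": list(config.lags), "perm_B": config.perm_B},
                     {"covariances": rows,
                      "perm_p_emp": None if perm is None else perm.p_emp})

    fst_df = None
    if enabled["scan"]:
        t0 = time.time()
        tmin, tmax = gt.samples["time_index"].min(), gt.samples["time_index"].max()
        pair = gt.subset_samples(gt.samples["time_index"].isin([tmin, tmax]).to_numpy())
        fst_df = scan.fst_windows(pair, pair.samples["time_index"].to_numpy(),
                                  window_bp=config.fst_window_bp)
        fst_df.to_csv(out / "fst_windows.tsv", sep="\t", index=False)
        tot = fst_df[["sum_a", "sum_b", "sum_c"]].sum()
        genome_fst = float(tot["sum_a"] / (tot["sum_a"] + tot["sum_b"] + tot["sum_c"]))
        stage_record("scan", t0, {"vcf": out / "genotypes.vcf"},
                     {"window_bp": config.fst_window_bp},
                     {"genome_fst_weighted": genome_fst,
                      "n_windows": int(len(fst_df))})

    if enabled["gwa_overlap"]:
        t0 = time.time()
        if "trait" not in gt.samples.columns:
            raise ValueError("gwa stage needs per-sample trait values "
                             "(selection simulation)")
        if fst_df is None:
            fst_df = pd.read_csv(out / "fst_windows.tsv", sep="\t")
        y = gt.samples["trait"].to_numpy(dtype=float)
        sex = (gt.samples["sex"] == "M").to_numpy(dtype=float)
        K = gwa.kinship_matrix(gt, maf_min=0.01)
        assoc = gwa.lmm_assoc_scan(gt, y, covariates=sex, K=K,
                                   maf_min=0.05, max_missing=0.1)
        assoc.to_csv(out / "assoc.tsv", sep="\t", index=False)
        outliers, thr = gwa.select_gwa_outliers(assoc, tail=config.gwa_tail)
        win = gwa.select_fst_outlier_windows(fst_df, top=config.fst_top)
        observed = gwa.count_overlaps(outliers, win)
        res = gwa.overlap_randomization_test(
            assoc, win, n_draw=len(outliers), B=config.overlap_B,
            seed=int(stage_seed["gwa_overlap"]), observed=observed)
        with open(out / "overlap.json", "w") as fh:
            json.dump({"observed": res.observed, "B": res.B,
                       "p_emp": res.p_emp,
                       "null_mean": float(res.null_values.mean())}, fh, indent=1)
        stage_record("gwa_overlap", t0,
                     {"vcf": out / "genotypes.vcf"},
                     {"tail": config.gwa_tail, "top": config.fst_top,
                      "B": config.overlap_B},
                     {"lambda_gc": gwa.genomic_inflation(assoc["wald_p"]),
                      "n_outliers": int(len(outliers)),
                      "observed_overlap": res.observed,
                      "p_emp": res.p_emp})

    report.to_json(out / "run_report.json")
    return report


def validate_inputs(paths: dict) -> list[str]:
    """Diagnostic checks on pipeline inputs; returns findings, mutates
    nothing.

    Checks: VCF records biallelic and diploid, VCF samples all present in
    the metadata CSV, otolith profile distances strictly increasing.
    """
    findings = []
    if "vcf" in paths:
        from cyvcf2 import VCF

        vcf = VCF(str(paths["vcf"]))
        names = list(vcf.samples)
        for rec in vcf:
            if len(rec.ALT) != 1:
                findings.append(f"multiallelic record at {rec.CHROM}:{rec.POS}")
            gts = rec.genotypes
            if any(len(g) != 3 for g in gts):   # [a, b, phased]
                findings.append(f"non-diploid genotype at {rec.CHROM}:{rec.POS}")
        vcf.close()
        if "metadata" in paths:
            meta = pd.read_csv(paths["metadata"])
            missing = set(names) - set(meta["sample_id"].astype(str))
            for m in sorted(missing):
                findings.append(f"sample in VCF absent from metadata: {m}")
    if "profiles" in paths:
        for p in sorted(Path(paths["profiles"]).glob("*.csv")):
            df = pd.read_csv(p)
            if np.any(np.diff(df["distance_um"].to_numpy()) <= 0):
                findings.append(f"profile distances not strictly increasing: {p.name}")
    return findings
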