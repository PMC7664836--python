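"""End-to-end orchestration: one config in, a reproducible report bundle out.

Stages run in the order of the underlying laboratory-to-analysis flow:
genotype acquisition (simulation or EIGENSTRAT input), QC and sex typing,
kinship, PCA projection, f-statistic scans, qpAdm model search, admixture
dating, and phenotype-SNP frequencies.  All randomness derives from one
global seed fanned out into per-stage streams, so stages are individually
reproducible.  Outputs are tab-separated tables plus a JSON run manifest.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, admixdate, fstats, kinship, pca, qc, qpadm, simulate, snpfreq
from .genodata import read_eigenstrat
from .study import make_study, _stage_rng


@dataclass
class PipelineConfig:
    output_dir: str
    seed: int = 0
    simulation: dict | None = None  # n_snps, ref_n, target{...}
    inputs: dict | None = None  # geno/snp/ind paths
    thresholds: dict = field(default_factory=lambda: {
        "min_endogenous_pct": 0.1,
        "min_snps": 10_000,
        "max_contamination_pct": 5.0,
        "p_value": 0.05,
    })
    models: list = field(default_factory=list)  # [[source, source], ...]
    dating: dict | None = None  # {refA, refB}

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError("config must provide exactly one of simulation / inputs")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns the manifest dict.

    On a synthetic config the planted truths (kin pair, mixture
    proportions, admixture time) travel through the report so recovery can
    be checked downstream.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": config.thresholds,
        "stages": [],
    }

    def log_stage(name, started):
        manifest["stages"].append({"stage": name, "seconds": round(time.time() - started, 2)})

    # --- stage 1: data -----------------------------------------------------
    t = time.time()
    if config.simulation is not None:
        study = make_study(seed=config.seed, **{
            k: v for k, v in config.simulation.items()
            if k in ("n_snps", "ref_n", "ref_missing", "target")
        })
        dataset = study.combined()
        manifest["truth"] = {
            "sources": study.sources,
            "proportions": study.proportions,
            "generations": study.generations,
        }
    else:
        study = None
        dataset = read_eigenstrat(
            config.inputs["geno"], config.inputs["snp"], config.inputs["ind"]
        )
    log_stage("data", t)

    # --- stage 2: QC, sex, screening --------------------------------------
    t = time.time()
    rng = _stage_rng(config.seed, 10)
    reports = []
    sex_rows = []
    n_covered = (dataset.calls != 9).sum(axis=0)
    for j, ind in enumerate(dataset.individuals):
        if study is not None:
            truth_sex = ind.genetic_sex if ind.genetic_sex in "MF" else ("M" if rng.random() < 0.5 else "F")
            cov = simulate.simulate_sex_coverage(truth_sex, 1.0, rng)
            call = qc.assign_genetic_sex(cov["x_ratio"], cov["y_ratio"])
            ind.genetic_sex = call.call
            sex_rows.append((ind.individual_id, truth_sex, cov["x_ratio"], cov["y_ratio"], call.call))
            endogenous = float(np.round(rng.uniform(1.0, 60.0), 2))
            contam = float(np.round(rng.uniform(0.1, 2.0), 2))
        else:
            call = None
            endogenous, contam = None, None
        reports.append(
            qc.screen_individual(
                ind.individual_id,
                endogenous_pct=endogenous,
                n_snps_covered=int(n_covered[j]),
                mt_contamination_pct=contam,
                genetic_sex=ind.genetic_sex,
                thresholds=qc.ScreenThresholds(
                    config.thresholds["min_endogenous_pct"],
                    config.thresholds["min_snps"],
                    config.thresholds["max_contamination_pct"],
                ),
            )
        )
    _write(qc.screen_table(reports), out / "screening.tsv")
    if sex_rows:
        _write(
            pd.DataFrame(sex_rows, columns=["individual_id", "true_sex", "x_ratio", "y_ratio", "call"]),
            out / "sex_typing.tsv",
        )
    passed = [r.individual_id for r in reports if r.decision == "pass"]
    log_stage("qc", t)

    # --- stage 3: kinship ---------------------------------------------------
    t = time.time()
    kin = kinship.kinship_table(dataset)
    _write(kin, out / "kinship.tsv")
    log_stage("kinship", t)

    # --- stage 4: PCA -------------------------------------------------------
    t = time.time()
    if study is not None:
        pca_rng = _stage_rng(config.seed, 11)
        ref_rows = []
        ref_inds = []
        for pop in ("WSH", "ANA", "han", "iran"):
            dip = simulate.sample_individuals_from_freqs(
                study.freqs[pop], study.panel, 20, f"modern_{pop}", pca_rng
            )
            ref_rows.append(dip.calls)
            ref_inds.extend(dip.individuals)
        modern = type(dataset)(
            study.panel, ref_inds, np.concatenate(ref_rows, axis=1), ploidy_mode="diploid"
        )
        model = pca.fit_pca(modern, k=4, anchor_group="modern_WSH")
        proj = pca.project_dataset(study.target, model, min_snps=min(5000, len(study.panel) // 4))
        _write(proj, out / "pca_projection.tsv")
    log_stage("pca", t)

    # --- stage 5: f-statistics ---------------------------------------------
    t = time.time()
    freqs = fstats.group_frequencies(dataset)
    blocks = fstats.default_block_ids(dataset.panel)
    target_label = "target" if "target" in freqs.groups else dataset.individuals[0].group_label
    outgroup = "african" if "african" in freqs.groups else freqs.groups[-1]
    candidates = [g for g in freqs.groups if g not in (target_label, outgroup)]
    if candidates:
        scan = fstats.outgroup_f3_scan(target_label, candidates, outgroup, freqs, blocks)
        _write(scan, out / "outgroup_f3.tsv")
    log_stage("fstats", t)

    # --- stage 6: qpAdm model search ---------------------------------------
    t = time.time()
    models = config.models or ([["WSH", "ANA"]] if study is not None else [])
    best_summary = None
    if models:
        outgroups = study.outgroups if study is not None else candidates[:8]
        best, table = qpadm.model_search(
            target_label, models, outgroups, freqs,
            p_threshold=config.thresholds["p_value"],
        )
        _write(table, out / "qpadm_models.tsv")
        if best is not None:
            best_summary = best.summary()
            manifest["qpadm"] = {
                "sources": best.sources,
                "weights": [round(float(w), 4) for w in best.weights],
                "se": [round(float(e), 4) for e in best.se],
                "p_value": best.p_value,
            }
    log_stage("qpadm", t)

    # --- stage 7: admixture dating ------------------------------------------
    t = time.time()
    if study is not None:
        refA, refB = (config.dating or {}).get("refA", study.sources[0]), (
            config.dating or {}
        ).get("refB", study.sources[1])
        curve = admixdate.ancestry_covariance(
            study.target, study.freqs[refA], study.freqs[refB]
        )
        fit = admixdate.fit_decay(curve)
        if fit.detectable:
            date_bp, se_date = admixdate.generations_to_years(
                fit.generations, fit.se_generations
            )
            manifest["admixture_date"] = {
                "generations": round(fit.generations, 2),
                "se_generations": round(fit.se_generations, 2),
                "years_before_samples": round(date_bp, 1),
                "se_years": round(se_date, 1),
            }
        d, y = curve.covariance()
        _write(pd.DataFrame({"distance_m": d, "covariance": y}), out / "decay_curve.tsv")
    log_stage("dating", t)

    # --- stage 8: phenotype SNP frequencies ---------------------------------
    t = time.time()
    if study is not None:
        loci_idx = np.linspace(0, len(study.panel) - 1, 5).astype(int)
        loci = pd.DataFrame(
            {
                "snp_id": study.panel.table["snp_id"].iloc[loci_idx].to_list(),
                "rsid": snpfreq.PHENOTYPE_PANEL["rsid"],
                "effect_allele": "alt",
            }
        )
        obs = simulate.simulate_reads(
            study.target_diploid, mean_depth=2.0, seed=_stage_rng(config.seed, 12),
            max_recorded_reads=0,
        )
        grouping = {i: "target" for i in obs.individual_ids}
        freq_table = snpfreq.frequency_table(obs, loci, grouping)
        _write(freq_table, out / "phenotype_frequencies.tsv")
    log_stage("snpfreq", t)

    manifest["n_individuals"] = dataset.n_individuals
    manifest["n_pass_screening"] = len(passed)
    manifest["runtime_seconds"] = round(time.time() - t0, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    with open(out / "summary.txt", "w") as fh:
        fh.write(f"steppeadmix {__version__} run (seed {config.seed})\n")
        fh.write(f"{dataset.n_individuals} individuals, {len(dataset.panel)} SNPs\n")
        fh.write(f"screening passed: {len(passed)}/{dataset.n_individuals}\n")
        if best_summary:
            fh.write(f"best admixture model: {best_summary}\n")
        if "admixture_date" in manifest:
            ad = manifest["admixture_date"]
            fh.write(
                f"admixture dated {ad['generations']} ± {ad['se_generations']} generations "
                f"(~{ad['years_before_samples']} ± {ad['se_years']} years) before sampling\n"
            )
    return manifest
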