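"""End-to-end orchestration: simulate → EWAS → meta → DMR → enrichment →
twins → concordance → scores, with every intermediate written to disk and
a machine- plus human-readable run report."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from twinewas import io as tio
from twinewas.datatypes import DataError, MethylationDataset, ModelSpec
from twinewas.dmr import run_dmr_analysis
from twinewas.enrichment import annotate_proximity, enrichment_test
from twinewas.ewas import residualize, run_ewas
from twinewas.meta import estimate_inflation, meta_fixed_effects, top_k_concordance
from twinewas.scores import (
    build_weight_table, compute_score, evaluate_scores, results_to_frame, WeightTable,
)
from twinewas.simulate import SimConfig, generate_cohort
from twinewas.twins import build_discordant_pairs, within_pair_ewas

logger = logging.getLogger(__name__)

DEFAULT_BASIC_COVARIATES = ["age", "sex", "neut", "lymph", "mono", "eos", "plate", "row"]
DEFAULT_ADJUSTED_EXTRA = ["bmi", "smoking"]
TECHNICAL_COVARIATES = ["neut", "lymph", "mono", "eos", "plate", "row"]


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``from_yaml``)."""

    output_dir: str = "twinewas_out"
    seed: int = 0
    simulate: dict = field(default_factory=dict)  # cohort name -> SimConfig kwargs
    inputs: list = field(default_factory=list)    # cohort dicts with file paths
    basic_covariates: list = field(default_factory=lambda: list(DEFAULT_BASIC_COVARIATES))
    adjusted_extra: list = field(default_factory=lambda: list(DEFAULT_ADJUSTED_EXTRA))
    residual_covariates: list = field(default_factory=lambda: list(TECHNICAL_COVARIATES))
    dmr_p_enter: float = 0.05
    dmr_max_gap: int = 500
    enrichment_window: int = 500_000
    n_boot: int = 2000
    gwas_p_cutoffs: list = field(default_factory=lambda: [1e-8, 1e-6, 1e-5])
    exclude_cpgs_file: str | None = None
    score_thresholds: list = field(default_factory=lambda: [1e-1, 1e-3, 1e-5])
    prevalence_K: float = 0.12
    top_k: int = 100
    n_analyses: int = 13
    stages: list = field(default_factory=lambda: [
        "simulate", "ewas", "meta", "inflation", "dmr", "enrich",
        "twins", "concordance", "score",
    ])

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.simulate and not self.inputs:
            raise DataError("config must provide either 'simulate' or 'inputs'")
        for coh in self.inputs:
            for key in ("beta", "manifest", "samples"):
                if key not in coh:
                    raise DataError(f"input cohort entry lacks {key!r}")
                if not Path(coh[key]).exists():
                    raise DataError(f"input path does not exist: {coh[key]}")
        if self.exclude_cpgs_file and not Path(self.exclude_cpgs_file).exists():
            raise DataError(f"exclusion list not found: {self.exclude_cpgs_file}")


@dataclass
class CohortData:
    name: str
    dataset: MethylationDataset
    estimator: str
    genotypes: pd.DataFrame | None = None
    locus_sets: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)


def _default_sim_cohorts(config: RunConfig) -> dict:
    return {
        "twin": dict(n_samples=1000, n_cpgs=5000, seed=config.seed,
                     cohort_name="twin"),
        "unrelated": dict(
            n_samples=800, n_cpgs=5000, seed=config.seed + 1,
            family_structure={"mz_pairs": 0.0, "dz_pairs": 0.0, "singletons": 1.0},
            cohort_name="unrelated"),
    }


def _load_cohorts(config: RunConfig, outdir: Path, report: dict) -> list:
    cohorts = []
    if config.inputs:
        for coh in config.inputs:
            ds = tio.read_dataset(coh["beta"], coh["manifest"], coh["samples"])
            cohorts.append(CohortData(
                name=coh.get("name", f"cohort{len(cohorts)}"),
                dataset=ds,
                estimator=coh.get("estimator", "ols"),
                genotypes=tio.read_genotypes_tsv(coh["genotypes"]) if coh.get("genotypes") else None,
                locus_sets={
                    name: tio.read_locus_tsv(p)
                    for name, p in coh.get("locus_sets", {}).items()},
            ))
        return cohorts
    spec_map = config.simulate or _default_sim_cohorts(config)
    for name, kwargs in spec_map.items():
        kwargs = dict(kwargs)
        kwargs.setdefault("cohort_name", name)
        kwargs.setdefault("seed", config.seed)
        sim = generate_cohort(SimConfig(**kwargs))
        fs = kwargs.get("family_structure", {})
        has_twins = fs.get("mz_pairs", 0.4) + fs.get("dz_pairs", 0.3) > 0 if fs else True
        cohorts.append(CohortData(
            name=name, dataset=sim.dataset,
            estimator="cluster-exchangeable" if has_twins else "ols",
            genotypes=sim.genotypes, locus_sets=sim.locus_sets, truth=sim.truth,
        ))
        cdir = outdir / f"cohort_{name}"
        cdir.mkdir(parents=True, exist_ok=True)
        tio.write_beta_tsv(sim.dataset.beta, cdir / "beta.tsv")
        tio.write_manifest_csv(sim.dataset.manifest, cdir / "manifest.csv")
        tio.write_samples_csv(sim.dataset.samples, cdir / "samples.csv")
        tio.write_genotypes_tsv(sim.genotypes, cdir / "genotypes.tsv")
        for lname, loci in sim.locus_sets.items():
            tio.write_locus_tsv(loci, cdir / f"loci_{lname}.tsv")
        tio.write_truth_json(sim.truth, cdir / "truth.json")
        report["cohorts"][name] = {
            "n_samples": sim.dataset.n_samples,
            "n_cpgs": sim.dataset.n_cpgs,
            "case_fraction": sim.truth["case_fraction"],
        }
    return cohorts


def _available(covs, dataset) -> list:
    return [c for c in covs if c in dataset.samples.columns
            and dataset.samples[c].nunique(dropna=True) > 1]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the run report dict.

    Any stage failure aborts with the stage name in the exception message;
    outputs written before the failure are retained.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": dataclasses.asdict(config), "cohorts": {}, "stages": {}}
    stage = "setup"
    t_start = time.time()
    try:
        cohorts = _load_cohorts(config, outdir, report)

        summaries: dict = {}
        residuals: dict = {}
        if "ewas" in config.stages:
            stage = "ewas"
            t0 = time.time()
            for coh in cohorts:
                basic = _available(config.basic_covariates, coh.dataset)
                adjusted = basic + _available(config.adjusted_extra, coh.dataset)
                for tag, covs in (("basic", basic), ("adjusted", adjusted)):
                    spec = ModelSpec(covariates=covs, estimator=coh.estimator, tag=tag)
                    summ = run_ewas(coh.dataset, spec, cohort=coh.name)
                    summaries[(coh.name, tag)] = summ
                    tio.write_summary_tsv(summ, outdir / f"ewas_{coh.name}_{tag}.tsv")
                residuals[coh.name] = residualize(
                    coh.dataset, _available(config.residual_covariates, coh.dataset))
            report["stages"]["ewas"] = {
                "analyses": [f"{c}/{t}" for c, t in summaries],
                "wall_s": round(time.time() - t0, 2),
            }

        meta = None
        if "meta" in config.stages and summaries:
            stage = "meta"
            t0 = time.time()
            adj = [summaries[(c.name, "adjusted")] for c in cohorts]
            meta = meta_fixed_effects(adj)
            tio.write_summary_tsv(meta, outdir / "meta_adjusted.tsv")
            report["stages"]["meta"] = {
                "m_cpgs_tested": int(meta.attrs["m_cpgs_tested"]),
                "bonferroni_threshold": meta.attrs["bonferroni_threshold"],
                "n_bonferroni_significant": int(meta["bonferroni_significant"].sum()),
                "n_fdr_significant": int((meta["q"] < 0.05).sum()),
                "wall_s": round(time.time() - t0, 2),
            }

        if "inflation" in config.stages and summaries:
            stage = "inflation"
            infl = {}
            for (name, tag), summ in summaries.items():
                z = summ["z"].to_numpy(dtype=float)
                est = estimate_inflation(z[np.isfinite(z)])
                infl[f"{name}/{tag}"] = {
                    "lambda_gc": est.lambda_gc, "null_mean": est.null_mean,
                    "null_sd": est.null_sd}
            if meta is not None:
                est = estimate_inflation(meta["z"].to_numpy(dtype=float))
                infl["meta/adjusted"] = {
                    "lambda_gc": est.lambda_gc, "null_mean": est.null_mean,
                    "null_sd": est.null_sd}
            report["stages"]["inflation"] = infl

        if "dmr" in config.stages and meta is not None:
            stage = "dmr"
            t0 = time.time()
            result = run_dmr_analysis(
                meta,
                [summaries[(c.name, "adjusted")] for c in cohorts],
                [residuals[c.name] for c in cohorts],
                cohort_names=[c.name for c in cohorts],
                p_enter=config.dmr_p_enter, max_gap=config.dmr_max_gap)
            tio.write_dmr_bed(result.tested_meta, outdir / "dmr_tested.bed")
            tio.write_dmr_csv(result.representatives, outdir / "dmr_representatives.csv")
            report["stages"]["dmr"] = {
                "n_candidates": len(result.candidates),
                "n_regions_tested": result.n_regions_tested,
                "n_regions_evaluated": result.n_regions_evaluated,
                "n_significant": sum(r.p_adjust < 0.05 for r in result.representatives),
                "wall_s": round(time.time() - t0, 2),
            }

        if "enrich" in config.stages and meta is not None:
            stage = "enrich"
            t0 = time.time()
            locus_sets = next((c.locus_sets for c in cohorts if c.locus_sets), {})
            exclude = (tio.read_cpg_list(config.exclude_cpgs_file)
                       if config.exclude_cpgs_file else None)
            enrich_out = []
            manifest_like = meta[["chr", "pos"]]
            for lname, loci in locus_sets.items():
                for cutoff in config.gwas_p_cutoffs:
                    sel = loci[loci["p"] < cutoff]
                    if sel.empty:
                        continue
                    ind = annotate_proximity(manifest_like, sel, config.enrichment_window)
                    if ind.min() == ind.max():
                        continue
                    for excl, mode in ((None, "all"), (exclude, "mqtl-excluded")):
                        if mode == "mqtl-excluded" and excl is None:
                            continue
                        res = enrichment_test(
                            meta, ind, n_boot=config.n_boot, seed=config.seed,
                            exclude=excl, locus_set=f"{lname}@{cutoff:g}/{mode}",
                            window=config.enrichment_window)
                        enrich_out.append(dataclasses.asdict(res))
            pd.DataFrame(enrich_out).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            (outdir / "enrichment.json").write_text(json.dumps(enrich_out, indent=1))
            report["stages"]["enrich"] = {
                "n_tests": len(enrich_out),
                "results": enrich_out,
                "wall_s": round(time.time() - t0, 2),
            }

        within = {}
        if "twins" in config.stages:
            stage = "twins"
            for coh in cohorts:
                if (coh.dataset.samples["zygosity"] == "MZ").sum() < 6:
                    continue
                pairs = build_discordant_pairs(coh.dataset.samples)
                if len(pairs.pairs) < 3:
                    continue
                pairs.pairs.to_csv(outdir / f"pairs_{coh.name}.csv", index=False)
                covs = _available(config.residual_covariates + ["bmi", "smoking"],
                                  coh.dataset)
                # Drop pair-constant covariates (identical in MZ co-twins).
                usable = []
                for cov in covs:
                    lv = coh.dataset.samples.loc[pairs.pairs["left_id"], cov].to_numpy()
                    rv = coh.dataset.samples.loc[pairs.pairs["right_id"], cov].to_numpy()
                    if not np.array_equal(lv, rv):
                        usable.append(cov)
                summ = within_pair_ewas(coh.dataset, pairs, usable, cohort=coh.name)
                within[coh.name] = summ
                tio.write_summary_tsv(summ, outdir / f"within_pair_{coh.name}.tsv")
                report["stages"].setdefault("twins", {})[coh.name] = {
                    "n_mz_complete_pairs": pairs.n_mz_complete,
                    "n_discordant_pairs": pairs.n_discordant,
                    "discordance_fraction": pairs.discordance_fraction,
                }

        if "concordance" in config.stages and summaries:
            stage = "concordance"
            named = {f"{c}/{t}": s for (c, t), s in summaries.items()}
            if meta is not None:
                named["meta/adjusted"] = meta
            named.update({f"{name}/within-pair": s for name, s in within.items()})
            universe = None
            for s in named.values():
                ids = set(s.loc[np.isfinite(s["beta"]), "cpg"])
                universe = ids if universe is None else universe & ids
            universe = sorted(universe)
            k = min(config.top_k, len(universe))
            rows = []
            labels = list(named)
            for la in labels:
                for lb in labels:
                    if la == lb:
                        continue
                    rep = top_k_concordance(
                        named[la], named[lb], k, universe,
                        n_analyses=config.n_analyses, label_a=la, label_b=lb)
                    rows.append(dataclasses.asdict(rep))
            conc = pd.DataFrame(rows)
            conc.to_csv(outdir / "concordance.csv", index=False)
            report["stages"]["concordance"] = {
                "n_pairs": len(rows),
                "k": k,
                "n_universe": len(universe),
                "alpha": 0.05 / (config.n_analyses**2 - config.n_analyses),
            }

        if "score" in config.stages and len(cohorts) >= 2 and summaries:
            stage = "score"
            disc, target = cohorts[0], cohorts[1]
            score_rows = []
            scores = []
            for thr in config.score_thresholds:
                wt = build_weight_table(
                    summaries[(disc.name, "adjusted")], thr, source=disc.name)
                if wt.n_features == 0:
                    continue
                sv = compute_score(target.dataset.beta.T, wt, label=f"MS@{thr:g}")
                scores.append(sv)
            if target.genotypes is not None and target.truth.get("pgs_weights"):
                wt = WeightTable(
                    weights=pd.Series(target.truth["pgs_weights"], dtype=float),
                    source="simulation-truth", threshold=np.nan)
                scores.append(compute_score(target.genotypes, wt, label="PGS"))
            if scores:
                covs = _available(["age", "sex"], target.dataset)
                cov_df = target.dataset.samples[covs]
                y = target.dataset.samples["handedness"].to_numpy(dtype=float)
                pgs_label = "PGS" if any(s.label == "PGS" for s in scores) else None
                results = evaluate_scores(
                    y, scores, cov_df, K=config.prevalence_K, pgs_label=pgs_label)
                frame = results_to_frame(results)
                frame.to_csv(outdir / "score_results.csv", index=False)
                score_rows = frame.to_dict("records")
            report["stages"]["score"] = {
                "n_scores": len(scores),
                "alpha": 0.05 / max(len(scores), 1),
                "results": score_rows,
            }

        report["wall_s_total"] = round(time.time() - t_start, 2)
        (outdir / "report.json").write_text(json.dumps(report, indent=1, default=str))
        (outdir / "report.txt").write_text(_render_report(report))
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _render_report(report: dict) -> str:
    lines = ["twinewas run report", "===================", ""]
    for name, info in report.get("cohorts", {}).items():
        lines.append(
            f"cohort {name}: {info['n_samples']} samples, {info['n_cpgs']} CpGs, "
            f"case fraction {info['case_fraction']:.3f}")
    for sname, sinfo in report.get("stages", {}).items():
        lines.append("")
        lines.append(f"[{sname}]")
        lines.append(json.dumps(sinfo, indent=1, default=str))
    return "\n".join(lines) + "\n"
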