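"""End-to-end orchestration: simulate -> train -> BAG -> association suite.

``run_full`` executes the whole replica pipeline on synthetic cohorts and
writes every result as CSV/JSON under a run directory, together with a
manifest (config, derived seeds, package version) that fully determines the
outputs. Per-stage seeds are derived from the global seed by hashing the
stage name, so a stage re-run in isolation reproduces its piece.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import FitConfig, SimConfig
from .model import (BrainAgeModel, apply_bias_correction, evaluate,
                    fit_bias_correction)
from .outcomes import (assign_tertiles, fit_competing_risk_cox, fit_cox,
                       lsmeans_by_group, phenotype_assoc)
from .pwas import pwas_report, run_pwas
from .simulate import derive_seed, simulate_study
from .volumes import build_mask, vectorize

__all__ = ["RunConfig", "run_full", "describe_cohort"]

COX_COVARIATES = ["age", "center_race", "sex", "smoking", "hypertension",
                  "education", "diabetes", "icv"]
PWAS_COVARIATES = ["age", "sex", "center_race", "smoking", "hypertension",
                   "education", "diabetes", "icv"]
PHENO_COVARIATES = ["age", "sex", "center_race"]
PHENOTYPES = ["bmi", "diabetes", "hypertension", "walk4m", "low_grip",
              "hf", "afib", "chd", "stroke"]


@dataclass
class RunConfig:
    """Everything one full run needs; round-trips losslessly through YAML."""

    sim: SimConfig = field(default_factory=SimConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    mask_threshold: float = 0.1
    alpha: float = 0.05
    pwas_transform: str = "raw"
    bias_fit_cohort: str = "train"        # "train" | "target"
    cox_covariates: list[str] = field(default_factory=lambda: list(COX_COVARIATES))
    pwas_covariates: list[str] = field(default_factory=lambda: list(PWAS_COVARIATES))
    pheno_covariates: list[str] = field(default_factory=lambda: list(PHENO_COVARIATES))
    lsmeans_covariates: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimConfig.from_dict(self.sim)
        if isinstance(self.fit, dict):
            self.fit = FitConfig.from_dict(self.fit)
        if self.bias_fit_cohort not in ("train", "target"):
            raise ValueError("bias_fit_cohort must be 'train' or 'target'")
        # propagate the global seed into sub-configs deterministically
        self.sim = dataclasses.replace(self.sim,
                                       seed=derive_seed(self.seed, "sim"))
        self.fit = dataclasses.replace(self.fit,
                                       seed=derive_seed(self.seed, "fit"))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def describe_cohort(pheno: pd.DataFrame,
                    strata_col: str = "cognitive_status") -> pd.DataFrame:
    """Cohort characteristics table stratified by cognitive status.

    Counts with percentages for categorical variables, mean (SD) for age and
    BMI; columns are Total plus one per stratum, empty strata rendered with
    n = 0.
    """
    strata = ["Total"] + [s for s in ("CN", "MCI", "DEM")
                          if s in set(pheno.get(strata_col, []))]
    subsets = {"Total": pheno}
    for s in strata[1:]:
        subsets[s] = pheno[pheno[strata_col] == s]
    rows = []

    def add(variable, fmt):
        row = {"variable": variable}
        for s in strata:
            sub = subsets[s]
            row[s] = fmt(sub) if len(sub) else "0"
        rows.append(row)

    add("N", lambda d: str(len(d)))
    for var in ("sex", "center_race", "smoking", "education"):
        if var not in pheno.columns:
            continue
        for level in sorted(pheno[var].dropna().unique()):
            add(f"{var}={level}",
                lambda d, v=var, l=level:
                f"{(d[v] == l).sum()} ({100 * (d[v] == l).mean():.1f}%)")
    for var in ("hypertension", "diabetes"):
        if var in pheno.columns:
            add(f"{var}=yes",
                lambda d, v=var: f"{int(d[v].sum())} ({100 * d[v].mean():.1f}%)")
    for var in ("age", "bmi"):
        if var in pheno.columns:
            add(var, lambda d, v=var: f"{d[v].mean():.1f} ({d[v].std():.1f})")
    return pd.DataFrame(rows)


def _write_csv(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, index=kwargs.pop("index", False),
              float_format="%.17g", **kwargs)


def run_full(config: RunConfig, out_dir: str | Path) -> Path:
    """Run every stage and persist results; returns the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        study = simulate_study(config.sim)

        stage = "design"
        mask = build_mask(study.template.data, config.mask_threshold)
        design_train = vectorize(study.train_volumes, mask)
        design_target = vectorize(study.target_volumes, mask)

        stage = "train"
        results = BrainAgeModel(design_train, config=config.fit).fit()
        train_pred = results.fitted_values()
        train_metrics = evaluate(train_pred, design_train.ages)

        stage = "bag"
        target_pred = results.predict(design_target)
        if config.bias_fit_cohort == "train":
            bias = fit_bias_correction(train_pred, design_train.ages)
        else:
            bias = fit_bias_correction(target_pred, design_target.ages)
        bag_table = apply_bias_correction(target_pred, design_target.ages, bias,
                                          design_target.subject_ids)
        target_metrics = evaluate(target_pred, design_target.ages)
        labels, boundaries = assign_tertiles(bag_table["bag"].to_numpy())
        bag_table["tertile"] = labels
        _write_csv(bag_table, out / "bag.csv")

        stage = "outcomes"
        pheno = study.phenotypes.merge(
            bag_table[["subject_id", "bag", "tertile"]], on="subject_id")
        cox_all = fit_cox(pheno, covariates=config.cox_covariates)
        cn = pheno[pheno["cognitive_status"] == "CN"]
        cox_cn = fit_cox(cn, covariates=config.cox_covariates)
        cox_cr = fit_competing_risk_cox(cn, covariates=config.cox_covariates,
                                        event_cause="nonCNS")
        for name, res in (("cox_all", cox_all), ("cox_cn", cox_cn),
                          ("cox_competing", cox_cr)):
            tab = res.table.reset_index(names="term")
            tab["n"] = res.n
            tab["n_events"] = res.n_events
            tab["n_competing"] = res.n_competing
            _write_csv(tab, out / f"{name}.csv")

        pheno["cognitive_status"] = pd.Categorical(
            pheno["cognitive_status"], categories=["CN", "MCI", "DEM"])
        lsm = lsmeans_by_group(pheno, "bag", "cognitive_status",
                               config.lsmeans_covariates)
        _write_csv(lsm.group_table, out / "lsmeans.csv")
        _write_csv(lsm.contrast_table, out / "lsmeans_contrasts.csv")

        assoc = phenotype_assoc(cn, "bag", PHENOTYPES, config.pheno_covariates)
        _write_csv(assoc, out / "phenotype_assoc.csv")

        stage = "pwas"
        bag_series = bag_table.set_index("subject_id")["bag"]
        cov = pheno.set_index("subject_id")[config.pwas_covariates]
        scan_all = run_pwas(bag_series, study.proteins, cov,
                            alpha=config.alpha, transform=config.pwas_transform)
        pwas_report(scan_all, out_dir=out / "pwas_all")
        cn_ids = cn["subject_id"]
        scan_cn = run_pwas(bag_series.loc[cn_ids], study.proteins,
                           cov.loc[cn_ids], alpha=config.alpha,
                           transform=config.pwas_transform)
        pwas_report(scan_cn, out_dir=out / "pwas_cn")

        stage = "report"
        _write_csv(describe_cohort(pheno), out / "table1.csv")
        metrics = {
            "train": dataclasses.asdict(train_metrics),
            "target_raw": dataclasses.asdict(target_metrics),
            "target_corrected": dataclasses.asdict(
                evaluate(bag_table["pred_corrected"], bag_table["age"])),
            "lambda_selected": results.lambda_selected,
            "lambda_per_repeat": results.lambda_per_repeat,
            "n_nonzero_weights": results.n_nonzero,
            "tertile_boundaries": list(boundaries),
        }
        (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "stage_seeds": {s: derive_seed(config.seed, s)
                            for s in ("sim", "fit")},
            "config": config.to_dict(),
            "n_train": study.train_volumes.n_subjects,
            "n_target": study.target_volumes.n_subjects,
            "n_mask_voxels": mask.n_voxels,
            "pwas_m_tested": scan_all.m_tested,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))
        report = "\n\n".join([
            "Synthetic brain-age-gap pipeline run",
            results.summary(),
            f"target cohort: raw r={target_metrics.pearson_r:.3f}, "
            f"corrected MAE={metrics['target_corrected']['mae']:.2f} y; "
            f"tertile cut-points {boundaries[0]:.2f} / {boundaries[1]:.2f} y",
            cox_all.summary(), cox_cn.summary(), cox_cr.summary(),
            lsm.summary(), scan_all.summary(), scan_cn.summary(),
        ])
        (out / "report.txt").write_text(report + "\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out
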