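"""Readers/writers for the declared file formats and the two pipelines.

Formats (all plain text):

* cohort CSV/TSV — header: id, age, bmi, weight_gain, ga_weeks, education,
  gravidity, parity, smoking, alcohol, alt, ast, ggt, alp, tc, tg, ldl_c,
  hdl_c, fbg, pbg1h, pbg2h, hx_flags (semicolon-separated history flags);
* summary statistics TSV — header: rsid, chr, pos, effect_allele,
  other_allele, eaf, beta, se, pval, n;
* LD TSV — rsid_a, rsid_b, r2; exclusion list — one rsid per line.

:func:`run_pipeline` ties the stages into the two analysis arms and writes
a report bundle of TSVs; every number in the bundle is the output of one
library operation (the report layer only formats).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cdom
from . import models, mr
from .models import DEFAULT_COVARIATES

logger = logging.getLogger("gdmliver")

__all__ = [
    "COHORT_COLUMNS",
    "RunConfig",
    "read_sumstats",
    "write_sumstats",
    "read_cohort",
    "write_cohort",
    "read_ld",
    "read_exclusion_list",
    "run_pipeline",
    "run_cohort_arm",
    "run_mr_arm",
]

COHORT_COLUMNS = (
    "id", "age", "bmi", "weight_gain", "ga_weeks", "education", "gravidity",
    "parity", "smoking", "alcohol", "alt", "ast", "ggt", "alp",
    "tc", "tg", "ldl_c", "hdl_c", "fbg", "pbg1h", "pbg2h", "hx_flags",
)

FLOAT_FMT = "%.10g"  # machine-readable outputs keep 10 significant digits


def read_sumstats(path) -> pd.DataFrame:
    """Read and validate a GWAS summary-statistics TSV.

    Rejects the file on a missing column or duplicate rsid; rejects
    individual rows (with a line-numbered log message) on non-positive se,
    out-of-range eaf or pval, or identical alleles.
    """
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "effect_allele": str, "other_allele": str})
    for col in mr.SUMSTATS_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column '{col}'")
    if df["rsid"].duplicated().any():
        dup = df.loc[df["rsid"].duplicated(), "rsid"].iloc[0]
        raise ValueError(f"{path}: duplicate rsid '{dup}'")
    bad = (
        (df["se"] <= 0)
        | (df["eaf"] <= 0) | (df["eaf"] >= 1)
        | (df["pval"] <= 0) | (df["pval"] > 1)
        | (df["effect_allele"].str.upper() == df["other_allele"].str.upper())
        | df[["eaf", "beta", "se", "pval"]].isna().any(axis=1)
    )
    if bad.any():
        for i in df.index[bad]:
            logger.warning("%s: line %d (rsid %s) rejected: invalid field", path, i + 2, df.at[i, "rsid"])
        df = df.loc[~bad].reset_index(drop=True)
    return df


def write_sumstats(df: pd.DataFrame, path) -> None:
    cols = [c for c in ("rsid", "chr", "pos", "effect_allele", "other_allele",
                        "eaf", "beta", "se", "pval", "n") if c in df.columns]
    df.to_csv(path, sep="\t", index=False, columns=cols, float_format=FLOAT_FMT)


def read_cohort(path, sep: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype={"id": str, "hx_flags": str,
                                           "education": str, "smoking": str, "alcohol": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing cohort column(s) {missing}")
    df["hx_flags"] = df["hx_flags"].fillna("")
    return df


def write_cohort(df: pd.DataFrame, path, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False, columns=list(COHORT_COLUMNS), float_format=FLOAT_FMT)


def read_ld(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"rsid_a": str, "rsid_b": str})
    for col in ("rsid_a", "rsid_b", "r2"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column '{col}'")
    return df


def read_exclusion_list(path) -> list:
    text = Path(path).read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


@dataclass
class RunConfig:
    """Thresholds and paths for one pipeline run; defaults are the study's
    published analysis constants."""

    arm: str = "both"  # cohort | mr | both
    cohort_path: str | None = None
    exposure_paths: dict = field(default_factory=dict)  # name -> sumstats path
    outcome_path: str | None = None
    ld_path: str | None = None
    exclusion_path: str | None = None
    bmi_exposure_path: str | None = None  # second MVMR exposure
    out_dir: str = "results"
    seed: int = 0
    p_threshold: float = 5e-8
    maf_min: float = 0.01
    r2_threshold: float = 0.001
    window_kb: float = 10_000
    exposures_cohort: tuple = ("alt", "ast", "ggt", "alp", "ast_alt_ratio", "hsi")
    lipids: tuple = ("tc", "tg", "ldl_c", "hdl_c")
    run_sensitivity: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for k, v in data.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown config key '{k}'")
            setattr(cfg, k, v)
        cfg.exposures_cohort = tuple(cfg.exposures_cohort)
        cfg.lipids = tuple(cfg.lipids)
        return cfg


def _or_rows(qr: models.QuartileLogisticResult, stratum: str, model: str):
    rows = []
    for r in qr.results:
        rows.append(dict(exposure=qr.exposure, contrast=r.contrast, stratum=stratum,
                         model=model, **{"or": r.or_point}, ci_low=r.ci_low, ci_high=r.ci_high,
                         p=r.p_value, p_trend=qr.p_trend, n_cases=r.n_cases,
                         n_total=r.n_total, flag=r.flag or ""))
    return rows


def run_cohort_arm(records: pd.DataFrame, out_dir: Path | None = None,
                   exposures=("alt", "ast", "ggt", "alp", "ast_alt_ratio", "hsi"),
                   lipids=("tc", "tg", "ldl_c", "hdl_c"),
                   run_sensitivity: bool = True) -> dict:
    """The full cohort arm on one cohort table.

    Applies inclusion/exclusion, derives indices and diagnosis, and produces
    the attrition log, baseline table, quartile OR tables (overall, per
    subtype, overweight strata and — optionally — the clinical-range
    sensitivity rerun), RCS summaries per biomarker-glucose pair, and the
    liver-index x lipid interaction table.
    """
    retained, attrition = cdom.apply_inclusion_exclusion(records)
    retained = cdom.add_derived_biomarkers(retained)
    status = cdom.classify_gdm(retained)
    retained = pd.concat([retained, status[["is_gdm", "subtype"]]], axis=1)

    bundle: dict = {"attrition": attrition, "n_analytic": len(retained)}
    bundle["prevalence"] = float(retained["is_gdm"].mean())
    bundle["baseline"] = models.baseline_table(retained, retained["is_gdm"])

    or_rows, subtype_rows, rcs_rows = [], [], []
    for exp in exposures:
        qr = models.fit_quartile_logistic(retained, exp)
        or_rows += _or_rows(qr, "overall", "main")
        try:
            sub = models.fit_subtype_multinomial(retained, exp)
        except ValueError:
            sub = {}
        for subtype, results in sub.items():
            for r in results:
                subtype_rows.append(dict(exposure=exp, subtype=subtype, contrast=r.contrast,
                                         **{"or": r.or_point}, ci_low=r.ci_low, ci_high=r.ci_high,
                                         p=r.p_value, n_cases=r.n_cases, flag=r.flag or ""))
        for ow, label in ((False, "non-overweight"), (True, "overweight")):
            sub_df = retained[retained["overweight"] == ow]
            if len(sub_df) >= 200:
                try:
                    qs = models.fit_quartile_logistic(sub_df, exp)
                    or_rows += _or_rows(qs, label, "stratified")
                except ValueError:
                    pass
        for channel in ("fbg", "pbg1h", "pbg2h"):
            fit = models.fit_rcs(retained, exp, channel)
            rcs_rows.append(dict(exposure=exp, outcome=channel, p_nonlinear=fit.p_nonlinear,
                                 chosen=fit.chosen,
                                 breakpoint=fit.breakpoint if fit.breakpoint is not None else "",
                                 linear_slope=fit.linear_slope, linear_slope_se=fit.linear_slope_se))
    if run_sensitivity:
        sens = cdom.clinical_range_filter(retained)
        for exp in exposures:
            try:
                qr = models.fit_quartile_logistic(sens, exp)
                or_rows += _or_rows(qr, "overall", "sensitivity")
            except ValueError:
                pass

    inter_rows = []
    with_lipids = retained.dropna(subset=[lip for lip in lipids if lip in retained])
    for exp in exposures:
        for lip in lipids:
            if lip not in with_lipids:
                continue
            res = models.crossover_interaction(with_lipids, exp, lip)
            hh = res.cell_or[("high", "high")]
            inter_rows.append(dict(lfi=exp, lipid=lip, p_interaction=res.p_interaction,
                                   or_high_high=hh[0], ci_low=hh[1], ci_high=hh[2],
                                   flag=res.flag or ""))

    bundle["quartile_or"] = pd.DataFrame(or_rows)
    bundle["subtype_or"] = pd.DataFrame(subtype_rows)
    bundle["rcs"] = pd.DataFrame(rcs_rows)
    bundle["interaction"] = pd.DataFrame(inter_rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        attrition.to_csv(out_dir / "attrition.tsv", sep="\t", index=False)
        bundle["baseline"].to_csv(out_dir / "baseline_table.tsv", sep="\t", index=False)
        bundle["quartile_or"].to_csv(out_dir / "quartile_or.tsv", sep="\t", index=False,
                                     float_format=FLOAT_FMT)
        bundle["subtype_or"].to_csv(out_dir / "subtype_or.tsv", sep="\t", index=False,
                                    float_format=FLOAT_FMT)
        bundle["rcs"].to_csv(out_dir / "rcs.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
        bundle["interaction"].to_csv(out_dir / "interaction.tsv", sep="\t", index=False,
                                     float_format=FLOAT_FMT)
    return bundle


def run_mr_arm(exposures: dict, outcome: pd.DataFrame, ld: pd.DataFrame | None = None,
               exclusion_list=(), bmi_exposure: pd.DataFrame | None = None,
               out_dir: Path | None = None, seed: int = 0,
               p_threshold: float = 5e-8, maf_min: float = 0.01,
               r2_threshold: float = 0.001, window_kb: float = 10_000) -> dict:
    """The full MR arm: selection, clumping, harmonization, diagnostics and
    the estimator suite for each exposure, with an instrument action log.

    ``exposures`` maps exposure name -> summary-statistics table. When
    ``bmi_exposure`` is given, SNPs present in it are additionally run
    through multivariable MR adjusting for BMI.
    """
    report_rows, log_rows = [], []
    bundle: dict = {"estimates": {}, "harmonized": {}}
    for name, sumstats in exposures.items():
        sel = mr.select_instruments(sumstats, p_threshold, maf_min, exclusion_list)
        log_rows.append(dict(exposure=name, stage="selected", count=len(sel)))
        clumped = mr.clump(sel, ld, r2_threshold, window_kb)
        log_rows.append(dict(exposure=name, stage="clumped", count=len(clumped)))
        h = mr.harmonize(clumped, outcome)
        for action, cnt in h.actions["action"].value_counts().items():
            log_rows.append(dict(exposure=name, stage=f"harmonize:{action}", count=int(cnt)))
        log_rows.append(dict(exposure=name, stage="analysed", count=len(h)))
        bundle["harmonized"][name] = h

        _, mean_f = mr.f_statistics(h)
        est_ivw = mr.ivw(h)
        q, qdf, qp = mr.cochran_q(h, est_ivw.beta)
        egger, intercept = mr.mr_egger(h) if len(h) >= 3 else (None, None)
        wmed = mr.weighted_median(h, seed=seed) if len(h) >= 3 else None
        presso = mr.mr_presso(h, n_sim=10_000, seed=seed,
                              significance_threshold=1e-6) if len(h) >= 4 else None

        ests = {"ivw": est_ivw, "mr_egger": egger, "weighted_median": wmed}
        if bmi_exposure is not None:
            merged = h.table.merge(
                bmi_exposure[["rsid", "beta", "se"]].rename(
                    columns={"beta": "beta_bmi", "se": "se_bmi"}),
                on="rsid", how="inner")
            if len(merged) > 2:
                mv = mr.mvmr(merged[["beta_exp", "beta_bmi"]].to_numpy(),
                             merged["beta_out"], merged["se_out"],
                             exposures=[name, "bmi"])
                ests["mvmr"] = mv[0]
        bundle["estimates"][name] = {k: v for k, v in ests.items() if v is not None}

        for method, est in bundle["estimates"][name].items():
            report_rows.append(dict(
                exposure=name, method=method, n_snps=est.n_snps, beta=est.beta, se=est.se,
                **{"or": est.or_point}, ci_low=est.or_ci[0], ci_high=est.or_ci[1], p=est.p,
                mean_f=mean_f, q_stat=q, q_p=qp,
                egger_intercept=intercept.beta if intercept else "",
                egger_intercept_p=intercept.p if intercept else "",
                presso_global_p=presso.global_p if presso else "",
                presso_outliers=";".join(presso.outliers) if presso else "",
            ))

    bundle["report"] = pd.DataFrame(report_rows)
    bundle["instrument_log"] = pd.DataFrame(log_rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        bundle["report"].to_csv(out_dir / "mr_report.tsv", sep="\t", index=False,
                                float_format=FLOAT_FMT)
        bundle["instrument_log"].to_csv(out_dir / "instrument_log.tsv", sep="\t", index=False)
    return bundle


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured arm(s) end to end from files; returns the merged
    report bundle. Stage errors propagate with the stage name prefixed."""
    out = Path(config.out_dir)
    bundle = {}
    if config.arm in ("cohort", "both"):
        try:
            records = read_cohort(config.cohort_path)
            bundle["cohort"] = run_cohort_arm(
                records, out / "cohort", exposures=config.exposures_cohort,
                lipids=config.lipids, run_sensitivity=config.run_sensitivity)
        except Exception as e:
            raise RuntimeError(f"cohort arm failed: {e}") from e
    if config.arm in ("mr", "both"):
        try:
            exposures = {name: read_sumstats(p) for name, p in config.exposure_paths.items()}
            outcome = read_sumstats(config.outcome_path)
            ld = read_ld(config.ld_path) if config.ld_path else None
            excl = read_exclusion_list(config.exclusion_path) if config.exclusion_path else ()
            bmi = read_sumstats(config.bmi_exposure_path) if config.bmi_exposure_path else None
            bundle["mr"] = run_mr_arm(
                exposures, outcome, ld, excl, bmi, out / "mr", seed=config.seed,
                p_threshold=config.p_threshold, maf_min=config.maf_min,
                r2_threshold=config.r2_threshold, window_kb=config.window_kb)
        except Exception as e:
            raise RuntimeError(f"mr arm failed: {e}") from e
    return bundle
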