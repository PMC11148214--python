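"""Replicated simulation studies: estimator recovery, robustness comparisons
and test-size calibration.

Every study generates its data through :mod:`gdmliver.simulate`, runs the
corresponding analysis exactly as the pipelines do, and summarises recovery
or rejection rates over replicates. All studies are deterministic given
their seed (replicate seeds are spawned from one generator and kept below
2**31).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import mr
from .cohort import add_derived_biomarkers, classify_gdm
from .models import crossover_interaction, fit_quartile_logistic, fit_rcs, fit_subtype_multinomial
from .simulate import CohortSimConfig, GwasSimConfig, simulate_cohort, simulate_gwas_pair

__all__ = [
    "ivw_recovery_study",
    "egger_vs_ivw_study",
    "weighted_median_vs_ivw_study",
    "cochran_q_calibration",
    "presso_null_calibration",
    "presso_spikein_detection",
    "trend_test_calibration",
    "rcs_test_calibration",
    "interaction_test_calibration",
    "subtype_pattern_study",
]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def _harmonized(cfg: GwasSimConfig) -> tuple[mr.HarmonizedSet, float]:
    exp, out, _, truth = simulate_gwas_pair(cfg)
    return mr.harmonize(exp, out), truth.theta


def ivw_recovery_study(n_rep: int = 500, m: int = 100, n_exp: int = 300_000,
                       n_out: int = 120_000, theta: float = 0.25,
                       seed: int = 0) -> dict:
    """IVW bias and 95%-CI coverage with valid instruments (no pleiotropy)."""
    rows = []
    for s in _child_seeds(seed, n_rep):
        h, _ = _harmonized(GwasSimConfig(m_snps=m, seed=int(s), n_exp=n_exp,
                                         n_out=n_out, theta=theta))
        est = mr.ivw(h)
        rows.append(dict(method="ivw", beta=est.beta, se=est.se,
                         ci_low=est.ci_low, ci_high=est.ci_high, p=est.p))
    df = pd.DataFrame(rows)
    return dict(
        theta=theta,
        bias=float(df["beta"].mean() - theta),
        coverage=float(np.mean((df["ci_low"] <= theta) & (theta <= df["ci_high"]))),
        estimates=df,
    )


def egger_vs_ivw_study(n_rep: int = 500, m: int = 150, theta: float = 0.25,
                       pleiotropy_mean: float = 0.02, seed: int = 1) -> dict:
    """Directional pleiotropy on every SNP: how often the Egger slope is
    closer to the truth than IVW, and the power of the intercept test."""
    egger_better, intercept_sig = 0, 0
    for s in _child_seeds(seed, n_rep):
        h, _ = _harmonized(GwasSimConfig(
            m_snps=m, seed=int(s), theta=theta, pleiotropy_mode="directional",
            fraction_invalid=1.0, pleiotropy_mean=pleiotropy_mean))
        b_ivw = mr.ivw(h).beta
        slope, intercept = mr.mr_egger(h)
        if abs(slope.beta - theta) < abs(b_ivw - theta):
            egger_better += 1
        if intercept.p < 0.05:
            intercept_sig += 1
    return dict(frac_egger_better=egger_better / n_rep,
                intercept_power=intercept_sig / n_rep)


def weighted_median_vs_ivw_study(n_rep: int = 200, m: int = 100, theta: float = 0.25,
                                 pleiotropy_mean: float = 0.02, seed: int = 2) -> dict:
    """Half the instruments invalid with directional pleiotropy: how often
    the weighted median is closer to the truth than IVW."""
    wm_better = 0
    for s in _child_seeds(seed, n_rep):
        h, _ = _harmonized(GwasSimConfig(
            m_snps=m, seed=int(s), theta=theta, pleiotropy_mode="directional",
            fraction_invalid=0.5, pleiotropy_mean=pleiotropy_mean))
        b_ivw = mr.ivw(h).beta
        b_wm = mr.weighted_median(h, n_boot=50, seed=int(s)).beta
        if abs(b_wm - theta) < abs(b_ivw - theta):
            wm_better += 1
    return dict(frac_wm_better=wm_better / n_rep)


def cochran_q_calibration(n_rep: int = 500, m: int = 100, seed: int = 3) -> dict:
    """Size of the Q heterogeneity test under its exact null: homogeneous
    Wald ratios (no causal effect, no pleiotropy), where the outcome effects
    are pure noise around zero."""
    rej = 0
    for s in _child_seeds(seed, n_rep):
        h, _ = _harmonized(GwasSimConfig(m_snps=m, seed=int(s), theta=0.0))
        _, _, p = mr.cochran_q(h)
        if p < 0.05:
            rej += 1
    return dict(type1=rej / n_rep)


def presso_null_calibration(n_rep: int = 200, m: int = 50, n_sim: int = 500,
                            seed: int = 4) -> dict:
    """Rejection rate of the MR-PRESSO global test on clean data."""
    rej = 0
    for s in _child_seeds(seed, n_rep):
        h, _ = _harmonized(GwasSimConfig(m_snps=m, seed=int(s)))
        res = mr.mr_presso(h, n_sim=n_sim, seed=int(s) + 1)
        if res.global_p < 0.05:
            rej += 1
    return dict(rejection=rej / n_rep)


def presso_spikein_detection(n_rep: int = 100, m: int = 50, n_sim: int = 2000,
                             shift_se: float = 10.0, seed: int = 5) -> dict:
    """Detection rate of a single spiked outlier (+shift_se * se_out)."""
    detected = 0
    for s in _child_seeds(seed, n_rep):
        h, _ = _harmonized(GwasSimConfig(m_snps=m, seed=int(s)))
        tab = h.table.copy()
        k = int(np.random.default_rng(int(s)).integers(len(tab)))
        tab.loc[k, "beta_out"] += shift_se * tab.loc[k, "se_out"]
        res = mr.mr_presso(mr.HarmonizedSet(tab, h.actions), n_sim=n_sim, seed=int(s) + 1)
        if tab.loc[k, "rsid"] in res.outliers:
            detected += 1
    return dict(detection=detected / n_rep)


def _prepared_cohort(cfg: CohortSimConfig) -> pd.DataFrame:
    df, _ = simulate_cohort(cfg)
    df = add_derived_biomarkers(df)
    status = classify_gdm(df)
    return pd.concat([df, status[["is_gdm", "subtype"]]], axis=1)


def trend_test_calibration(n_rep: int = 500, n: int = 1500, seed: int = 6) -> dict:
    """Size of the median-assigned linear-trend test when no biomarker
    affects glucose."""
    rej = 0
    for s in _child_seeds(seed, n_rep):
        df = _prepared_cohort(CohortSimConfig(n=n, seed=int(s), effects={},
                                              lipid_missing_frac=0.0))
        qr = fit_quartile_logistic(df, "alt")
        if qr.p_trend < 0.05:
            rej += 1
    return dict(type1=rej / n_rep)


def rcs_test_calibration(n_rep: int = 500, n: int = 2000, seed: int = 7) -> dict:
    """Size of the spline nonlinearity test when the biomarker-glucose
    relation is exactly linear on the measured scale."""
    rej = 0
    for s in _child_seeds(seed, n_rep):
        df, _ = simulate_cohort(CohortSimConfig(
            n=n, seed=int(s), effects={"alt": (0.0, 0.01, 0.0)}, effect_on="raw",
            lipid_missing_frac=0.0))
        fit = fit_rcs(df, "alt", "pbg1h", run_piecewise=False)
        if fit.p_nonlinear < 0.05:
            rej += 1
    return dict(type1=rej / n_rep)


def interaction_test_calibration(n_rep: int = 500, n: int = 2000, seed: int = 8) -> dict:
    """Size of the crossover product-term test when the liver index and the
    lipid are both independent of glucose."""
    rej = 0
    for s in _child_seeds(seed, n_rep):
        df = _prepared_cohort(CohortSimConfig(n=n, seed=int(s), effects={},
                                              lipid_missing_frac=0.0))
        res = crossover_interaction(df, "ast_alt_ratio", "tg")
        if res.p_interaction < 0.05:
            rej += 1
    return dict(type1=rej / n_rep)


def subtype_pattern_study(n: int = 9148, seed: int = 9) -> dict:
    """End-to-end subtype pattern: with generator effects only on the
    post-load glucose channels, the top-quartile ALT odds ratios should be
    elevated for i-IGT and b-GDM and null for i-IFG."""
    cfg = CohortSimConfig(n=n, seed=seed, effects={"alt": (0.0, 0.10, 0.10),
                                                   "ast": (0.0, 0.07, 0.07)})
    df = _prepared_cohort(cfg)
    sub = fit_subtype_multinomial(df, "alt")
    out = {}
    for subtype, rows in sub.items():
        q4 = rows[-1]
        out[subtype] = dict(odds_ratio=q4.or_point, ci_low=q4.ci_low, ci_high=q4.ci_high,
                            p=q4.p_value)
    return out
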