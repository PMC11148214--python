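"""Synthetic-data generators with recorded ground truth.

Two generators emulate the two analysis arms so every pipeline stage can be
exercised offline:

* :func:`simulate_cohort` draws a pregnancy cohort — covariates, correlated
  log-normal liver enzymes and lipids, and the three OGTT glucose channels
  as linear functions of the (standardised log) biomarkers plus noise, with
  the channel intercepts calibrated by bisection so the realised GDM
  prevalence hits a target (default 18.2%).
* :func:`simulate_gwas_pair` draws matched exposure/outcome GWAS summary
  statistics under the standard two-sample MR generative model with
  configurable pleiotropy, palindromic alleles and block LD structure.

Both are bit-reproducible under their seed, and both return a
:class:`SimTruth` carrying the realised ground-truth parameters for
recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort import classify_gdm

__all__ = [
    "CohortSimConfig",
    "GwasSimConfig",
    "SimTruth",
    "simulate_cohort",
    "simulate_gwas_pair",
    "truth_report",
]

BIOMARKERS = ("alt", "ast", "ggt", "alp", "tg", "tc", "ldl_c", "hdl_c")
CHANNELS = ("fbg", "pbg1h", "pbg2h")

# log-scale location/scale matched to first-trimester medians and IQRs of a
# Chinese pregnancy cohort (ALT 13 [10,19] U/L, AST 17 [14,19], GGT 11 [9,15],
# ALP 49 [43,57]; lipids in mmol/L)
_DEFAULT_LOG_MEAN = (2.565, 2.833, 2.398, 3.892, 0.262, 1.526, 0.833, 0.588)
_DEFAULT_LOG_SD = (0.476, 0.226, 0.379, 0.209, 0.35, 0.15, 0.25, 0.20)


def _default_corr() -> np.ndarray:
    c = np.eye(8)
    pairs = {
        ("alt", "ast"): 0.70, ("alt", "ggt"): 0.50, ("alt", "alp"): 0.20,
        ("ast", "ggt"): 0.45, ("ast", "alp"): 0.20, ("ggt", "alp"): 0.30,
        ("tg", "tc"): 0.30, ("tg", "ldl_c"): 0.20, ("tg", "hdl_c"): -0.35,
        ("tc", "ldl_c"): 0.85, ("tc", "hdl_c"): 0.35, ("ldl_c", "hdl_c"): 0.05,
        ("alt", "tg"): 0.25, ("ggt", "tg"): 0.25, ("alt", "tc"): 0.10,
        ("ast", "tg"): 0.10, ("alp", "tg"): 0.10,
    }
    idx = {b: i for i, b in enumerate(BIOMARKERS)}
    for (a, b), r in pairs.items():
        c[idx[a], idx[b]] = c[idx[b], idx[a]] = r
    return c


def _default_effects() -> dict:
    """Per-SD-of-log-biomarker effects on (fbg, pbg1h, pbg2h), in units of
    each channel's SD: transaminases act on post-load glucose only; GGT and
    ALP also raise fasting glucose; triglycerides act on all channels."""
    return {
        "alt": (0.00, 0.10, 0.10),
        "ast": (0.00, 0.07, 0.07),
        "ggt": (0.06, 0.09, 0.09),
        "alp": (0.06, 0.08, 0.08),
        "tg": (0.04, 0.08, 0.08),
    }


@dataclass
class CohortSimConfig:
    """Generator settings for the synthetic pregnancy cohort."""

    n: int = 9148
    seed: int | None = None
    prevalence_target: float = 0.182
    log_mean: tuple = _DEFAULT_LOG_MEAN
    log_sd: tuple = _DEFAULT_LOG_SD
    corr: np.ndarray = field(default_factory=_default_corr)
    # biomarker -> 3 channel effects; units depend on effect_on
    effects: dict = field(default_factory=_default_effects)
    effect_on: str = "log_sd"  # "log_sd": per SD of log-biomarker; "raw": per unit raw value
    covariate_effects: dict = field(default_factory=lambda: {"age": 0.012, "bmi": 0.045})
    # multiplicative high/high joint effect: indicator(lfi above median) *
    # indicator(lipid above median) * coef added to every channel (SD units)
    interaction_lfi: str = "ast_alt_ratio"
    interaction_lipid: str = "tg"
    interaction_coef: float = 0.0
    # optional hinge term coef*(x - threshold)_+^power on the raw scale:
    # power 1 gives a segmented (breakpoint) truth, power 2 a J-shape
    nonlinear_biomarker: str | None = None
    nonlinear_threshold: float = 0.0
    nonlinear_coef: float = 0.0
    nonlinear_power: float = 2.0
    glucose_mu: tuple = (4.40, 7.40, 6.40)
    glucose_sd: tuple = (0.35, 1.50, 1.20)
    glucose_noise_corr: float = 0.5
    lipid_missing_frac: float = 1.0 - 4340 / 9148
    prevalence_tol: float = 0.01

    def validate(self):
        if not (0 < self.prevalence_target < 1):
            raise ValueError("prevalence_target must be in (0,1)")
        np.linalg.cholesky(np.asarray(self.corr))  # raises if not PD
        if self.effect_on not in ("log_sd", "raw"):
            raise ValueError("effect_on must be 'log_sd' or 'raw'")


@dataclass
class GwasSimConfig:
    """Generator settings for a matched exposure/outcome GWAS pair.

    Defaults mirror the study conditions of a liver-enzyme MR on GDM:
    166 instruments (the ALT count), an exposure GWAS of 500,000 and an
    outcome GWAS of 123,579 (5,687 cases + 117,892 controls), causal
    log-OR 0.25 per unit exposure, and instrument strengths giving a mean
    F-statistic near 80.
    """

    m_snps: int = 166
    seed: int | None = None
    n_exp: int = 500_000
    n_out: int = 123_579
    maf_range: tuple = (0.05, 0.5)
    # instrument strengths are half-normal(gamma_sd) shifted by gamma_min,
    # oriented so the effect allele increases the exposure (as in a
    # post-selection instrument set); gamma_sd=0.02 gives mean F near 80
    # at n_exp=500,000
    gamma_sd: float = 0.02
    gamma_min: float = 0.0
    theta: float = 0.25  # causal log-OR of exposure on outcome
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_mean: float = 0.02
    pleiotropy_sd: float = 0.01
    fraction_invalid: float = 0.0
    fraction_palindromic: float = 0.0
    fraction_swapped: float = 0.3  # outcome rows reported on the opposite orientation
    ld_block_size: int = 1
    ld_within_r2: float = 0.9

    def validate(self):
        for frac in (self.fraction_invalid, self.fraction_palindromic, self.fraction_swapped):
            if not (0 <= frac <= 1):
                raise ValueError("fractions must be in [0,1]")
        if self.n_exp <= 0 or self.n_out <= 0:
            raise ValueError("sample sizes must be positive")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError("unknown pleiotropy mode")


@dataclass
class SimTruth:
    """Realised ground truth stored alongside every generated dataset."""

    theta: float | None = None
    gamma: np.ndarray | None = None  # per-SNP exposure effects
    alpha: np.ndarray | None = None  # per-SNP pleiotropy
    effects: dict | None = None  # cohort effect vector
    interaction_coef: float | None = None
    realized_prevalence: float | None = None
    intercept_shift: float | None = None
    config: dict | None = None


EDUCATION_LEVELS = ("primary-or-below", "middle", "high", "college-or-above")


def simulate_cohort(config: CohortSimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Draw a synthetic pregnancy cohort with known biomarker-glucose truth.

    The three glucose channels are Gaussian with correlated noise; the GDM
    label falls out of :func:`gdmliver.cohort.classify_gdm`, and a shared
    intercept shift (in channel-SD units) is found by bisection so the
    realised prevalence lands within ``prevalence_tol`` of the target.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n

    # covariates with Table-1-like frequencies
    age = np.clip(rng.normal(28.6, 4.0, n), 18, 45).round(1)
    education = rng.choice(EDUCATION_LEVELS, size=n, p=[0.169, 0.153, 0.309, 0.369])
    gravidity = rng.choice([1, 2, 3], size=n, p=[0.444, 0.370, 0.186])
    parity = rng.choice([0, 1, 2], size=n, p=[0.683, 0.280, 0.037])
    smoking = rng.choice(["no", "yes", "unknown"], size=n, p=[0.982, 0.012, 0.006])
    alcohol = rng.choice(["no", "yes", "unknown"], size=n, p=[0.980, 0.013, 0.007])
    weight_gain = np.clip(rng.normal(11.9, 3.8, n), 0, None).round(1)
    ga_weeks = rng.uniform(8, 14, n).round(1)

    # correlated log-normal biomarkers; BMI log-normal, linked to lipids via
    # a shared latent factor would overreach -- an independent draw suffices
    bmi = np.exp(rng.normal(np.log(21.0), 0.12, n)).round(1)
    L = np.linalg.cholesky(np.asarray(config.corr))
    z = rng.standard_normal((n, len(BIOMARKERS))) @ L.T
    logs = np.asarray(config.log_mean) + z * np.asarray(config.log_sd)
    bio = np.exp(logs)

    idx = {b: i for i, b in enumerate(BIOMARKERS)}

    def _standardized(name: str) -> np.ndarray:
        if name == "ast_alt_ratio":
            d = logs[:, idx["ast"]] - logs[:, idx["alt"]]
        else:
            d = logs[:, idx[name]] - config.log_mean[idx[name]]
        return (d - d.mean()) / d.std()

    # linear predictor per channel, in channel-SD units
    lin = np.zeros((n, 3))
    for b, eff in config.effects.items():
        if config.effect_on == "log_sd":
            x = _standardized(b)
        else:
            x = bio[:, idx[b]]
        lin += np.outer(x, np.asarray(eff, dtype=float))
    lin += np.outer(age - 28.6, np.full(3, config.covariate_effects.get("age", 0.0)))
    lin += np.outer(bmi - 21.0, np.full(3, config.covariate_effects.get("bmi", 0.0)))

    if config.interaction_coef != 0.0:
        a = _standardized(config.interaction_lfi)
        c = _standardized(config.interaction_lipid)
        hi = ((a > np.median(a)) & (c > np.median(c))).astype(float)
        lin += config.interaction_coef * hi[:, None]

    if config.nonlinear_biomarker is not None and config.nonlinear_coef != 0.0:
        x = bio[:, idx[config.nonlinear_biomarker]]
        hinge = np.clip(x - config.nonlinear_threshold, 0, None) ** config.nonlinear_power
        lin += config.nonlinear_coef * hinge[:, None]

    rho = config.glucose_noise_corr
    cov = np.full((3, 3), rho) + np.eye(3) * (1 - rho)
    eps = rng.multivariate_normal(np.zeros(3), cov, size=n, method="cholesky")
    mu = np.asarray(config.glucose_mu)
    sd = np.asarray(config.glucose_sd)
    base = mu + sd * (lin + eps)

    def prevalence(shift: float) -> float:
        g = base + sd * shift
        f = g[:, 0] >= 5.1
        p = (g[:, 1] >= 10.0) | (g[:, 2] >= 8.5)
        return float(np.mean(f | p))

    lo, hi = -6.0, 6.0
    if prevalence(lo) > config.prevalence_target or prevalence(hi) < config.prevalence_target:
        raise ValueError("prevalence target unattainable under this configuration")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if prevalence(mid) < config.prevalence_target:
            lo = mid
        else:
            hi = mid
    shift = hi
    realized = prevalence(shift)
    if abs(realized - config.prevalence_target) > config.prevalence_tol:
        raise ValueError(
            f"bisection failed: realised prevalence {realized:.4f} vs "
            f"target {config.prevalence_target:.4f}"
        )
    glucose = np.round(base + sd * shift, 2)
    glucose = np.clip(glucose, 0.5, None)

    df = pd.DataFrame(
        {
            "id": [f"P{i+1:06d}" for i in range(n)],
            "age": age,
            "bmi": bmi,
            "weight_gain": weight_gain,
            "ga_weeks": ga_weeks,
            "education": education,
            "gravidity": gravidity,
            "parity": parity,
            "smoking": smoking,
            "alcohol": alcohol,
            "alt": np.round(bio[:, idx["alt"]], 1),
            "ast": np.round(bio[:, idx["ast"]], 1),
            "ggt": np.round(bio[:, idx["ggt"]], 1),
            "alp": np.round(bio[:, idx["alp"]], 1),
            "tc": np.round(bio[:, idx["tc"]], 2),
            "tg": np.round(bio[:, idx["tg"]], 2),
            "ldl_c": np.round(bio[:, idx["ldl_c"]], 2),
            "hdl_c": np.round(bio[:, idx["hdl_c"]], 2),
            "fbg": glucose[:, 0],
            "pbg1h": glucose[:, 1],
            "pbg2h": glucose[:, 2],
            "hx_flags": "",
        }
    )
    if config.lipid_missing_frac > 0:
        miss = rng.random(n) < config.lipid_missing_frac
        df.loc[miss, ["tc", "tg", "ldl_c", "hdl_c"]] = np.nan

    status = classify_gdm(df)
    realized = float(status["is_gdm"].mean())
    cfg = asdict(config)
    cfg["corr"] = np.asarray(config.corr).tolist()
    truth = SimTruth(
        effects=dict(config.effects),
        interaction_coef=config.interaction_coef,
        realized_prevalence=realized,
        intercept_shift=float(shift),
        config=cfg,
    )
    return df, truth


_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"))
_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))


def simulate_gwas_pair(
    config: GwasSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Draw exposure and outcome summary statistics with known causal truth.

    Per SNP j: maf ~ U(maf_range); true exposure effect gamma_j =
    gamma_min + |N(0, gamma_sd)| (positive: the effect allele is the
    exposure-increasing allele); sampling SEs follow the standard
    1/sqrt(2 maf (1-maf) n)
    form; beta_exp_j ~ N(gamma_j, se_exp_j); the outcome effect is
    beta_out_j ~ N(theta * gamma_j + alpha_j, se_out_j) where alpha_j is the
    horizontal-pleiotropy term applied to a fraction of SNPs (balanced:
    mean-zero; directional: nonzero mean, which breaks IVW but not Egger).
    SNPs are laid out in LD blocks (exchangeable within-block r²) so that
    clumping has structure to prune; a pairwise LD table is returned.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.m_snps

    maf = rng.uniform(*config.maf_range, m)
    gamma = config.gamma_min + np.abs(rng.normal(0.0, config.gamma_sd, m))
    se_exp = 1.0 / np.sqrt(2 * maf * (1 - maf) * config.n_exp)
    beta_exp = rng.normal(gamma, se_exp)
    from scipy.stats import norm

    pval_exp = 2 * norm.sf(np.abs(beta_exp) / se_exp)
    pval_exp = np.clip(pval_exp, 1e-300, 1.0)

    alpha = np.zeros(m)
    n_invalid = int(round(config.fraction_invalid * m))
    if config.pleiotropy_mode != "none" and n_invalid > 0:
        invalid = rng.choice(m, size=n_invalid, replace=False)
        mean = config.pleiotropy_mean if config.pleiotropy_mode == "directional" else 0.0
        alpha[invalid] = rng.normal(mean, config.pleiotropy_sd, n_invalid)

    se_out = 1.0 / np.sqrt(2 * maf * (1 - maf) * config.n_out)
    beta_out = rng.normal(config.theta * gamma + alpha, se_out)
    pval_out = np.clip(2 * norm.sf(np.abs(beta_out) / se_out), 1e-300, 1.0)

    # alleles
    n_pal = int(round(config.fraction_palindromic * m))
    pal_idx = set(rng.choice(m, size=n_pal, replace=False).tolist()) if n_pal else set()
    ea, oa = [], []
    for j in range(m):
        pool = _PALINDROMIC_PAIRS if j in pal_idx else _ALLELE_PAIRS
        a1, a2 = pool[rng.integers(len(pool))]
        ea.append(a1)
        oa.append(a2)

    # block LD layout: blocks 50 Mb apart (far outside any clumping window)
    block = np.arange(m) // max(config.ld_block_size, 1)
    chrom = (block % 22) + 1
    pos = (block // 22) * 50_000_000 + 1_000_000 + (np.arange(m) % max(config.ld_block_size, 1)) * 10_000
    rsids = np.array([f"rs{j+1:06d}" for j in range(m)])

    ld_rows = []
    if config.ld_block_size > 1:
        for b in np.unique(block):
            members = np.nonzero(block == b)[0]
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    ld_rows.append((rsids[members[i]], rsids[members[j]], config.ld_within_r2))
    ld = pd.DataFrame(ld_rows, columns=["rsid_a", "rsid_b", "r2"])

    exposure = pd.DataFrame(
        {
            "rsid": rsids, "chr": chrom, "pos": pos,
            "effect_allele": ea, "other_allele": oa,
            "eaf": maf, "beta": beta_exp, "se": se_exp,
            "pval": pval_exp, "n": config.n_exp,
        }
    )
    outcome = pd.DataFrame(
        {
            "rsid": rsids, "chr": chrom, "pos": pos,
            "effect_allele": ea, "other_allele": oa,
            "eaf": maf, "beta": beta_out, "se": se_out,
            "pval": pval_out, "n": config.n_out,
        }
    )
    # report a fraction of outcome rows on the opposite allele orientation
    swap = rng.random(m) < config.fraction_swapped
    outcome.loc[swap, ["effect_allele", "other_allele"]] = outcome.loc[
        swap, ["other_allele", "effect_allele"]
    ].to_numpy()
    outcome.loc[swap, "beta"] = -outcome.loc[swap, "beta"]
    outcome.loc[swap, "eaf"] = 1.0 - outcome.loc[swap, "eaf"]

    truth = SimTruth(theta=config.theta, gamma=gamma, alpha=alpha, config=asdict(config))
    return exposure, outcome, ld, truth


def truth_report(truth_theta: float, estimates: pd.DataFrame) -> pd.DataFrame:
    """Estimator-recovery metrics over replicates.

    ``estimates`` needs columns method, beta, se, ci_low, ci_high, p (one
    row per replicate per method, equal counts per method). Returns bias,
    RMSE, 95%-CI coverage of the truth and power (p < 0.05) per method.
    """
    required = {"method", "beta", "ci_low", "ci_high", "p"}
    if not required <= set(estimates.columns):
        raise ValueError(f"estimates table missing columns {required - set(estimates.columns)}")
    counts = estimates.groupby("method").size()
    if counts.nunique() > 1:
        raise ValueError("mismatched replicate counts across methods")
    rows = []
    for method, g in estimates.groupby("method"):
        err = g["beta"] - truth_theta
        rows.append(
            dict(
                method=method,
                n_replicates=len(g),
                bias=float(err.mean()),
                rmse=float(np.sqrt(np.mean(err**2))),
                coverage=float(np.mean((g["ci_low"] <= truth_theta) & (truth_theta <= g["ci_high"]))),
                power=float(np.mean(g["p"] < 0.05)),
            )
        )
    return pd.DataFrame(rows)
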