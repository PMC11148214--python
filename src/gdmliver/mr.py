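"""Two-sample Mendelian randomization engine.

Summary statistics for an exposure (e.g. a liver enzyme from a population
GWAS) and a binary outcome (gestational diabetes from a case-control GWAS)
are combined through genetic instruments: instrument selection, LD clumping,
allele harmonization, instrument-strength diagnostics and the estimator
suite — per-SNP Wald ratios, inverse-variance-weighted (IVW) meta-analysis,
MR-Egger regression, the weighted median, Cochran's Q heterogeneity test,
the MR-PRESSO global/outlier/distortion procedure, and multivariable MR.

Per-allele outcome effects are taken on the log-odds scale, so causal
estimates exponentiate to odds ratios per unit of exposure.

A summary-statistics table is a pandas DataFrame with columns
``rsid, effect_allele, other_allele, eaf, beta, se, pval, n`` (plus
``chr, pos`` when clumping is needed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st

__all__ = [
    "SUMSTATS_COLUMNS",
    "MREstimate",
    "HarmonizedSet",
    "PressoResult",
    "validate_sumstats",
    "select_instruments",
    "clump",
    "harmonize",
    "f_statistics",
    "wald_ratio",
    "ivw",
    "cochran_q",
    "mr_egger",
    "weighted_median",
    "mr_presso",
    "mvmr",
]

Z95 = st.norm.ppf(0.975)

SUMSTATS_COLUMNS = ("rsid", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n")

_PALINDROMIC = ({"A", "T"}, {"C", "G"})


@dataclass
class MREstimate:
    """One causal estimate: log-OR per unit exposure with Wald 95% CI."""

    method: str
    beta: float
    se: float
    p: float
    n_snps: int
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ci_low = self.beta - Z95 * self.se
        self.ci_high = self.beta + Z95 * self.se

    @property
    def or_point(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple:
        return (float(np.exp(self.ci_low)), float(np.exp(self.ci_high)))


@dataclass
class HarmonizedSet:
    """Exposure/outcome effects on a common effect-allele orientation."""

    table: pd.DataFrame  # rsid, beta_exp, se_exp, beta_out, se_out, eaf_exp, eaf_out
    actions: pd.DataFrame  # rsid, action

    def __len__(self):
        return len(self.table)

    @property
    def beta_exp(self):
        return self.table["beta_exp"].to_numpy(dtype=float)

    @property
    def se_exp(self):
        return self.table["se_exp"].to_numpy(dtype=float)

    @property
    def beta_out(self):
        return self.table["beta_out"].to_numpy(dtype=float)

    @property
    def se_out(self):
        return self.table["se_out"].to_numpy(dtype=float)


@dataclass
class PressoResult:
    global_rss: float
    global_p: float
    outliers: list
    corrected: MREstimate | None
    distortion_p: float | None


def validate_sumstats(df: pd.DataFrame) -> pd.DataFrame:
    """Check the summary-statistics invariants; raises on violations."""
    for col in SUMSTATS_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"summary statistics missing column '{col}'")
    if df["rsid"].duplicated().any():
        dup = df.loc[df["rsid"].duplicated(), "rsid"].iloc[0]
        raise ValueError(f"duplicate rsid '{dup}'")
    if (df["se"] <= 0).any():
        raise ValueError("se must be > 0")
    if ((df["eaf"] <= 0) | (df["eaf"] >= 1)).any():
        raise ValueError("eaf must be in (0, 1)")
    if ((df["pval"] <= 0) | (df["pval"] > 1)).any():
        raise ValueError("pval must be in (0, 1]")
    if (df["effect_allele"] == df["other_allele"]).any():
        raise ValueError("effect and other allele must differ")
    return df


# ---------------------------------------------------------------------------
# instrument selection and LD clumping


def select_instruments(
    sumstats: pd.DataFrame,
    p_threshold: float = 5e-8,
    maf_min: float = 0.01,
    exclusion_list=(),
) -> pd.DataFrame:
    """Keep genome-wide-significant, common, non-pleiotropic SNPs.

    Inclusion is strict on both bounds: pval < p_threshold and
    min(eaf, 1-eaf) > maf_min. ``exclusion_list`` holds rsids known to be
    associated with confounding traits (the user-supplied stand-in for a
    GWAS-catalog pleiotropy screen).
    """
    excl = set(exclusion_list)
    maf = np.minimum(sumstats["eaf"], 1.0 - sumstats["eaf"])
    keep = (sumstats["pval"] < p_threshold) & (maf > maf_min) & ~sumstats["rsid"].isin(excl)
    out = sumstats.loc[keep].copy()
    if out.empty:
        raise ValueError("no valid instruments after selection")
    return out


def _ld_lookup(ld: pd.DataFrame | None) -> dict:
    table = {}
    if ld is None or len(ld) == 0:
        return table
    for a, b, r2 in zip(ld["rsid_a"], ld["rsid_b"], ld["r2"]):
        table[(a, b)] = float(r2)
        table[(b, a)] = float(r2)
    return table


def clump(
    snps: pd.DataFrame,
    ld: pd.DataFrame | None = None,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
) -> pd.DataFrame:
    """Greedy LD clumping of a summary-statistics table.

    Repeatedly take the unassigned SNP with the lowest p-value as the index
    SNP and discard every unassigned SNP on the same chromosome within
    ±window_kb whose r² with the index exceeds r2_threshold. Ties in
    p-value break lexicographically on rsid. Pairs absent from the LD table
    are treated as uncorrelated (r² = 0), with one warning.

    Requires ``chr`` and ``pos`` (base-pair) columns.
    """
    for col in ("chr", "pos"):
        if col not in snps.columns or snps[col].isna().any():
            raise ValueError(f"clump: missing positions (column '{col}')")
    lookup = _ld_lookup(ld)
    warned_missing = False

    df = snps.sort_values(["pval", "rsid"], kind="mergesort").reset_index(drop=True)
    chrom = df["chr"].to_numpy()
    pos = df["pos"].to_numpy(dtype=float)
    rsid = df["rsid"].to_numpy()
    window_bp = window_kb * 1000.0

    assigned = np.zeros(len(df), dtype=bool)
    keep_idx = []
    for i in range(len(df)):
        if assigned[i]:
            continue
        assigned[i] = True
        keep_idx.append(i)
        near = ~assigned & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window_bp)
        for j in np.nonzero(near)[0]:
            key = (rsid[i], rsid[j])
            if key not in lookup and ld is not None and not warned_missing:
                warnings.warn("clump: SNP pair(s) absent from LD table treated as r²=0")
                warned_missing = True
            if lookup.get(key, 0.0) > r2_threshold:
                assigned[j] = True
    return df.iloc[keep_idx].reset_index(drop=True)


# ---------------------------------------------------------------------------
# harmonization


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1.upper(), a2.upper()} in _PALINDROMIC


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame) -> HarmonizedSet:
    """Express outcome effects on the exposure's effect allele.

    SNPs are intersected on rsid. Matching allele pairs are kept as-is;
    swapped pairs have the outcome beta sign-flipped and eaf complemented;
    palindromic SNPs (A/T or C/G) are dropped outright because their strand
    cannot be resolved from alleles alone; any other configuration is
    dropped as an allele mismatch. Every decision is logged per rsid.
    """
    actions = []
    exp = exposure.set_index("rsid")
    out = outcome.set_index("rsid")
    for rid in exposure["rsid"]:
        if rid not in out.index:
            actions.append((rid, "dropped_missing"))
    common = [r for r in exposure["rsid"] if r in out.index]

    rows = []
    for rid in common:
        e, o = exp.loc[rid], out.loc[rid]
        ea_e, oa_e = str(e["effect_allele"]).upper(), str(e["other_allele"]).upper()
        ea_o, oa_o = str(o["effect_allele"]).upper(), str(o["other_allele"]).upper()
        if _is_palindromic(ea_e, oa_e):
            actions.append((rid, "dropped_palindromic"))
            continue
        if (ea_o, oa_o) == (ea_e, oa_e):
            beta_o, eaf_o, act = float(o["beta"]), float(o["eaf"]), "kept"
        elif (ea_o, oa_o) == (oa_e, ea_e):
            beta_o, eaf_o, act = -float(o["beta"]), 1.0 - float(o["eaf"]), "flipped"
        else:
            actions.append((rid, "dropped_mismatch"))
            continue
        actions.append((rid, act))
        rows.append(
            dict(
                rsid=rid,
                effect_allele=ea_e,
                other_allele=oa_e,
                beta_exp=float(e["beta"]),
                se_exp=float(e["se"]),
                eaf_exp=float(e["eaf"]),
                beta_out=beta_o,
                se_out=float(o["se"]),
                eaf_out=eaf_o,
            )
        )
    if not rows:
        raise ValueError("harmonize: no SNPs shared between exposure and outcome")
    table = pd.DataFrame(rows)
    log = pd.DataFrame(actions, columns=["rsid", "action"])
    return HarmonizedSet(table=table, actions=log)


# ---------------------------------------------------------------------------
# diagnostics and estimators


def f_statistics(h: HarmonizedSet) -> tuple[pd.Series, float]:
    """Per-SNP instrument-strength F = (beta_exp/se_exp)² and its mean.

    Mean F <= 10 triggers a weak-instrument warning (the conventional bound).
    """
    if len(h) == 0:
        raise ValueError("no SNPs")
    f = pd.Series((h.beta_exp / h.se_exp) ** 2, index=h.table["rsid"], name="F")
    mean_f = float(f.mean())
    if mean_f <= 10:
        warnings.warn(f"weak instruments: mean F = {mean_f:.2f} <= 10")
    return f, mean_f


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float) -> MREstimate:
    """Single-SNP causal estimate: beta_out / beta_exp with first-order
    (outcome-uncertainty-only) delta-method SE."""
    if beta_exp == 0:
        raise ValueError("wald_ratio: beta_exp must be nonzero")
    beta = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    p = 2.0 * st.norm.sf(abs(beta) / se)
    return MREstimate("wald_ratio", float(beta), float(se), float(p), 1)


def _ivw_core(beta_exp, se_exp, beta_out, se_out):
    """Fixed-effect IVW beta, fixed SE, Q statistic and df."""
    theta = beta_out / beta_exp
    w = beta_exp**2 / se_out**2
    beta = float(np.sum(w * theta) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (theta - beta) ** 2))
    return beta, se_fixed, q, len(theta) - 1


def ivw(h: HarmonizedSet, random_effects: bool = True) -> MREstimate:
    """Inverse-variance-weighted meta-analysis of the Wald ratios.

    Equivalent to zero-intercept weighted regression of beta_out on
    beta_exp with weights 1/se_out². The default reports a multiplicative
    random-effects SE (fixed SE inflated by sqrt(Q/(m-1)), floored at 1),
    appropriate under the heterogeneity typically seen with many
    instruments; the fixed-effect SE is kept in the diagnostics.
    """
    m = len(h)
    if m == 0:
        raise ValueError("ivw: empty instrument set")
    if np.all(h.beta_exp == 0):
        raise ValueError("ivw: all exposure effects are zero")
    if m == 1:
        est = wald_ratio(h.beta_exp[0], h.se_exp[0], h.beta_out[0], h.se_out[0])
        est.method = "ivw"
        return est
    beta, se_fixed, q, dof = _ivw_core(h.beta_exp, h.se_exp, h.beta_out, h.se_out)
    scale = max(1.0, np.sqrt(q / dof)) if random_effects else 1.0
    se = se_fixed * scale
    p = 2.0 * st.norm.sf(abs(beta) / se)
    est = MREstimate("ivw", beta, float(se), float(p), m)
    est.diagnostics.update(
        se_fixed=se_fixed, q_stat=q, q_df=dof, q_p=float(st.chi2.sf(q, dof)),
        random_effects=random_effects,
    )
    return est


def cochran_q(h: HarmonizedSet, ivw_beta: float | None = None) -> tuple[float, int, float]:
    """Heterogeneity of the per-SNP Wald ratios around the IVW estimate:
    Q = sum w_j (theta_j - beta)², chi-square with m-1 df."""
    m = len(h)
    if m < 2:
        raise ValueError("cochran_q: need at least 2 SNPs")
    theta = h.beta_out / h.beta_exp
    w = h.beta_exp**2 / h.se_out**2
    if ivw_beta is None:
        ivw_beta = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - ivw_beta) ** 2))
    dof = m - 1
    return q, dof, float(st.chi2.sf(q, dof))


def mr_egger(h: HarmonizedSet) -> tuple[MREstimate, MREstimate]:
    """MR-Egger: weighted regression of beta_out on beta_exp with a free
    intercept, each SNP oriented so beta_exp >= 0.

    Returns (slope estimate, intercept estimate). The slope is the causal
    effect under the InSIDE assumption; a nonzero intercept indicates
    directional pleiotropy. SEs use multiplicative dispersion floored at 1
    and a t reference with m-2 degrees of freedom.
    """
    m = len(h)
    if m < 3:
        raise ValueError("mr_egger: need at least 3 SNPs")
    sign = np.where(h.beta_exp < 0, -1.0, 1.0)
    bx = h.beta_exp * sign
    by = h.beta_out * sign
    w = 1.0 / h.se_out**2
    X = np.column_stack([np.ones(m), bx])
    XtW = X.T * w
    xtwx_inv = np.linalg.inv(XtW @ X)
    coef = xtwx_inv @ (XtW @ by)
    resid = by - X @ coef
    sigma2 = float(np.sum(w * resid**2) / (m - 2))
    cov = xtwx_inv * max(1.0, sigma2)
    se = np.sqrt(np.diag(cov))
    tdist = st.t(m - 2)
    p = 2.0 * tdist.sf(np.abs(coef / se))
    slope = MREstimate("mr_egger", float(coef[1]), float(se[1]), float(p[1]), m)
    intercept = MREstimate("mr_egger_intercept", float(coef[0]), float(se[0]), float(p[0]), m)
    slope.diagnostics.update(intercept=float(coef[0]), intercept_se=float(se[0]),
                             intercept_p=float(p[0]))
    return slope, intercept


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int | None = None) -> MREstimate:
    """Weighted-median estimator, consistent while valid instruments carry
    more than half the weight.

    Wald ratios are ordered; with inverse-variance weights normalised to
    sum 1, the estimate interpolates the ratio at cumulative weight 0.5.
    The SE comes from a seeded parametric bootstrap that resamples
    beta_exp and beta_out from normals with the reported SEs.
    """
    m = len(h)
    if m < 3:
        raise ValueError("weighted_median: need at least 3 SNPs")

    def _wm(bx, by):
        theta = by / bx
        w = bx**2 / h.se_out**2
        order = np.argsort(theta)
        theta, w = theta[order], w[order]
        cw = np.cumsum(w) - 0.5 * w
        cw = cw / np.sum(w)
        return float(np.interp(0.5, cw, theta))

    beta = _wm(h.beta_exp, h.beta_out)
    rng = np.random.default_rng(seed)
    draws = np.empty(n_boot)
    for b in range(n_boot):
        bx = rng.normal(h.beta_exp, h.se_exp)
        by = rng.normal(h.beta_out, h.se_out)
        draws[b] = _wm(bx, by)
    se = float(np.std(draws, ddof=1)) if n_boot > 1 else float("nan")
    p = 2.0 * st.norm.sf(abs(beta) / se) if np.isfinite(se) and se > 0 else float("nan")
    return MREstimate("weighted_median", beta, se, float(p), m)


def _loo_ivw_beta(bx, by, se_out):
    """Leave-one-out fixed-effect IVW estimates, vectorised."""
    w = bx**2 / se_out**2
    theta = by / bx
    sw, swt = np.sum(w), np.sum(w * theta)
    return (swt - w * theta) / (sw - w)


def mr_presso(
    h: HarmonizedSet,
    n_sim: int = 10_000,
    outlier_alpha: float = 0.05,
    seed: int | None = None,
    significance_threshold: float | None = None,
) -> PressoResult:
    """MR-PRESSO: pleiotropy residual sum and outlier test.

    Global test: the observed weighted residual sum of squares of each SNP
    against its leave-one-out IVW prediction is compared with a parametric
    simulated null (n_sim seeded draws of beta_exp/beta_out around their
    expected values); the empirical p has floor 1/n_sim. Outlier test:
    each SNP's observed residual against its own simulated distribution,
    Bonferroni-corrected. Distortion test: the shift in the IVW estimate
    after outlier removal is compared with the shift produced by replacing
    the outliers with resampled inliers.
    """
    m = len(h)
    if m < 4:
        raise ValueError("mr_presso: need at least 4 SNPs")
    if significance_threshold is not None and 1.0 / n_sim > significance_threshold:
        warnings.warn(
            f"mr_presso: n_sim={n_sim} cannot resolve p below {1.0/n_sim:.2e} "
            f"(requested threshold {significance_threshold:.2e})"
        )
    rng = np.random.default_rng(seed)
    bx, by, sx, sy = h.beta_exp, h.beta_out, h.se_exp, h.se_out
    w = 1.0 / sy**2

    beta_loo = _loo_ivw_beta(bx, by, sy)
    resid_obs = w * (by - beta_loo * bx) ** 2
    rss_obs = float(np.sum(resid_obs))

    # simulated null: data consistent with the leave-one-out causal model
    bx_sim = rng.normal(bx, sx, size=(n_sim, m))
    by_sim = rng.normal(beta_loo * bx, sy, size=(n_sim, m))
    w_sim = w[None, :]
    wsum = np.sum(bx_sim**2 * w_sim, axis=1)
    wtheta = np.sum(bx_sim * by_sim * w_sim, axis=1)
    # vectorised LOO IVW on simulated data
    beta_loo_sim = (wtheta[:, None] - bx_sim * by_sim * w_sim) / (
        wsum[:, None] - bx_sim**2 * w_sim
    )
    resid_sim = w_sim * (by_sim - beta_loo_sim * bx_sim) ** 2
    rss_sim = np.sum(resid_sim, axis=1)
    global_p = max(float(np.mean(rss_sim >= rss_obs)), 1.0 / n_sim)

    outliers: list = []
    distortion_p = None
    corrected = None
    outlier_p = np.minimum(np.mean(resid_sim >= resid_obs[None, :], axis=0) * m, 1.0)
    outlier_p = np.maximum(outlier_p, m / n_sim)
    if global_p < outlier_alpha:
        mask = outlier_p < outlier_alpha
        outliers = list(h.table.loc[mask, "rsid"])
        if outliers and mask.sum() < m:
            inl = ~mask
            sub = HarmonizedSet(h.table.loc[inl].reset_index(drop=True),
                                h.actions)
            corrected = ivw(sub)
            beta_all = ivw(h).beta
            d_obs = beta_all - corrected.beta
            n_out = int(mask.sum())
            inl_idx = np.nonzero(inl)[0]
            n_d = min(n_sim, 2000)
            d_null = np.empty(n_d)
            for b in range(n_d):
                repl = rng.choice(inl_idx, size=n_out, replace=True)
                idx = np.concatenate([inl_idx, repl])
                bset, _, _, _ = _ivw_core(bx[idx], sx[idx], by[idx], sy[idx])
                d_null[b] = bset - corrected.beta
            distortion_p = float(np.mean(np.abs(d_null) >= abs(d_obs)))
    res = PressoResult(rss_obs, global_p, outliers, corrected, distortion_p)
    return res


def mvmr(
    beta_exp: pd.DataFrame,
    beta_out,
    se_out,
    exposures: list | None = None,
) -> list[MREstimate]:
    """Multivariable MR: zero-intercept weighted regression of the outcome
    effects on the matrix of exposure effects (one column per exposure,
    e.g. a liver enzyme and BMI), weights 1/se_out².

    Returns one estimate per exposure: its direct effect on the outcome
    conditional on the other exposures. SEs use multiplicative dispersion
    floored at 1 with m - k residual degrees of freedom.
    """
    X = np.asarray(beta_exp, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(beta_out, dtype=float)
    sy = np.asarray(se_out, dtype=float)
    m, k = X.shape
    if exposures is None:
        exposures = list(beta_exp.columns) if isinstance(beta_exp, pd.DataFrame) else [
            f"exposure{i+1}" for i in range(k)
        ]
    # an exposure with no genetic signal at these instruments is dropped
    # from the regression (its direct effect is unidentified), whereas a
    # genuinely rank-deficient design (e.g. duplicated columns) is an error
    active = [j for j in range(k) if np.any(X[:, j] != 0)]
    Xa = X[:, active]
    ka = len(active)
    if ka == 0:
        raise ValueError("mvmr: all exposure effects are zero")
    if np.linalg.matrix_rank(Xa) < ka:
        raise ValueError("mvmr: rank-deficient exposure-effect matrix")
    if m <= ka:
        raise ValueError("mvmr: more exposures than instruments")
    w = 1.0 / sy**2
    XtW = Xa.T * w
    xtwx_inv = np.linalg.inv(XtW @ Xa)
    coef = xtwx_inv @ (XtW @ y)
    resid = y - Xa @ coef
    sigma2 = float(np.sum(w * resid**2) / (m - ka))
    cov = xtwx_inv * max(1.0, sigma2)
    se = np.sqrt(np.diag(cov))
    out = []
    pos = {j: i for i, j in enumerate(active)}
    for j, name in enumerate(exposures):
        if j in pos:
            i = pos[j]
            p = 2.0 * st.norm.sf(abs(coef[i]) / se[i])
            est = MREstimate("mvmr", float(coef[i]), float(se[i]), float(p), m)
        else:
            est = MREstimate("mvmr", float("nan"), float("nan"), float("nan"), m)
            est.diagnostics["flag"] = "no instrument signal for this exposure"
        est.diagnostics["exposure"] = name
        out.append(est)
    return out
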