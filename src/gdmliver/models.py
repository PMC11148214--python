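"""Statistical models for the cohort arm.

Adjusted quartile logistic models with median-assigned trend tests,
restricted-cubic-spline (RCS) nonlinearity screening of biomarker vs OGTT
glucose with a segmented fallback, multinomial models for GDM subtypes,
a descriptive baseline table, and multiplicative crossover interaction
between a liver index and a lipid.

Model fitting is delegated to statsmodels (logit / OLS / multinomial logit);
this module owns the design construction (quartile coding, RCS basis,
hinge terms), the contrasts and the tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .cohort import bmi_category, quartile_bin, QuartileBins

__all__ = [
    "ORResult",
    "QuartileLogisticResult",
    "RcsFit",
    "PiecewiseFit",
    "InteractionResult",
    "DEFAULT_COVARIATES",
    "baseline_table",
    "rcs_basis",
    "fit_quartile_logistic",
    "fit_rcs",
    "fit_piecewise",
    "fit_subtype_multinomial",
    "crossover_interaction",
]

Z95 = st.norm.ppf(0.975)

# adjustment set used throughout the cohort arm
DEFAULT_COVARIATES = (
    "age",
    "bmi",
    "education",
    "gravidity",
    "parity",
    "weight_gain",
    "ga_weeks",
    "smoking",
    "alcohol",
)

EDUCATION_ORDER = ("primary-or-below", "middle", "high", "college-or-above")


@dataclass
class ORResult:
    exposure: str
    contrast: str
    or_point: float
    ci_low: float
    ci_high: float
    p_value: float
    n_cases: int = 0
    n_total: int = 0
    flag: str | None = None


@dataclass
class QuartileLogisticResult:
    exposure: str
    results: list  # ORResult for Q2..Q4 vs Q1
    p_trend: float
    trend_or: float
    bins: QuartileBins


@dataclass
class RcsFit:
    exposure: str
    outcome: str
    knots: np.ndarray
    coef: pd.Series
    p_nonlinear: float
    chosen: str  # "linear" | "piecewise"
    breakpoint: float | None = None
    linear_slope: float | None = None
    linear_slope_se: float | None = None


@dataclass
class PiecewiseFit:
    exposure: str
    outcome: str
    breakpoint: float | None
    slope_below: float
    slope_above: float
    se_below: float
    se_above: float
    fallback_linear: bool = False


@dataclass
class InteractionResult:
    lfi: str
    lipid: str
    cuts: tuple
    cell_or: dict  # (lfi_level, lipid_level) -> (or, lo, hi)
    p_interaction: float
    n_cells: dict = field(default_factory=dict)
    flag: str | None = None


# ---------------------------------------------------------------------------
# design-matrix helpers


def _covariate_matrix(records: pd.DataFrame, covariates, exposure: str | None = None) -> pd.DataFrame:
    """Numeric covariate design columns (no intercept).

    Education enters as an ordinal integer; smoking and alcohol as
    categorical dummies with 'unknown' kept as its own level; BMI enters
    as category dummies instead of a continuous term when the exposure is
    the hepatic steatosis index (which already contains BMI).
    """
    cols = {}
    for cov in covariates:
        if cov == "education":
            s = records["education"]
            if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
                codes = s.map({lab: i for i, lab in enumerate(EDUCATION_ORDER)})
                if codes.isna().any():
                    raise ValueError("unknown education level")
                cols["education_ord"] = codes.astype(float)
            else:
                cols["education_ord"] = s.astype(float)
        elif cov in ("smoking", "alcohol"):
            d = pd.get_dummies(records[cov].astype(str), prefix=cov, drop_first=True, dtype=float)
            for c in d.columns:
                cols[c] = d[c]
        elif cov == "bmi" and exposure == "hsi":
            cats = records["bmi_category"] if "bmi_category" in records else bmi_category(records["bmi"])
            d = pd.get_dummies(cats, prefix="bmi_cat", drop_first=True, dtype=float)
            for c in d.columns:
                cols[c] = d[c]
        else:
            cols[cov] = records[cov].astype(float)
    return pd.DataFrame(cols, index=records.index)


def _wald_or(params, bse, pvalues, name, exposure, contrast, n_cases, n_total, flag=None):
    b, se = params[name], bse[name]
    if not np.isfinite(se) or se > 1e3:
        return ORResult(exposure, contrast, float(np.exp(b)), 0.0, np.inf, np.nan,
                        n_cases, n_total, flag or "quasi-separation")
    return ORResult(
        exposure,
        contrast,
        float(np.exp(b)),
        float(np.exp(b - Z95 * se)),
        float(np.exp(b + Z95 * se)),
        float(pvalues[name]),
        n_cases,
        n_total,
        flag,
    )


def _fit_logit(y, X):
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.GLM(y, Xc, family=sm.families.Binomial()).fit(maxiter=200)


# ---------------------------------------------------------------------------
# baseline description


def baseline_table(
    records: pd.DataFrame,
    group: pd.Series,
    continuous=("age", "bmi", "weight_gain", "alt", "ast", "ggt", "alp", "ast_alt_ratio", "hsi"),
    categorical=("gravidity_cat", "parity_cat", "smoking", "alcohol"),
    ordinal=("education",),
) -> pd.DataFrame:
    """Descriptive comparison of the two diagnosis groups.

    Continuous variables as median (IQR), compared by Mann-Whitney rank-sum;
    categorical as N (column %), compared by chi-square over all levels;
    ordinal variables (education) as N (%) compared by rank-sum on the
    ordinal codes. ``group`` is the boolean GDM indicator.

    Output: one row per variable/level with formatted cells, the raw counts
    and percentages, and the between-group p-value on the variable's first row.
    """
    group = group.astype(bool)
    n1, n0 = int(group.sum()), int((~group).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("baseline_table: empty group")
    rows = []

    def _fmt_med(s):
        med, lo, hi = s.median(), s.quantile(0.25), s.quantile(0.75)
        return f"{med:.1f} ({lo:.1f}, {hi:.1f})"

    for var in continuous:
        if var not in records:
            continue
        a = records.loc[group, var].dropna()
        b = records.loc[~group, var].dropna()
        p = st.mannwhitneyu(a, b, alternative="two-sided").pvalue if len(a) and len(b) else np.nan
        rows.append(dict(variable=var, level="", group1=_fmt_med(a), group0=_fmt_med(b),
                         count1=np.nan, pct1=np.nan, count0=np.nan, pct0=np.nan, p=p))

    def _cat_rows(var, levels, s, ptest):
        ct = pd.crosstab(s, group)
        ct = ct.reindex(index=levels, fill_value=0)
        p = ptest(ct)
        for i, lev in enumerate(levels):
            c1 = int(ct.loc[lev, True]) if True in ct else 0
            c0 = int(ct.loc[lev, False]) if False in ct else 0
            pct1, pct0 = 100.0 * c1 / n1, 100.0 * c0 / n0
            rows.append(dict(variable=var, level=str(lev),
                             group1=f"{c1} ({pct1:.1f})", group0=f"{c0} ({pct0:.1f})",
                             count1=c1, pct1=pct1, count0=c0, pct0=pct0,
                             p=p if i == 0 else np.nan))

    def _chi2(ct):
        tab = ct.to_numpy()
        tab = tab[tab.sum(axis=1) > 0]
        if tab.shape[0] < 2:
            return np.nan
        return st.chi2_contingency(tab).pvalue

    for var in categorical:
        if var == "gravidity_cat" and "gravidity" in records:
            s = np.where(records["gravidity"] >= 2, ">=2", "1")
            _cat_rows("gravidity", ["1", ">=2"], pd.Series(s, index=records.index), _chi2)
        elif var == "parity_cat" and "parity" in records:
            s = np.where(records["parity"] >= 1, ">=1", "0")
            _cat_rows("parity", ["0", ">=1"], pd.Series(s, index=records.index), _chi2)
        elif var in records:
            levels = sorted(records[var].astype(str).unique())
            _cat_rows(var, levels, records[var].astype(str), _chi2)

    for var in ordinal:
        if var not in records:
            continue
        codes = records[var].map({lab: i for i, lab in enumerate(EDUCATION_ORDER)}) \
            if records[var].dtype == object else records[var].astype(float)

        def _ranksum(ct, codes=codes):
            a, b = codes[group].dropna(), codes[~group].dropna()
            return st.mannwhitneyu(a, b, alternative="two-sided").pvalue

        levels = [lab for lab in EDUCATION_ORDER if (records[var] == lab).any()] \
            if records[var].dtype == object else sorted(records[var].unique())
        _cat_rows(var, levels, records[var], _ranksum)

    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# quartile logistic model + trend


def fit_quartile_logistic(
    records: pd.DataFrame,
    exposure: str,
    outcome: str = "is_gdm",
    covariates=DEFAULT_COVARIATES,
) -> QuartileLogisticResult:
    """Adjusted logistic model of GDM on quartiles of one liver index.

    The exposure is binned into sample quartiles (Q1 reference); odds
    ratios are exp(coefficient) with Wald 95% CIs on the log scale.
    The linear-trend p-value comes from a second model in which each
    woman is assigned her quartile's median exposure value, entered as a
    continuous term (Wald test).

    A quartile cell with zero cases (or zero controls) is quasi-separated:
    the corresponding contrast is returned flagged with an infinite CI.
    """
    df = records.dropna(subset=[exposure, outcome]).copy()
    y = df[outcome].astype(float)
    q, bins = quartile_bin(df[exposure])
    X = _covariate_matrix(df, covariates, exposure=exposure)
    qd = pd.get_dummies(q, prefix="q", dtype=float)
    labels = [c for c in ("q_Q2", "q_Q3", "q_Q4") if c in qd.columns]
    Xq = pd.concat([qd[labels], X], axis=1)

    cell_cases = y.groupby(q, observed=False).sum()
    cell_n = y.groupby(q, observed=False).size()
    sep_flag = {
        lab: ("quasi-separation" if (cell_cases.get(lab, 0) == 0 or
                                     cell_cases.get(lab, 0) == cell_n.get(lab, 0)) else None)
        for lab in ("Q1", "Q2", "Q3", "Q4")
    }

    res = _fit_logit(y, Xq)
    out = []
    for lab in ("Q2", "Q3", "Q4"):
        name = f"q_{lab}"
        if name not in res.params.index:
            out.append(ORResult(exposure, f"{lab} vs Q1", np.nan, 0.0, np.inf, np.nan,
                                0, 0, "empty quartile"))
            continue
        out.append(
            _wald_or(res.params, res.bse, res.pvalues, name, exposure, f"{lab} vs Q1",
                     int(cell_cases.get(lab, 0)), int(cell_n.get(lab, 0)),
                     flag=sep_flag[lab] or sep_flag["Q1"])
        )

    med = q.map(bins.medians).astype(float)
    med.name = f"{exposure}_median_assigned"
    Xt = pd.concat([med, X], axis=1)
    rt = _fit_logit(y, Xt)
    p_trend = float(rt.pvalues[med.name])
    trend_or = float(np.exp(rt.params[med.name]))
    return QuartileLogisticResult(exposure, out, p_trend, trend_or, bins)


# ---------------------------------------------------------------------------
# restricted cubic splines and segmented regression


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted cubic spline basis (truncated power form).

    Columns: x itself plus k-2 nonlinear terms that force the function to
    be linear beyond the boundary knots (zero second derivative outside).
    Nonlinear terms are scaled by the squared knot span for conditioning.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    k = len(t)
    if k < 3:
        raise ValueError("need at least 3 knots")
    span2 = (t[-1] - t[0]) ** 2

    def plus3(u):
        return np.clip(u, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        term = (
            plus3(x - t[j])
            - plus3(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + plus3(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        )
        cols.append(term / span2)
    return np.column_stack(cols)


def default_knots(x, n_knots: int = 4) -> np.ndarray:
    """Knots at the 5th/35th/65th/95th percentiles (4-knot default);
    equally spaced in probability between 5 and 95 otherwise."""
    probs = np.linspace(5, 95, n_knots)
    return np.percentile(np.asarray(x, dtype=float), probs)


def fit_rcs(
    records: pd.DataFrame,
    exposure: str,
    outcome: str,
    covariates=DEFAULT_COVARIATES,
    n_knots: int = 4,
    run_piecewise: bool = True,
) -> RcsFit:
    """Test for a non-linear biomarker-glucose relationship with an RCS.

    Fits a linear model of the continuous glucose outcome on the RCS
    expansion of the exposure plus covariates; p_nonlinear is the
    likelihood-ratio test of the nonlinear spline terms against the plain
    linear term. If p_nonlinear >= 0.05 the linear model is retained,
    otherwise a single-breakpoint segmented model is fit.
    """
    df = records.dropna(subset=[exposure, outcome]).copy()
    if len(df) < 50:
        raise ValueError("fit_rcs: fewer than 50 observations; spline basis unstable")
    x = df[exposure].to_numpy(dtype=float)
    knots = default_knots(x, n_knots)
    if len(np.unique(knots)) < n_knots:
        raise ValueError("fit_rcs: degenerate knots (too many ties)")
    basis = rcs_basis(x, knots)
    names = [exposure] + [f"{exposure}_rcs{j}" for j in range(1, n_knots - 1)]
    B = pd.DataFrame(basis, columns=names, index=df.index)
    X = _covariate_matrix(df, covariates, exposure=exposure)
    y = df[outcome].astype(float)

    full = sm.OLS(y, sm.add_constant(pd.concat([B, X], axis=1), has_constant="add")).fit()
    lin = sm.OLS(y, sm.add_constant(pd.concat([B[[exposure]], X], axis=1), has_constant="add")).fit()
    lr = 2.0 * (full.llf - lin.llf)
    p_nonlin = float(st.chi2.sf(max(lr, 0.0), n_knots - 2))

    fit = RcsFit(
        exposure=exposure,
        outcome=outcome,
        knots=knots,
        coef=full.params,
        p_nonlinear=p_nonlin,
        chosen="linear" if p_nonlin >= 0.05 else "piecewise",
        linear_slope=float(lin.params[exposure]),
        linear_slope_se=float(lin.bse[exposure]),
    )
    if fit.chosen == "piecewise" and run_piecewise:
        pw = fit_piecewise(df, exposure, outcome, covariates)
        fit.breakpoint = pw.breakpoint
    return fit


def fit_piecewise(
    records: pd.DataFrame,
    exposure: str,
    outcome: str,
    covariates=DEFAULT_COVARIATES,
    grid_size: int = 81,
) -> PiecewiseFit:
    """Single-breakpoint segmented linear model, continuous at the break.

    The breakpoint is profiled over a grid of exposure percentiles
    (10th-90th), choosing the residual-sum-of-squares minimiser; the model
    is y = a + b1*x + b2*(x - c)+ + covariates, so the slopes below/above
    are b1 and b1 + b2. If no interior breakpoint improves on the plain
    linear fit, the linear fit is returned with a warning.
    """
    df = records.dropna(subset=[exposure, outcome]).copy()
    x = df[exposure].to_numpy(dtype=float)
    y = df[outcome].astype(float)
    X = _covariate_matrix(df, covariates, exposure=exposure)

    lin = sm.OLS(y, sm.add_constant(pd.concat(
        [pd.Series(x, index=df.index, name=exposure), X], axis=1), has_constant="add")).fit()

    candidates = np.unique(np.percentile(x, np.linspace(10, 90, grid_size)))
    candidates = [c for c in candidates if (x < c).sum() >= 3 and (x > c).sum() >= 3]
    if not candidates:
        warnings.warn("fit_piecewise: no admissible interior breakpoint; returning linear fit")
        return PiecewiseFit(exposure, outcome, None,
                            float(lin.params[exposure]), float(lin.params[exposure]),
                            float(lin.bse[exposure]), float(lin.bse[exposure]),
                            fallback_linear=True)

    best = None
    for c in candidates:
        hinge = np.clip(x - c, 0.0, None)
        D = pd.concat([pd.Series(x, index=df.index, name=exposure),
                       pd.Series(hinge, index=df.index, name="hinge"), X], axis=1)
        r = sm.OLS(y, sm.add_constant(D, has_constant="add")).fit()
        rss = float(np.sum(r.resid ** 2))
        if best is None or rss < best[0]:
            best = (rss, c, r)

    rss_lin = float(np.sum(lin.resid ** 2))
    rss_pw, c, r = best
    if rss_pw >= rss_lin * (1 - 1e-10):
        warnings.warn("fit_piecewise: flat RSS profile; returning linear fit")
        return PiecewiseFit(exposure, outcome, None,
                            float(lin.params[exposure]), float(lin.params[exposure]),
                            float(lin.bse[exposure]), float(lin.bse[exposure]),
                            fallback_linear=True)

    b1, b2 = float(r.params[exposure]), float(r.params["hinge"])
    cov = r.cov_params()
    se_below = float(np.sqrt(cov.loc[exposure, exposure]))
    se_above = float(np.sqrt(cov.loc[exposure, exposure] + cov.loc["hinge", "hinge"]
                             + 2 * cov.loc[exposure, "hinge"]))
    return PiecewiseFit(exposure, outcome, float(c), b1, b1 + b2, se_below, se_above)


# ---------------------------------------------------------------------------
# subtype multinomial model


def fit_subtype_multinomial(
    records: pd.DataFrame,
    exposure: str,
    covariates=DEFAULT_COVARIATES,
    subtype_col: str = "subtype",
) -> dict:
    """Multinomial logit of GDM subtype (i-IFG / i-IGT / b-GDM vs non-GDM)
    on exposure quartiles plus covariates.

    Returns ``{subtype: [ORResult Q2..Q4 vs Q1]}``; a subtype with no cases
    is omitted with a warning.
    """
    df = records.dropna(subset=[exposure, subtype_col]).copy()
    order = ["none", "i-IFG", "i-IGT", "b-GDM"]
    present = [s for s in order if (df[subtype_col] == s).any()]
    missing = [s for s in order[1:] if s not in present]
    if missing:
        warnings.warn(f"fit_subtype_multinomial: empty subtype cell(s) {missing}; omitted")
    if "none" not in present or len(present) < 2:
        raise ValueError("need the non-GDM reference and at least one subtype")
    code = df[subtype_col].map({s: i for i, s in enumerate(present)}).astype(int)

    q, bins = quartile_bin(df[exposure])
    qd = pd.get_dummies(q, prefix="q", dtype=float)
    labels = [c for c in ("q_Q2", "q_Q3", "q_Q4") if c in qd.columns]
    C = _covariate_matrix(df, covariates, exposure=exposure)
    # centre/scale covariates for Newton stability; the quartile-dummy
    # coefficients (the reported contrasts) are invariant to this
    C = (C - C.mean()) / C.std().replace(0.0, 1.0)
    X = pd.concat([qd[labels], C], axis=1)
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.MNLogit(code, Xc).fit(disp=0, maxiter=300)
        if np.isnan(res.params.to_numpy()).any():
            res = sm.MNLogit(code, Xc).fit(method="bfgs", disp=0, maxiter=1000)
        params = res.params  # columns: categories 1..k-1 in `present` order
        bse = res.bse
        pvals = res.pvalues

    out = {}
    for j, subtype in enumerate(present[1:]):
        rows = []
        mask = code.isin([0, j + 1])
        for lab in ("Q2", "Q3", "Q4"):
            name = f"q_{lab}"
            if name not in params.index:
                continue
            b = float(params.loc[name, j])
            se = float(bse.loc[name, j])
            n_cases = int(((code == j + 1) & (q == lab)).sum())
            n_total = int((mask & (q == lab)).sum())
            if not np.isfinite(se) or se > 1e3:
                rows.append(ORResult(exposure, f"{lab} vs Q1", float(np.exp(b)), 0.0, np.inf,
                                     np.nan, n_cases, n_total, "quasi-separation"))
            else:
                rows.append(ORResult(exposure, f"{lab} vs Q1", float(np.exp(b)),
                                     float(np.exp(b - Z95 * se)), float(np.exp(b + Z95 * se)),
                                     float(pvals.loc[name, j]), n_cases, n_total))
        out[subtype] = rows
    return out


# ---------------------------------------------------------------------------
# crossover interaction


def crossover_interaction(
    records: pd.DataFrame,
    lfi: str,
    lipid: str,
    outcome: str = "is_gdm",
    covariates=DEFAULT_COVARIATES,
    cuts: tuple | None = None,
) -> InteractionResult:
    """Joint-effect and multiplicative-interaction analysis of a liver index
    and a lipid on GDM.

    Both variables are dichotomised (default: at their sample medians; the
    cut points are configurable). A logistic model with both main effects,
    their product and the covariates gives the four joint-category odds
    ratios against the low/low reference; p_interaction is the Wald p of
    the product term.
    """
    df = records.dropna(subset=[lfi, lipid, outcome]).copy()
    if cuts is None:
        cuts = (float(df[lfi].median()), float(df[lipid].median()))
    a = (df[lfi] > cuts[0]).astype(float)
    b = (df[lipid] > cuts[1]).astype(float)
    y = df[outcome].astype(float)

    n_cells = {
        (ai, bi): int(((a == ai) & (b == bi)).sum()) for ai in (0, 1) for bi in (0, 1)
    }
    flag = "empty cell" if any(v == 0 for v in n_cells.values()) else None

    X = pd.concat(
        [a.rename("lfi_high"), b.rename("lipid_high"), (a * b).rename("lfi_x_lipid"),
         _covariate_matrix(df, covariates, exposure=lfi)],
        axis=1,
    )
    res = _fit_logit(y, X)
    p_int = float(res.pvalues["lfi_x_lipid"])
    cov = res.cov_params()

    def cell(vec, names):
        bhat = sum(res.params[n] * v for n, v in zip(names, vec))
        var = 0.0
        for n1, v1 in zip(names, vec):
            for n2, v2 in zip(names, vec):
                var += v1 * v2 * cov.loc[n1, n2]
        se = np.sqrt(var)
        return (float(np.exp(bhat)), float(np.exp(bhat - Z95 * se)), float(np.exp(bhat + Z95 * se)))

    names = ["lfi_high", "lipid_high", "lfi_x_lipid"]
    cell_or = {
        ("low", "low"): (1.0, 1.0, 1.0),
        ("high", "low"): cell((1, 0, 0), names),
        ("low", "high"): cell((0, 1, 0), names),
        ("high", "high"): cell((1, 1, 1), names),
    }
    return InteractionResult(lfi, lipid, cuts, cell_or, p_int, n_cells, flag)
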