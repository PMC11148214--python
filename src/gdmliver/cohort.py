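"""Cohort-arm domain logic: inclusion/exclusion, derived liver indices,
GDM diagnosis and subtyping, quartile binning.

The cohort is a table of pregnant women with first-trimester (8-14 weeks)
liver function tests (ALT, AST, GGT, ALP in U/L), lipids (mmol/L), covariates
and a 24-28 week 75 g OGTT (fasting, 1-h and 2-h post-load glucose, mmol/L).
All derivations here are deterministic; statistical models live in
:mod:`gdmliver.models`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GDM_THRESHOLDS",
    "EXCLUSION_BOUNDS",
    "CLINICAL_BOUNDS",
    "HISTORY_FLAGS",
    "BMI_BIN_EDGES",
    "OVERWEIGHT_BMI",
    "GdmStatus",
    "compute_hsi",
    "diagnose_gdm",
    "classify_gdm",
    "apply_inclusion_exclusion",
    "clinical_range_filter",
    "quartile_bin",
    "bmi_category",
    "add_derived_biomarkers",
]

# OGTT diagnostic cut-offs (mmol/L), inclusive: any value at or above flags GDM.
GDM_THRESHOLDS = {"fbg": 5.1, "pbg1h": 10.0, "pbg2h": 8.5}

# Abnormally elevated liver enzymes excluded at enrolment (U/L, strictly above).
EXCLUSION_BOUNDS = {"alt": 90.0, "ast": 80.0, "ggt": 90.0, "alp": 240.0}

# Clinical reference upper bounds (U/L, strictly above) for sensitivity reruns.
CLINICAL_BOUNDS = {"alt": 45.0, "ast": 40.0, "ggt": 45.0, "alp": 120.0}

# Pre-existing conditions that exclude a participant.
HISTORY_FLAGS = frozenset({"hypertension", "diabetes", "heart", "hepatobiliary", "kidney"})

# First-trimester BMI categories (kg/m^2): <18.5, 18.5-23.9, 24.0-27.9, >=28.
BMI_BIN_EDGES = (18.5, 24.0, 28.0)
BMI_BIN_LABELS = ("<18.5", "18.5-23.9", "24.0-27.9", ">=28")
OVERWEIGHT_BMI = 24.0

LIVER_ENZYMES = ("alt", "ast", "ggt", "alp")
GLUCOSE_CHANNELS = ("fbg", "pbg1h", "pbg2h")

SUBTYPES = ("none", "i-IFG", "i-IGT", "b-GDM")


@dataclass(frozen=True)
class GdmStatus:
    """Diagnosis of one participant from the three OGTT glucose values."""

    is_gdm: bool
    subtype: str  # one of SUBTYPES
    fbg_high: bool
    pbg1h_high: bool
    pbg2h_high: bool


def compute_hsi(alt, ast, bmi, female=True):
    """Hepatic steatosis index: 8 * ALT/AST + BMI + 2 if female.

    A non-invasive fatty-liver screen. Accepts scalars or arrays; all inputs
    must be strictly positive.
    """
    alt = np.asarray(alt, dtype=float)
    ast = np.asarray(ast, dtype=float)
    bmi = np.asarray(bmi, dtype=float)
    if np.any(alt <= 0) or np.any(ast <= 0) or np.any(bmi <= 0):
        raise ValueError("alt, ast and bmi must all be strictly positive")
    out = 8.0 * alt / ast + bmi + np.where(np.asarray(female, dtype=bool), 2.0, 0.0)
    return float(out) if out.ndim == 0 else out


def diagnose_gdm(fbg: float, pbg1h: float, pbg2h: float) -> GdmStatus:
    """Diagnose GDM and its subtype from one OGTT.

    Cut-offs are inclusive: fasting >= 5.1, 1-h >= 10.0, 2-h >= 8.5 mmol/L.
    Subtypes: isolated impaired fasting glucose (i-IFG, fasting only),
    isolated impaired glucose tolerance (i-IGT, any post-load value only),
    b-GDM (both fasting and post-load elevated).

    Raises ``ValueError`` on missing or non-positive values; an incomplete
    OGTT yields no diagnosis rather than a silent non-GDM label.
    """
    vals = (fbg, pbg1h, pbg2h)
    if any(v is None or not np.isfinite(v) for v in vals):
        raise ValueError("incomplete OGTT: diagnosis unavailable")
    if any(v <= 0 for v in vals):
        raise ValueError("glucose values must be positive")
    f = fbg >= GDM_THRESHOLDS["fbg"]
    p1 = pbg1h >= GDM_THRESHOLDS["pbg1h"]
    p2 = pbg2h >= GDM_THRESHOLDS["pbg2h"]
    pbg = p1 or p2
    if f and pbg:
        subtype = "b-GDM"
    elif f:
        subtype = "i-IFG"
    elif pbg:
        subtype = "i-IGT"
    else:
        subtype = "none"
    return GdmStatus(is_gdm=f or pbg, subtype=subtype, fbg_high=f, pbg1h_high=p1, pbg2h_high=p2)


def classify_gdm(records: pd.DataFrame) -> pd.DataFrame:
    """Vectorised GDM diagnosis for a cohort table.

    Returns a DataFrame aligned to ``records`` with boolean component flags,
    ``is_gdm`` and ``subtype``. Rows with any missing glucose value get
    ``subtype = NaN`` and ``diagnosis_missing = True``; they must be excluded
    upstream, never treated as non-GDM.
    """
    fbg = records["fbg"].to_numpy(dtype=float)
    p1 = records["pbg1h"].to_numpy(dtype=float)
    p2 = records["pbg2h"].to_numpy(dtype=float)
    missing = ~(np.isfinite(fbg) & np.isfinite(p1) & np.isfinite(p2))
    f = fbg >= GDM_THRESHOLDS["fbg"]
    h1 = p1 >= GDM_THRESHOLDS["pbg1h"]
    h2 = p2 >= GDM_THRESHOLDS["pbg2h"]
    pbg = h1 | h2
    subtype = np.where(
        f & pbg, "b-GDM", np.where(f, "i-IFG", np.where(pbg, "i-IGT", "none"))
    ).astype(object)
    subtype[missing] = np.nan
    out = pd.DataFrame(
        {
            "fbg_high": f & ~missing,
            "pbg1h_high": h1 & ~missing,
            "pbg2h_high": h2 & ~missing,
            "is_gdm": (f | pbg) & ~missing,
            "subtype": subtype,
            "diagnosis_missing": missing,
        },
        index=records.index,
    )
    return out


def _has_history(hx) -> bool:
    if hx is None or (isinstance(hx, float) and np.isnan(hx)):
        return False
    if isinstance(hx, str):
        flags = {tok.strip() for tok in hx.split(";") if tok.strip()}
    else:
        flags = set(hx)
    return bool(flags & HISTORY_FLAGS)


def apply_inclusion_exclusion(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the enrolment exclusions, in order, logging the first reason.

    Drops, in order: (1) missing liver tests or missing OGTT evaluation;
    (2) history of hypertensive disorders, diabetes, heart, hepatobiliary or
    kidney disease; (3) abnormally elevated liver enzymes (ALT > 90,
    AST > 80, GGT > 90 or ALP > 240 U/L; bounds are strict, a value exactly
    at the bound is retained).

    Returns ``(retained, attrition)`` where attrition has columns
    ``id`` and ``reason``.
    """
    if records.empty:
        return records.copy(), pd.DataFrame(columns=["id", "reason"])

    liver = records[list(LIVER_ENZYMES)].apply(pd.to_numeric, errors="coerce")
    glucose = records[list(GLUCOSE_CHANNELS)].apply(pd.to_numeric, errors="coerce")
    missing = liver.isna().any(axis=1) | glucose.isna().any(axis=1)

    history = records["hx_flags"].map(_has_history) if "hx_flags" in records else pd.Series(
        False, index=records.index
    )

    elevated = pd.Series(False, index=records.index)
    for enz, bound in EXCLUSION_BOUNDS.items():
        elevated |= liver[enz] > bound

    # first-matching-reason attribution, in enrolment order
    reason = pd.Series(pd.NA, index=records.index, dtype=object)
    reason[missing] = "missing liver tests or GDM evaluation"
    reason[history & reason.isna()] = "medical history"
    reason[elevated & reason.isna()] = "elevated liver enzymes"

    dropped = reason.notna()
    attrition = pd.DataFrame({"id": records.loc[dropped, "id"], "reason": reason[dropped]})
    return records.loc[~dropped].copy(), attrition.reset_index(drop=True)


def clinical_range_filter(records: pd.DataFrame) -> pd.DataFrame:
    """Drop records with any enzyme strictly above the clinical reference
    range (ALT > 45, AST > 40, GGT > 45, ALP > 120 U/L). Sensitivity use only."""
    if records.empty:
        return records.copy()
    keep = pd.Series(True, index=records.index)
    for enz, bound in CLINICAL_BOUNDS.items():
        keep &= ~(pd.to_numeric(records[enz], errors="coerce") > bound)
    return records.loc[keep].copy()


@dataclass
class QuartileBins:
    """Quartile partition of one biomarker: interpolated cut points plus the
    observed (min, max) of each occupied bin, the form results are reported in."""

    cut_points: tuple[float, float, float]
    observed_ranges: dict = field(default_factory=dict)
    medians: dict = field(default_factory=dict)


def quartile_bin(values) -> tuple[pd.Series, QuartileBins]:
    """Assign Q1..Q4 labels by sample quartiles.

    Cut points are the 25th/50th/75th percentiles (linear interpolation).
    Bins above Q1 are left-open/right-closed, so a value tied with a cut
    point goes to the lower bin. Requires at least 4 distinct values.
    """
    s = pd.Series(values).astype(float)
    if s.isna().any():
        raise ValueError("quartile_bin: missing values not allowed")
    if s.nunique() < 4:
        raise ValueError("quartile_bin: need at least 4 distinct values")
    q25, q50, q75 = np.percentile(s.to_numpy(), [25, 50, 75])
    if not (q25 < q75):
        raise ValueError("quartile_bin: degenerate quartiles (too many ties)")
    edges = [-np.inf, q25, q50, q75, np.inf]
    # pd.cut with duplicates dropped (q25==q50 or q50==q75 under heavy ties)
    uniq_edges, labels = [edges[0]], []
    all_labels = ["Q1", "Q2", "Q3", "Q4"]
    for i, e in enumerate(edges[1:]):
        if e > uniq_edges[-1]:
            uniq_edges.append(e)
            labels.append(all_labels[i])
    cats = pd.cut(s, bins=uniq_edges, labels=labels, right=True)
    cats = cats.cat.set_categories(all_labels)
    bins = QuartileBins(cut_points=(float(q25), float(q50), float(q75)))
    for lab in all_labels:
        sub = s[cats == lab]
        if len(sub):
            bins.observed_ranges[lab] = (float(sub.min()), float(sub.max()))
            bins.medians[lab] = float(sub.median())
    cats.name = getattr(values, "name", None) or "quartile"
    return cats, bins


def bmi_category(bmi) -> pd.Series:
    """First-trimester BMI category: <18.5, 18.5-23.9, 24.0-27.9, >=28 kg/m^2."""
    s = pd.Series(bmi).astype(float)
    edges = [-np.inf, *BMI_BIN_EDGES, np.inf]
    # right-open bins: 24.0 falls in "24.0-27.9"
    return pd.cut(s, bins=edges, labels=BMI_BIN_LABELS, right=False)


def add_derived_biomarkers(records: pd.DataFrame, female: bool = True) -> pd.DataFrame:
    """Return a copy of the cohort with hsi, ast_alt_ratio, bmi_category and
    overweight (BMI >= 24 kg/m^2) columns added."""
    out = records.copy()
    out["hsi"] = compute_hsi(out["alt"], out["ast"], out["bmi"], female=female)
    out["ast_alt_ratio"] = out["ast"] / out["alt"]
    out["bmi_category"] = bmi_category(out["bmi"])
    out["overweight"] = out["bmi"] >= OVERWEIGHT_BMI
    return out
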