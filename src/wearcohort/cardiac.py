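"""Cardiac MRI parameters versus wearable-derived physical activity.

Left ventricular mass (LVM) and left/right ventricular end-diastolic
volumes (LVEDV, RVEDV) are indexed to body surface area (Dubois formula);
aortic forward flow (AoF) is analysed raw with weight and height as extra
covariates. Linear models adjust for age, gender and systolic blood
pressure, restricting to outcome values within 2 SD of their mean. Average
daily steps enter either per 1,000 or binned into four activity categories
at the cohort's 10th/50th/90th percentiles. A logistic model estimates the
odds of abnormally high BSA-indexed LVM (gender-specific cutoffs, Chinese
ethnicity subset) for subjects in the upper quartile of daily steps.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .risk import ModelResult, _terms_frame

logger = logging.getLogger(__name__)

CARDIAC_PARAMS = ("lvm", "lvedv", "rvedv", "aof")
INDEXED_PARAMS = ("lvm", "lvedv", "rvedv")  # AoF is never BSA-indexed
HIGH_LVM_CUTOFF = {"male": 70.0, "female": 50.0}  # g/m², indexed LVM
CATEGORY_LABELS = ("I", "II", "III", "IV")


def dubois_bsa(weight_kg: float, height_cm: float) -> float:
    """Dubois body surface area, m²: 0.007184 · W^0.425 · H^0.725."""
    weight_kg = np.asarray(weight_kg, dtype=float)
    height_cm = np.asarray(height_cm, dtype=float)
    if np.any(weight_kg <= 0) or np.any(height_cm <= 0):
        raise ValueError("weight and height must be positive")
    out = 0.007184 * weight_kg**0.425 * height_cm**0.725
    return float(out) if out.ndim == 0 else out


def index_to_bsa(cardiac: pd.DataFrame) -> pd.DataFrame:
    """Add ``bsa`` and ``{param}_i`` columns (raw / BSA) for LVM, LVEDV, RVEDV."""
    out = cardiac.copy()
    out["bsa"] = dubois_bsa(out["weight"].to_numpy(), out["height"].to_numpy())
    for p in INDEXED_PARAMS:
        if p in out.columns:
            out[f"{p}_i"] = out[p] / out["bsa"]
    return out


def activity_categories(steps: pd.Series | np.ndarray) -> pd.Series:
    """Bin daily steps into categories I–IV at the 10th/50th/90th percentiles.

    Percentiles use linear interpolation between order statistics; boundary
    values fall into the lower category. An all-equal vector has degenerate
    cuts and raises.
    """
    s = pd.Series(np.asarray(steps, dtype=float))
    obs = s.dropna()
    if len(obs) < 10:
        raise ValueError("need at least 10 observed step values")
    p10, p50, p90 = np.quantile(obs, [0.10, 0.50, 0.90], method="linear")
    if not (p10 < p50 < p90):
        raise ValueError("degenerate percentile cuts (ties across cut points)")
    labels = pd.cut(
        s,
        bins=[-np.inf, p10, p50, p90, np.inf],
        labels=CATEGORY_LABELS,
        right=True,  # boundary value goes to the lower category
    )
    return labels


def two_sd_inclusion(values: pd.Series) -> pd.Series:
    """Mask of values within 2 SD of their mean (missing excluded)."""
    v = values.astype(float)
    mu, sd = v.mean(), v.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return v.notna()
    return ((v - mu).abs() <= 2 * sd).fillna(False)


def cardiac_model(
    data: pd.DataFrame,
    param: str,
    predictor: str = "steps",
    *,
    indexed: bool = True,
) -> ModelResult:
    """Linear model of one cardiac parameter on an activity predictor.

    ``predictor`` is one of ``'steps'`` (daily steps per 1,000),
    ``'category'`` (activity categories, Category I as reference) or
    ``'resting_hr'``. Covariates are age, gender and SBP, plus weight and
    height for AoF (which is analysed raw). The 2-SD inclusion rule is
    applied to the analysis-ready outcome before fitting.
    """
    outcome = param
    if indexed and param in INDEXED_PARAMS:
        outcome = f"{param}_i"
    covs = ["age", "gender", "sbp"]
    if param == "aof":
        covs += ["weight", "height"]

    df = data.copy()
    df = df[two_sd_inclusion(df[outcome])]
    if predictor == "steps":
        df["_x"] = df["daily_steps"] / 1000.0
        rhs = "_x"
    elif predictor == "resting_hr":
        df["_x"] = df["resting_hr"]
        rhs = "_x"
    elif predictor == "category":
        df["_x"] = pd.Categorical(activity_categories(df["daily_steps"]),
                                  categories=list(CATEGORY_LABELS))
        rhs = "_x"  # Category I becomes the reference level
    else:
        raise ValueError(f"unknown predictor {predictor!r}")
    df["gender"] = pd.Categorical(df["gender"], categories=["female", "male"])
    cols = [outcome, "_x", *covs]
    df = df[cols].dropna()
    formula = f"{outcome} ~ {' + '.join(covs)} + {rhs}"
    res = smf.ols(formula, data=df).fit()
    return ModelResult(f"{param}~{predictor}", _terms_frame(res, exponentiate=False),
                       int(res.nobs), bool(np.isfinite(res.bse).all()))


def high_lvm_model(data: pd.DataFrame, *, ethnicity: str = "Chinese") -> ModelResult:
    """Logistic model of abnormally high indexed LVM on upper-quartile activity.

    Restricted to one ethnicity (reference-range provenance); outcome is
    indexed LVM strictly above 70 g/m² (males) / 50 g/m² (females);
    predictor is an indicator of daily steps strictly above the subset's
    75th percentile.
    """
    df = data[data["ethnicity"] == ethnicity].copy()
    df = df.dropna(subset=["lvm_i", "gender", "daily_steps"])
    cutoff = df["gender"].map(HIGH_LVM_CUTOFF).astype(float)
    df["_high_lvm"] = (df["lvm_i"] > cutoff).astype(float)
    p75 = float(np.quantile(df["daily_steps"], 0.75, method="linear"))
    df["_upper_q"] = (df["daily_steps"] > p75).astype(float)
    n = len(df)
    if df["_high_lvm"].nunique() < 2:
        return ModelResult("high_lvm~upper_quartile", pd.DataFrame(), n, False,
                           "outcome has a single class")
    try:
        res = smf.glm("_high_lvm ~ _upper_q", data=df, family=sm.families.Binomial()).fit()
    except Exception as exc:
        return ModelResult("high_lvm~upper_quartile", pd.DataFrame(), n, False, f"fit failed: {exc}")
    if not np.isfinite(res.bse).all():
        return ModelResult("high_lvm~upper_quartile", pd.DataFrame(), n, False, "separation suspected")
    return ModelResult("high_lvm~upper_quartile", _terms_frame(res, exponentiate=True), n, True)
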