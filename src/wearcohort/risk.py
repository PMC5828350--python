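"""Cardiometabolic risk markers and their association with wearable metrics.

Nine clinical markers are dichotomised at commonly used thresholds (strict
inequalities; waist circumference is gender-specific). Associations with
wearable metrics use logistic regression: step-based metrics enter with a
gender interaction (``marker ~ age + gender + steps_k + gender:steps_k``,
steps scaled per 1,000, the interaction term reported), heart-rate metrics
as a main effect per bpm. Gender is coded with female as the reference
level. Linear models, Bland-Altman agreement, the modified 4-level GPPAQ
physical-activity index (cycling excluded) and a gender-stratified cohort
summary table round out the module.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

logger = logging.getLogger(__name__)

#: strict-inequality thresholds; (column, direction, cutoff) or gender dict
RISK_THRESHOLDS: dict[str, tuple[str, str, float | dict[str, float]]] = {
    "high_bmi": ("bmi", ">", 27.5),
    "high_wc": ("wc", ">", {"male": 100.0, "female": 90.0}),
    "high_sbp": ("sbp", ">", 140.0),
    "high_dbp": ("dbp", ">", 90.0),
    "high_totalchol": ("totalchol", ">", 6.2),
    "low_hdl": ("hdl", "<", 1.0),
    "high_ldl": ("ldl", ">", 4.1),
    "high_tg": ("tg", ">", 2.3),
    "high_fbg": ("fbg", ">", 6.0),
}

ACTIVE_STEP_THRESHOLD = 8000  # DailySteps above this marks an active subject


def dichotomize(records: pd.DataFrame) -> pd.DataFrame:
    """Binary risk flags per subject; missing source values yield missing flags.

    All comparisons are strict, so a value exactly at a threshold is not
    flagged. Requires a ``gender`` column ('female'/'male') for the waist
    circumference flag.
    """
    out = pd.DataFrame(index=records.index)
    for flag, (col, op, cut) in RISK_THRESHOLDS.items():
        if col not in records.columns:
            out[flag] = pd.Series(pd.NA, index=records.index, dtype="boolean")
            continue
        v = records[col].astype(float)
        if isinstance(cut, dict):
            cutoff = records["gender"].map(cut).astype(float)
        else:
            cutoff = cut
        res = v > cutoff if op == ">" else v < cutoff
        out[flag] = res.astype("boolean").mask(v.isna())
    return out


@dataclass
class ModelResult:
    """One fitted association model: per-term estimates, CIs and p-values."""

    model: str
    terms: pd.DataFrame  # term, estimate, or_, ci_low, ci_high, p
    n: int
    converged: bool
    message: str = ""

    def term(self, name_fragment: str) -> pd.Series:
        hit = self.terms[self.terms["term"].str.contains(name_fragment, regex=False)]
        if len(hit) != 1:
            raise KeyError(f"{name_fragment!r} matches {len(hit)} terms in {self.model}")
        return hit.iloc[0]


def _terms_frame(res, *, exponentiate: bool) -> pd.DataFrame:
    ci = res.conf_int()
    df = pd.DataFrame(
        {
            "term": res.params.index,
            "estimate": res.params.to_numpy(),
            "ci_low": ci[0].to_numpy(),
            "ci_high": ci[1].to_numpy(),
            "p": res.pvalues.to_numpy(),
        }
    )
    if exponentiate:
        with np.errstate(over="ignore"):
            df["or_"] = np.exp(df["estimate"].to_numpy())
            df["ci_low"] = np.exp(df["ci_low"].to_numpy())
            df["ci_high"] = np.exp(df["ci_high"].to_numpy())
    return df.reset_index(drop=True)


def _prepare(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    data = df[cols].dropna().copy()
    if "gender" in data.columns:
        # female is the reference level throughout
        data["gender"] = pd.Categorical(data["gender"], categories=["female", "male"])
    return data


def fit_logistic(
    data: pd.DataFrame,
    outcome: str,
    metric: str,
    *,
    model: str = "steps",
    covariates: tuple[str, ...] = ("age", "gender"),
    cluster_col: str | None = None,
) -> ModelResult:
    """Maximum-likelihood logistic fit of a binary marker on a wearable metric.

    ``model='steps'`` fits ``outcome ~ covariates + metric + gender:metric``
    with the metric scaled per 1,000 steps, and the gender × metric
    interaction is the reported term; ``model='hr'`` fits the metric main
    effect per bpm. ``cluster_col`` appends an activity-cluster factor with
    'AM' as reference. Non-convergence or separation yields a flagged result
    with no usable estimates.
    """
    cols = [outcome, metric, *covariates] + ([cluster_col] if cluster_col else [])
    data = _prepare(data, list(dict.fromkeys(cols)))
    y = data[outcome].astype(float)
    n = len(data)
    if n == 0 or y.nunique() < 2:
        return ModelResult(model, pd.DataFrame(), n, False, "outcome has a single class")

    data = data.assign(_y=y)
    if model == "steps":
        data["_metric"] = data[metric] / 1000.0
        rhs = " + ".join(c for c in covariates) + " + _metric + gender:_metric"
    elif model == "hr":
        data["_metric"] = data[metric]
        rhs = " + ".join(c for c in covariates) + " + _metric"
    else:
        raise ValueError(f"unknown model tag {model!r}")
    if cluster_col:
        data["_cluster"] = pd.Categorical(
            data[cluster_col], categories=["AM", "MidDay", "PM"]
        )
        rhs += " + _cluster"

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            warnings.simplefilter("error", category=PerfectSeparationWarning)
            res = smf.glm(f"_y ~ {rhs}", data=data, family=sm.families.Binomial()).fit()
        if not np.isfinite(res.bse).all() or np.abs(res.params).max() > 50:
            return ModelResult(model, pd.DataFrame(), n, False, "separation suspected")
        if (res.bse == 0).any() or not np.isfinite(res.pvalues).all():
            return ModelResult(model, pd.DataFrame(), n, False, "rank-deficient design")
    except Exception as exc:  # separation, rank deficiency, non-convergence
        return ModelResult(model, pd.DataFrame(), n, False, f"fit failed: {exc}")
    return ModelResult(model, _terms_frame(res, exponentiate=True), n, True)


def interaction_term(result: ModelResult) -> pd.Series:
    """The gender × metric interaction row of a step-model result."""
    return result.term("gender[T.male]:_metric")


def metric_term(result: ModelResult) -> pd.Series:
    """The metric main-effect row of an HR-model result."""
    return result.term("_metric")


def fit_linear(data: pd.DataFrame, formula: str, *, model: str = "ols") -> ModelResult:
    """Ordinary least squares with Gaussian errors via a model formula.

    Column references in ``formula`` follow patsy syntax; rows with any
    missing variable are dropped (complete case). Collinearity is flagged.
    """
    res = smf.ols(formula, data=data).fit()
    terms = _terms_frame(res, exponentiate=False)
    converged = bool(np.isfinite(res.bse).all())
    msg = "" if converged else "collinear design (non-finite standard errors)"
    if msg:
        logger.warning("fit_linear %s: %s", formula, msg)
    return ModelResult(model, terms, int(res.nobs), converged, msg)


def bland_altman(x, y) -> tuple[float, float, float] | None:
    """Mean difference and 95% limits of agreement for paired measurements.

    d = x − y; limits are mean(d) ± 1.96·SD(d). Returns None below 2 pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    d = x[ok] - y[ok]
    if d.size < 2:
        return None
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    return mean_diff, mean_diff - 1.96 * sd, mean_diff + 1.96 * sd


# GPPAQ physical activity index: occupational activity class crossed with
# weekly hours of physical exercise (cycling is deliberately not counted,
# so wearable-derived activity and the index measure comparable behaviour).
# Rows: occupation class; columns: exercise-hours band
# 0 = none, 1 = some but <1 h, 2 = 1 to <3 h, 3 = 3 h or more.
# Scores: 0 Inactive, 1 Moderately Inactive, 2 Moderately Active, 3 Active.
GPPAQ_MATRIX: dict[str, tuple[int, int, int, int]] = {
    "sedentary": (0, 1, 2, 3),
    "standing": (1, 2, 3, 3),
    "physical": (2, 3, 3, 3),
    "heavy_manual": (3, 3, 3, 3),
}
PAI_LEVELS = ("Inactive", "Moderately Inactive", "Moderately Active", "Active")


def gppaq_pai(occupation: str | None, exercise_band: int | None, cycling_band: int | None = None) -> int | None:
    """4-level physical activity index from occupation and exercise hours.

    ``exercise_band`` indexes the weekly-hours band (0: none, 1: <1 h,
    2: 1–<3 h, 3: ≥3 h). ``cycling_band`` is accepted for schema
    compatibility but ignored. Returns 0–3 (Inactive … Active) or None when
    occupation or exercise band is missing.
    """
    del cycling_band  # cycling is excluded from the index by design
    if occupation is None or (isinstance(occupation, float) and np.isnan(occupation)):
        return None
    if exercise_band is None or (isinstance(exercise_band, float) and np.isnan(exercise_band)):
        return None
    try:
        row = GPPAQ_MATRIX[str(occupation)]
    except KeyError as exc:
        raise ValueError(f"unknown occupation class {occupation!r}") from exc
    band = int(exercise_band)
    if not 0 <= band <= 3:
        raise ValueError(f"exercise band must be 0–3, got {band}")
    return row[band]


def active_flag(daily_steps: float | None) -> bool | None:
    """True when average daily steps strictly exceed 8,000; None if absent."""
    if daily_steps is None or (isinstance(daily_steps, float) and np.isnan(daily_steps)):
        return None
    return bool(daily_steps > ACTIVE_STEP_THRESHOLD)


def cohort_summary(
    data: pd.DataFrame,
    *,
    group: str = "gender",
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
    continuity_correction: bool = False,
) -> pd.DataFrame:
    """Gender-stratified summary: mean (SD) with Student t-tests for
    continuous variables, count (%) with chi-squared tests for categorical.

    Degenerate comparisons (a constant variable, or a group with <2 values)
    report a missing p-value.
    """
    levels = [lv for lv in data[group].dropna().unique()]
    if len(levels) != 2:
        raise ValueError("cohort_summary expects exactly 2 groups")
    ga, gb = levels
    rows = []
    for col in continuous or []:
        a = data.loc[data[group] == ga, col].dropna().astype(float)
        b = data.loc[data[group] == gb, col].dropna().astype(float)
        p = np.nan
        if len(a) >= 2 and len(b) >= 2 and (a.std(ddof=1) > 0 or b.std(ddof=1) > 0):
            p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
        rows.append(
            {
                "variable": col, "kind": "continuous",
                str(ga): f"{a.mean():.2f} ({a.std(ddof=1):.2f})",
                str(gb): f"{b.mean():.2f} ({b.std(ddof=1):.2f})",
                "p": p,
            }
        )
    for col in categorical or []:
        tab = pd.crosstab(data[col], data[group])
        p = np.nan
        if tab.shape[0] >= 2 and (tab.to_numpy().sum(axis=0) > 0).all():
            try:
                p = float(stats.chi2_contingency(tab, correction=continuity_correction).pvalue)
            except ValueError:
                pass
        pct = tab / tab.sum(axis=0) * 100
        for level in tab.index:
            rows.append(
                {
                    "variable": f"{col}={level}", "kind": "categorical",
                    str(ga): f"{tab.loc[level, ga]} ({pct.loc[level, ga]:.1f})",
                    str(gb): f"{tab.loc[level, gb]} ({pct.loc[level, gb]:.1f})",
                    "p": p if level == tab.index[0] else np.nan,
                }
            )
    return pd.DataFrame(rows)


def chi2_statistic(table: np.ndarray, *, correction: bool = False) -> float:
    """Pearson chi-squared statistic for a contingency table."""
    return float(stats.chi2_contingency(np.asarray(table), correction=correction).statistic)
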