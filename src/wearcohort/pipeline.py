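"""End-to-end orchestration: from intraday streams to association tables.

Each stage consumes the previous stage's tables and logs the number of
subjects surviving every filter (complete-day inclusion, 2-SD exclusions,
per-model complete cases), so the flow of the cohort through the analysis
is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cardiac as cardiac_mod
from . import ingest, lipids, metrics, profiles, risk
from .synth import SubjectData, SynthCohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Collected outputs of a full pipeline run."""

    metrics: pd.DataFrame
    ledger_table: pd.DataFrame
    profile_matrix: pd.DataFrame | None = None
    cluster: profiles.ClusterModel | None = None
    assignments: pd.DataFrame | None = None
    risk_models: pd.DataFrame | None = None
    cardiac_models: pd.DataFrame | None = None
    lipid_table: pd.DataFrame | None = None
    summary: pd.DataFrame | None = None
    filter_counts: dict[str, int] = field(default_factory=dict)


def process_subject(sub: SubjectData) -> tuple[metrics.SubjectMetrics, pd.DataFrame, np.ndarray | None]:
    """Metrics, day ledger and activity profile for one subject."""
    timeline = ingest.merge_by_time(sub.hr, sub.steps)
    ledger = ingest.build_day_ledger(timeline, sub.steps)
    m = metrics.subject_metrics(sub.subject_id, timeline, sub.steps, sub.sleep, ledger)
    profile = profiles.build_profile(sub.steps, ledger)
    return m, ledger, profile


def wearable_stage(subjects: dict[str, SubjectData]) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run ingest + metrics + profiles for every subject.

    Returns (metrics table, per-subject-day ledger table, profile matrix
    indexed by subject with 96 bin columns; subjects without complete days
    are absent from the profile matrix).
    """
    all_metrics, ledger_rows, profile_rows = [], [], {}
    for sid, sub in subjects.items():
        m, ledger, profile = process_subject(sub)
        all_metrics.append(m)
        led = ledger.assign(subject_id=sid)
        ledger_rows.append(led)
        if profile is not None:
            profile_rows[sid] = profile
    mtable = metrics.metrics_table(all_metrics)
    ledger_table = pd.concat(ledger_rows, ignore_index=True) if ledger_rows else pd.DataFrame()
    pmatrix = pd.DataFrame.from_dict(profile_rows, orient="index")
    logger.info("wearable stage: %d subjects read, %d with complete days",
                len(subjects), int((mtable["n_complete_days"] > 0).sum()))
    return mtable, ledger_table, pmatrix


def cluster_stage(pmatrix: pd.DataFrame, *, k: int = 3, restarts: int = profiles.DEFAULT_RESTARTS,
                  seed: int = profiles.DEFAULT_SEED) -> tuple[profiles.ClusterModel, pd.DataFrame]:
    model = profiles.kmeans_correlation(pmatrix.to_numpy(), k, restarts=restarts, seed=seed)
    named = model.named_assignments()
    assignments = pd.DataFrame({"subject_id": pmatrix.index, "cluster": named})
    return model, assignments


def risk_stage(
    mtable: pd.DataFrame,
    clinical: pd.DataFrame,
    assignments: pd.DataFrame | None = None,
    *,
    common_subset: bool = False,
) -> pd.DataFrame:
    """Fit the step-interaction and resting-HR logistic models for all markers.

    ``common_subset`` restricts every model to subjects with all metric
    types observed, so results across metrics are directly comparable.
    """
    data = clinical.merge(mtable, on="subject_id", how="inner")
    flags = risk.dichotomize(data)
    data = pd.concat([data, flags], axis=1)
    if assignments is not None:
        data = data.merge(assignments, on="subject_id", how="left")
    if common_subset:
        needed = ["daily_steps", "resting_hr", "abpm_hr", "ecg_hr"]
        before = len(data)
        data = data.dropna(subset=[c for c in needed if c in data.columns])
        logger.info("common-subset restriction: %d -> %d subjects", before, len(data))

    rows = []
    for flag in risk.RISK_THRESHOLDS:
        data["_flag"] = data[flag].astype("float")
        for metric_col, tag in (("daily_steps", "steps"), ("resting_hr", "hr"), ("ecg_hr", "hr")):
            res = risk.fit_logistic(data, "_flag", metric_col, model=tag)
            if not res.converged:
                rows.append({"marker": flag, "metric": metric_col, "n": res.n,
                             "or_": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                             "p": np.nan, "note": res.message})
                continue
            term = risk.interaction_term(res) if tag == "steps" else risk.metric_term(res)
            rows.append({"marker": flag, "metric": metric_col, "n": res.n,
                         "or_": term["or_"], "ci_low": term["ci_low"],
                         "ci_high": term["ci_high"], "p": term["p"], "note": ""})
    return pd.DataFrame(rows)


def cardiac_stage(mtable: pd.DataFrame, clinical: pd.DataFrame, cardiac: pd.DataFrame) -> pd.DataFrame:
    data = (
        cardiac.drop(columns=["weight", "height"], errors="ignore")
        .merge(clinical, on="subject_id")
        .merge(mtable[["subject_id", "daily_steps", "resting_hr"]], on="subject_id")
    )
    data = cardiac_mod.index_to_bsa(data)
    rows = []
    for param in cardiac_mod.CARDIAC_PARAMS:
        for predictor in ("steps", "category", "resting_hr"):
            try:
                res = cardiac_mod.cardiac_model(data.dropna(subset=[param]), param, predictor)
            except ValueError as exc:
                logger.warning("cardiac %s~%s failed: %s", param, predictor, exc)
                continue
            for _, t in res.terms.iterrows():
                if t["term"].startswith("_x"):
                    rows.append({"param": param, "predictor": predictor, "term": t["term"],
                                 "beta": t["estimate"], "ci_low": t["ci_low"],
                                 "ci_high": t["ci_high"], "p": t["p"], "n": res.n})
    high = cardiac_mod.high_lvm_model(data.dropna(subset=["lvm"]))
    if high.converged:
        t = high.term("_upper_q")
        rows.append({"param": "high_lvm", "predictor": "upper_quartile", "term": "_upper_q",
                     "beta": t["or_"], "ci_low": t["ci_low"], "ci_high": t["ci_high"],
                     "p": t["p"], "n": high.n})
    return pd.DataFrame(rows)


def lipid_stage(mtable: pd.DataFrame, clinical: pd.DataFrame, panel: pd.DataFrame) -> pd.DataFrame:
    filtered = lipids.filter_species(panel)
    normalized = lipids.batch_zscore(filtered)
    covariates = clinical.merge(mtable[["subject_id", "daily_steps"]], on="subject_id")
    covariates = covariates[["subject_id", "age", "gender", "bmi", "daily_steps", "fbg"]]
    return lipids.lipid_associations(normalized, covariates)


def run_all(cohort: SynthCohort, *, seed: int = profiles.DEFAULT_SEED,
            restarts: int = profiles.DEFAULT_RESTARTS) -> PipelineResult:
    """Run every stage on an in-memory cohort."""
    mtable, ledger_table, pmatrix = wearable_stage(cohort.subjects)
    result = PipelineResult(metrics=mtable, ledger_table=ledger_table, profile_matrix=pmatrix)
    result.filter_counts["subjects_read"] = len(cohort.subjects)
    result.filter_counts["with_complete_days"] = int((mtable["n_complete_days"] > 0).sum())

    if len(pmatrix) >= 3:
        result.cluster, result.assignments = cluster_stage(pmatrix, seed=seed, restarts=restarts)

    sleep_cols = mtable.set_index("subject_id")[["sleep_duration", "sleep_hour", "wake_hour"]].copy()
    sleep_cols["sleep_hour"] = metrics.sleep_hour_continuous(sleep_cols["sleep_hour"])
    observed = sleep_cols.dropna(how="all")
    if len(observed) >= 3:
        keep = metrics.two_sd_filter(observed)
        result.filter_counts["sleep_2sd_retained"] = int(keep.sum())

    result.risk_models = risk_stage(mtable, cohort.clinical, result.assignments)
    result.cardiac_models = cardiac_stage(mtable, cohort.clinical, cohort.cardiac)
    result.lipid_table = lipid_stage(mtable, cohort.clinical, cohort.lipids)
    result.summary = risk.cohort_summary(
        cohort.clinical.merge(mtable, on="subject_id"),
        continuous=["age", "bmi", "wc", "sbp", "dbp", "resting_hr", "ecg_hr",
                    "totalchol", "ldl", "hdl", "tg", "fbg", "daily_steps"],
        categorical=["ethnicity"],
    )
    return result
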