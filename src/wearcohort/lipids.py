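"""Serum sphingolipid panel processing and activity associations.

Species names encode class and chain composition — ``Cer(d18:1/20:0)`` is a
ceramide with a d18:1 sphingoid backbone and a 20:0 acyl chain, while
``SM(36:1)`` carries a total carbon:double-bond count. Odd-chain species
(any chain with an odd carbon count, or an odd total where only a total is
given) and species missing in more than 20% of samples are excluded.
Abundances (pmol) are z-scored per species within each acquisition batch
before batches are pooled, removing batch location/scale effects. Each
surviving species is regressed on average daily steps (per 1,000) adjusting
for age, gender and BMI, with Benjamini-Hochberg FDR control across
species; a parallel model uses fasting blood glucose as the predictor
(uncorrected p).
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

MISSINGNESS_MAX = 0.20  # exclusion is strict: fraction must exceed this
FDR_THRESHOLD = 0.1

_NAME_RE = re.compile(r"^(?P<cls>[A-Za-z]+)\((?P<comp>[^()]*(?:\([^()]*\))?[^()]*)\)$")
_CHAIN_RE = re.compile(r"^[a-z]?(?P<carbons>\d+):\d+(?:\([^()]*\))?$")


def parse_species(name: str) -> tuple[str, list[int]]:
    """Parse a sphingolipid name into (class, chain carbon counts).

    Chains are separated by '/'; a lone composition like ``SM(36:1)`` yields
    the single total carbon count. Raises ValueError on unparseable names.
    """
    m = _NAME_RE.match(name.strip())
    if not m:
        raise ValueError(f"unparseable sphingolipid name {name!r}")
    carbons = []
    for chain in m.group("comp").split("/"):
        cm = _CHAIN_RE.match(chain.strip())
        if not cm:
            raise ValueError(f"unparseable chain {chain!r} in {name!r}")
        carbons.append(int(cm.group("carbons")))
    return m.group("cls"), carbons


def is_odd_chain(name: str) -> bool:
    """True when any chain (or the total, for total-composition names) is odd."""
    _, carbons = parse_species(name)
    return any(c % 2 == 1 for c in carbons)


def filter_species(panel: pd.DataFrame, *, id_cols: tuple[str, ...] = ("subject_id", "batch")) -> pd.DataFrame:
    """Drop odd-chain species and species missing in >20% of samples.

    Unparseable species names are excluded with a warning. ``panel`` is a
    wide table: identifier columns plus one column per species.
    """
    keep = list(id_cols)
    species = [c for c in panel.columns if c not in id_cols]
    for sp in species:
        try:
            odd = is_odd_chain(sp)
        except ValueError:
            logger.warning("excluding unparseable species name %r", sp)
            continue
        if odd:
            continue
        if panel[sp].isna().mean() > MISSINGNESS_MAX:
            continue
        keep.append(sp)
    return panel[keep]


def batch_zscore(panel: pd.DataFrame, *, id_cols: tuple[str, ...] = ("subject_id", "batch")) -> pd.DataFrame:
    """Within-batch per-species z-score; missing values stay missing.

    A species with zero variance (or a single observation) inside a batch
    is set missing for that batch, with a warning.
    """
    out = panel.copy()
    species = [c for c in panel.columns if c not in id_cols]
    for batch, idx in panel.groupby("batch").groups.items():
        block = panel.loc[idx, species].astype(float)
        mu = block.mean()
        sd = block.std(ddof=1)
        bad = ~np.isfinite(sd) | (sd == 0)
        if bad.any():
            logger.warning("batch %s: zero-variance species set missing: %s",
                           batch, list(sd.index[bad]))
        z = (block - mu) / sd.where(~bad)
        out.loc[idx, species] = z
    return out


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1, mapped back to the
    input order. Raises on p outside [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def lipid_associations(
    panel: pd.DataFrame,
    covariates: pd.DataFrame,
    *,
    id_cols: tuple[str, ...] = ("subject_id", "batch"),
) -> pd.DataFrame:
    """Per-species associations with daily steps and fasting glucose.

    ``panel`` holds normalised abundances; ``covariates`` one row per subject
    with ``subject_id``, ``age``, ``gender``, ``bmi``, ``daily_steps`` and
    ``fbg``. For each species: OLS of the species on age + gender + BMI +
    steps (per 1,000), BH FDR over the steps p-values across species, and a
    parallel model with FBG as predictor (uncorrected p). Returns a tidy
    table: species, beta_steps, p_steps, q_steps, beta_fbg, p_fbg, n_steps.
    """
    species = [c for c in panel.columns if c not in id_cols]
    merged = panel.merge(covariates, on="subject_id", how="inner", validate="one_to_one")
    merged = merged.assign(
        _male=(merged["gender"] == "male").astype(float),
        _steps_k=merged["daily_steps"] / 1000.0,
    )
    rows = []
    for sp in species:
        base = merged[[sp, "age", "_male", "bmi", "_steps_k", "fbg"]].rename(columns={sp: "_y"})
        d = base.dropna(subset=["_y", "age", "_male", "bmi", "_steps_k"])
        row = {"species": sp, "beta_steps": np.nan, "p_steps": np.nan,
               "ci_low_steps": np.nan, "ci_high_steps": np.nan,
               "beta_fbg": np.nan, "p_fbg": np.nan, "n_steps": len(d)}
        if len(d) > 5:
            X = sm.add_constant(d[["age", "_male", "bmi", "_steps_k"]].to_numpy())
            res = sm.OLS(d["_y"].to_numpy(), X).fit()
            row["beta_steps"], row["p_steps"] = float(res.params[-1]), float(res.pvalues[-1])
            ci = res.conf_int()[-1]
            row["ci_low_steps"], row["ci_high_steps"] = float(ci[0]), float(ci[1])
        dg = base.dropna(subset=["_y", "age", "_male", "bmi", "fbg"])
        if len(dg) > 5:
            Xg = sm.add_constant(dg[["age", "_male", "bmi", "fbg"]].to_numpy())
            resg = sm.OLS(dg["_y"].to_numpy(), Xg).fit()
            row["beta_fbg"], row["p_fbg"] = float(resg.params[-1]), float(resg.pvalues[-1])
        rows.append(row)
    out = pd.DataFrame(rows)
    tested = out["p_steps"].notna()
    out["q_steps"] = np.nan
    if tested.any():
        out.loc[tested, "q_steps"] = bh_fdr(out.loc[tested, "p_steps"].to_numpy())
    return out.sort_values("p_steps", ignore_index=True)
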