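"""Diurnal activity profiles and correlation-distance k-means.

A profile is the subject's average day of movement: 96 fifteen-minute
time-of-day bins of step counts, smoothed with a centred 5-bin moving
average, averaged across data-complete days, zero-filled where no data
exist, and smoothed again. Profiles are clustered with Lloyd's algorithm
under the distance d(p, q) = 1 − Pearson(p, q), which compares the *shape*
of the day (when a subject moves) rather than its amplitude (how much), so
assignments are invariant to per-subject rescaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .ingest import complete_days

logger = logging.getLogger(__name__)

N_BINS = 96
SMOOTH_WINDOW = 5
DEFAULT_RESTARTS = 100
DEFAULT_SEED = 20180227


def _smooth(values: np.ndarray, *, circular: bool = False) -> np.ndarray:
    """Centred moving average over SMOOTH_WINDOW bins, NaN-aware.

    Edges use the available shrinking window (or wrap when ``circular``).
    """
    s = pd.Series(values)
    if circular:
        pad = SMOOTH_WINDOW // 2
        ext = pd.concat([s.iloc[-pad:], s, s.iloc[:pad]], ignore_index=True)
        sm = ext.rolling(SMOOTH_WINDOW, center=True, min_periods=1).mean()
        return sm.iloc[pad : pad + len(s)].to_numpy()
    return s.rolling(SMOOTH_WINDOW, center=True, min_periods=1).mean().to_numpy()


def build_profile(
    steps: pd.DataFrame, ledger: pd.DataFrame, *, circular: bool = False
) -> np.ndarray | None:
    """96-bin smoothed average time-of-day step profile over complete days.

    Each complete day is smoothed, days are averaged bin-wise over observed
    values, still-empty bins become 0, and the averaged profile is smoothed
    once more. Returns None when the subject has no complete days.
    """
    days = complete_days(ledger)
    if steps.empty or len(days) == 0:
        return None
    on_complete = steps[steps["start"].dt.normalize().isin(days)]
    if on_complete.empty:
        return None

    bin_idx = (on_complete["start"].dt.hour * 4 + on_complete["start"].dt.minute // 15).to_numpy()
    day_key = on_complete["start"].dt.normalize().to_numpy()
    smoothed_days = []
    for day in pd.unique(day_key):
        mask = day_key == day
        vec = np.full(N_BINS, np.nan)
        vec[bin_idx[mask]] = on_complete["steps"].to_numpy(dtype=float)[mask]
        smoothed_days.append(_smooth(vec, circular=circular))
    avg = np.nanmean(np.vstack(smoothed_days), axis=0)
    avg = np.nan_to_num(avg, nan=0.0)
    return _smooth(avg, circular=circular)


def correlation_distance(p: np.ndarray, q: np.ndarray) -> float:
    """1 − Pearson correlation, in [0, 2]; constant profiles sit at 1 from everything."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.std() == 0 or q.std() == 0:
        return 1.0
    return float(1.0 - np.corrcoef(p, q)[0, 1])


@dataclass
class ClusterModel:
    """Fitted correlation-distance k-means with canonical timing labels."""

    k: int
    centroids: np.ndarray                 # (k, 96)
    assignments: np.ndarray               # cluster index per profile
    inertia: float
    seed: int
    restarts: int
    labels: dict[int, str] | None = None  # cluster index -> AM/MidDay/PM
    inertia_trace: np.ndarray | None = None  # per-iteration objective of the winning restart

    def named_assignments(self) -> list[str]:
        if self.labels is None:
            return [str(a) for a in self.assignments]
        return [self.labels[a] for a in self.assignments]


def _zrows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-standardised matrix and a mask of zero-variance (constant) rows."""
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    flat = (sd[:, 0] == 0)
    sd[flat] = 1.0
    return (x - mu) / sd, flat


def _distance_matrix(profiles_z: np.ndarray, flat_p: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    cz, flat_c = _zrows(centroids)
    corr = profiles_z @ cz.T / profiles_z.shape[1]
    d = 1.0 - corr
    d[flat_p, :] = 1.0
    d[:, flat_c] = 1.0
    return d


def kmeans_correlation(
    profiles: np.ndarray,
    k: int = 3,
    *,
    restarts: int = DEFAULT_RESTARTS,
    seed: int = DEFAULT_SEED,
    max_iter: int = 300,
    canonicalize: bool = True,
) -> ClusterModel:
    """Lloyd k-means under correlation distance, best of ``restarts`` inits.

    Assignment minimises 1 − Pearson (ties to the lowest cluster index);
    the centroid update is the arithmetic mean. Each restart seeds centroids
    from k distinct profiles. An emptied cluster is re-seeded with the point
    farthest from its centroid. Deterministic given ``seed``.
    """
    profiles = np.asarray(profiles, dtype=float)
    n = profiles.shape[0]
    if profiles.ndim != 2 or profiles.shape[1] != N_BINS:
        raise ValueError(f"profiles must be (n, {N_BINS})")
    if n < k:
        raise ValueError(f"need at least k={k} profiles, got {n}")
    if not np.isfinite(profiles).all() or (profiles < 0).any():
        raise ValueError("profiles must be finite and non-negative")

    pz, flat_p = _zrows(profiles)
    rng = np.random.default_rng(seed)
    # distinct-profile seeding: avoid duplicate rows collapsing initial centroids
    _, uniq_idx = np.unique(profiles, axis=0, return_index=True)

    best: ClusterModel | None = None
    for _ in range(restarts):
        if len(uniq_idx) >= k:
            init = rng.choice(uniq_idx, size=k, replace=False)
        else:
            init = rng.choice(n, size=k, replace=False)
        centroids = profiles[init].copy()
        state = None  # (centroids, assignments, inertia) of the best iterate
        trace: list[float] = []
        for _it in range(max_iter):
            d = _distance_matrix(pz, flat_p, centroids)
            assign = d.argmin(axis=1)  # argmin takes the lowest index on ties
            inertia = float(d[np.arange(n), assign].sum())
            if state is not None and inertia >= state[2] - 1e-12:
                break  # converged (mean update cannot improve the objective further)
            state = (centroids.copy(), assign.copy(), inertia)
            trace.append(inertia)
            new_centroids = centroids.copy()
            for j in range(k):
                members = assign == j
                if members.any():
                    new_centroids[j] = profiles[members].mean(axis=0)
                else:
                    far = int(d[np.arange(n), assign].argmax())
                    logger.debug("re-seeding empty cluster %d with profile %d", j, far)
                    new_centroids[j] = profiles[far]
            centroids = new_centroids
        assert state is not None
        centroids, assign, inertia = state
        if best is None or inertia < best.inertia:
            best = ClusterModel(k=k, centroids=centroids, assignments=assign,
                                inertia=inertia, seed=seed, restarts=restarts,
                                inertia_trace=np.asarray(trace))

    assert best is not None
    if canonicalize and k == 3:
        best.labels = _canonical_labels(best.centroids)
    return best


def _canonical_labels(centroids: np.ndarray) -> dict[int, str]:
    """Name clusters by peak-activity timing: earliest peak AM, latest PM."""
    peak_bin = centroids.argmax(axis=1)
    order = np.argsort(peak_bin, kind="stable")
    names = {int(order[0]): "AM", int(order[1]): "MidDay", int(order[2]): "PM"}
    return names


def compare_clusters(assignments, covariate) -> tuple[float | None, pd.DataFrame | None]:
    """One-way ANOVA p-value plus Tukey HSD pairwise p-values across clusters.

    Returns (None, None) with a log message for degenerate groupings
    (fewer than 2 clusters with at least 2 members each).
    """
    df = pd.DataFrame({"group": list(assignments), "y": np.asarray(covariate, dtype=float)}).dropna()
    sizes = df.groupby("group").size()
    usable = sizes[sizes >= 2].index
    df = df[df["group"].isin(usable)]
    if df["group"].nunique() < 2:
        logger.warning("compare_clusters: fewer than 2 usable groups")
        return None, None
    groups = [g["y"].to_numpy() for _, g in df.groupby("group")]
    anova_p = float(stats.f_oneway(*groups).pvalue)
    tk = pairwise_tukeyhsd(df["y"].to_numpy(), df["group"].to_numpy())
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    return anova_p, tukey
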