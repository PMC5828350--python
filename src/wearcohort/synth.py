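"""Synthetic wearable-study cohort generator with known ground truth.

Emulates a short consumer-wearable tracking study in a healthy adult
cohort: 2–6 calendar days of wear per subject with partial first/last
days, 15-minute step counts from an overdispersed (negative binomial)
count model driven by one of three diurnal activity archetypes (morning-,
midday- or evening-peaked, with matching sleep/wake timing), 5-minute HR
readings built from a subject resting level, a circadian oscillation, a
per-step activity coupling and observation noise, invalid-confidence
gaps, plus linked clinical, cardiac MRI and serum sphingolipid tables.

Every latent quantity (archetype, expected daily steps, true resting HR,
sleep timing, effect sizes) is recorded in a truth table so each pipeline
stage has a parameter-recovery test. Default effect magnitudes are
centred on published cohort-scale estimates: a −0.252 bpm change in
resting HR per 1,000 daily steps, cardiac slopes of 0.353/0.386/0.617/
0.466 per 1,000 steps, lipid slopes around −0.05 per 1,000 steps on the
z-score scale, and a 0.710 male × steps interaction odds ratio for high
BMI. Randomness is split hierarchically (cohort → subject → stream), so
adding a subject never perturbs the others.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

N_BINS = 96
HR_PER_DAY = 288  # 5-minute cadence
ARCHETYPES = ("AM", "MidDay", "PM")

#: per-archetype (peak activity hour, peak width h, sleep-onset hour, wake hour)
ARCHETYPE_SHAPE = {
    "AM": (8.5, 2.0, 23.30, 6.65),
    "MidDay": (13.0, 3.5, 23.67, 7.72),
    "PM": (18.5, 2.0, 24.12, 8.17),
}

#: risk markers: column, strict threshold (dict = by gender), direction,
#: (female mean, male mean, SD) of the underlying continuous value
MARKER_SPECS: dict[str, tuple[str, float | dict[str, float], str, tuple[float, float, float]]] = {
    "high_bmi": ("bmi", 27.5, ">", (22.68, 24.65, 3.9)),
    "high_wc": ("wc", {"female": 90.0, "male": 100.0}, ">", (78.33, 88.54, 10.5)),
    "high_sbp": ("sbp", 140.0, ">", (122.80, 133.81, 16.5)),
    "high_dbp": ("dbp", 90.0, ">", (72.88, 83.12, 12.0)),
    "high_totalchol": ("totalchol", 6.2, ">", (5.33, 5.26, 0.95)),
    "low_hdl": ("hdl", 1.0, "<", (1.60, 1.33, 0.33)),
    "high_ldl": ("ldl", 4.1, ">", (3.28, 3.37, 0.88)),
    "high_tg": ("tg", 2.3, ">", (0.98, 1.34, 0.70)),
    "high_fbg": ("fbg", 6.0, ">", (5.24, 5.44, 0.52)),
}

#: species truly coupled to activity: name -> (β per 1,000 steps on the
#: z scale, β per mmol/l fasting glucose); magnitudes follow cohort-scale
#: serum sphingolipid estimates
TRUE_LIPID_SPECIES: dict[str, tuple[float, float]] = {
    "Cer(d18:1/20:0)": (-0.073, 0.112),
    "Cer(d18:0/20:0)": (-0.066, 0.044),
    "Cer(d18:1/24:1(15Z))": (-0.067, 0.045),
    "Cer(d18:1/18:0)": (-0.071, 0.112),
    "Cer(d18:0/24:1(15Z))": (-0.062, 0.035),
    "Cer(d18:1/16:0)": (-0.061, 0.028),
    "Cer(d18:1/22:0)": (-0.060, 0.095),
    "SM(36:0)": (-0.056, 0.123),
    "Cer(d18:1/24:0)": (-0.053, 0.067),
    "SM(36:1)": (-0.051, 0.109),
    "GlcCer(d18:1/16:0)": (-0.043, -0.113),
    "SM(36:2)": (-0.045, 0.125),
}

NULL_LIPID_SPECIES = [
    "Cer(d18:1/26:0)", "Cer(d18:1/26:1(17Z))", "Cer(d18:0/16:0)", "Cer(d18:0/18:0)",
    "Cer(d18:0/22:0)", "Cer(d18:0/24:0)", "SM(34:0)", "SM(34:1)", "SM(34:2)",
    "SM(38:1)", "SM(38:2)", "SM(40:1)", "SM(40:2)", "SM(42:1)", "SM(42:2)", "SM(42:3)",
    "GlcCer(d18:1/18:0)", "GlcCer(d18:1/22:0)", "GlcCer(d18:1/24:0)", "GlcCer(d18:1/24:1(15Z))",
    "LacCer(d18:1/16:0)", "LacCer(d18:1/18:0)", "LacCer(d18:1/22:0)", "LacCer(d18:1/24:0)",
    "Cer(d18:1/14:0)", "SM(36:3)", "SM(38:3)", "GlcCer(d18:1/20:0)",
]
#: odd-chain species: the pipeline must drop them before testing
ODD_CHAIN_SPECIES = ["Cer(d18:1/17:0)", "Cer(d18:1/19:0)", "SM(35:1)", "SM(37:1)"]
#: even-chain but unreliably detected (>20% missing): also dropped
HIGH_MISSING_SPECIES = ["Cer(d18:1/28:0)", "GlcCer(d18:1/26:0)"]


@dataclass
class SynthConfig:
    """Generator configuration; defaults define the study conditions."""

    n_subjects: int = 233
    seed: int = 0
    start_date: str = "2017-03-06"  # a Monday; wear typically spans a work week

    # cohort composition
    female_fraction: float = 0.588
    ethnicity_probs: tuple[tuple[str, float], ...] = (
        ("Chinese", 0.910), ("Malay", 0.030), ("Indian", 0.034), ("Others", 0.026),
    )
    age_mean: float = 46.0
    age_sd: float = 12.0
    age_range: tuple[float, float] = (21.0, 69.0)

    # activity archetypes and tracking span
    cluster_weights: tuple[float, float, float] = (62 / 233, 108 / 233, 63 / 233)  # AM, MidDay, PM
    tracking_days_probs: tuple[float, ...] = (0.08, 0.22, 0.40, 0.20, 0.10)  # days 2..6
    partial_last_day_prob: float = 0.7
    timing_jitter_sd: float = 0.75      # h, per-subject shift of the archetype day
    sleep_between_sd: float = 0.50      # h, subject-level sleep/wake offset
    sleep_within_sd: float = 0.30       # h, night-to-night variation

    # step counts
    daily_steps_mean: float = 10850.0
    daily_steps_cv: float = 0.36        # lognormal between-subject spread
    nb_dispersion: float = 3.0          # negative binomial size; smaller = burstier
    asleep_intensity: float = 0.02      # relative bin intensity while asleep

    # heart rate model
    hr_baseline_mean: float = 69.7
    hr_baseline_sd: float = 6.5
    hr_per_1000_steps: float = -0.252   # fitness effect on resting HR
    circadian_amplitude: float = 7.0    # bpm, peak mid-afternoon, trough pre-dawn
    circadian_peak_hour: float = 14.5
    hr_step_coupling: float = 0.045     # bpm per concurrent step (15-min interval)
    hr_noise_sd: float = 3.0

    # missingness
    invalid_conf_rate: float = 0.03
    missing_interval_rate: float = 0.02

    # in-clinic HR measurements relative to the wearable resting level
    ecg_hr_offset: float = -5.0
    ecg_hr_sd: float = 7.4
    abpm_hr_offset: float = 9.0
    abpm_hr_sd: float = 10.7

    # risk-marker logistic links: marker -> (OR per bpm resting HR,
    # male × steps interaction OR per 1,000 steps)
    risk_links: dict = field(default_factory=lambda: {
        "high_bmi": (1.06, 0.710),
        "high_wc": (1.06, 0.760),
        "high_sbp": (1.07, 1.0),
        "high_dbp": (1.07, 1.0),
        "high_totalchol": (1.05, 1.0),
        "low_hdl": (1.06, 1.0),
        "high_ldl": (1.04, 1.0),
        "high_tg": (1.06, 0.800),
        "high_fbg": (1.07, 1.0),
    })
    risk_age_beta: float = 0.02         # per year, on the logit scale

    # cardiac links: parameter -> (female mean, male mean, SD, β per 1,000 steps)
    # on the analysis scale (indexed g/m² or ml/m²; AoF raw ml)
    cardiac_links: dict = field(default_factory=lambda: {
        "lvm": (40.0, 56.0, 7.0, 0.353),
        "lvedv": (67.0, 76.0, 9.0, 0.386),
        "rvedv": (66.0, 79.0, 10.0, 0.617),
        "aof": (65.6, 78.4, 11.0, 0.466),
    })
    cardiac_sbp_beta: float = 0.08
    cardiac_availability: dict = field(default_factory=lambda: {
        "lvm": 0.91, "lvedv": 0.97, "rvedv": 0.57, "aof": 0.91,
    })

    # lipid panel
    lipid_subset: int = 112
    lipid_noise_sd: float = 0.95
    lipid_missing_rate: float = 0.05
    lipid_high_missing_rate: float = 0.30
    lipid_bmi_beta: float = 0.04        # per kg/m², on the z scale

    def __post_init__(self) -> None:
        w = np.asarray(self.cluster_weights, dtype=float)
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("cluster weights must sum to 1")
        if not np.isclose(sum(self.tracking_days_probs), 1.0):
            raise ValueError("tracking-day probabilities must sum to 1")
        for rate in (self.invalid_conf_rate, self.missing_interval_rate,
                     self.lipid_missing_rate, self.partial_last_day_prob):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")

    def noise_free(self) -> "SynthConfig":
        """Copy with every stochastic disturbance of the HR signal removed."""
        return dataclasses.replace(
            self, hr_noise_sd=0.0, circadian_amplitude=0.0, hr_step_coupling=0.0,
            invalid_conf_rate=0.0, missing_interval_rate=0.0,
        )


@dataclass
class SubjectData:
    """In-memory intraday record for one generated subject."""

    subject_id: str
    steps: pd.DataFrame
    hr: pd.DataFrame
    sleep: pd.DataFrame


@dataclass
class SynthCohort:
    """A generated cohort: intraday data, linked tables, and the truth."""

    config: SynthConfig
    subjects: dict[str, SubjectData]
    clinical: pd.DataFrame
    cardiac: pd.DataFrame
    lipids: pd.DataFrame
    truth: pd.DataFrame


def archetype_curve(
    archetype: str,
    *,
    jitter_h: float = 0.0,
    asleep_intensity: float = 0.02,
) -> np.ndarray:
    """Relative expected-step intensity per 15-minute time-of-day bin (sums to 1)."""
    peak, width, sleep_h, wake_h = ARCHETYPE_SHAPE[archetype]
    peak += jitter_h
    sleep_h += jitter_h
    wake_h += jitter_h
    hours = (np.arange(N_BINS) + 0.5) / 4.0
    # circular distance to the activity peak
    delta = np.minimum(np.abs(hours - peak), 24.0 - np.abs(hours - peak))
    bump = np.exp(-0.5 * (delta / width) ** 2)
    awake = (hours >= wake_h % 24) & (hours < sleep_h % 24) if sleep_h % 24 > wake_h % 24 else (
        (hours >= wake_h % 24) | (hours < sleep_h % 24)
    )
    curve = np.where(awake, 1.0 + 3.0 * bump, asleep_intensity)
    return curve / curve.sum()


def _truncnorm_scalar(rng: np.random.Generator, mean: float, sd: float,
                      low: float, high: float) -> float:
    """Inverse-CDF truncated normal draw from the given generator."""
    a = stats.norm.cdf(low, mean, sd)
    b = stats.norm.cdf(high, mean, sd)
    u = a + rng.random() * (b - a)
    return float(stats.norm.ppf(np.clip(u, 1e-12, 1 - 1e-12), mean, sd))


def _draw_subject_latents(config: SynthConfig, rng: np.random.Generator, index: int) -> dict:
    """Demographics, archetype, activity level and HR truth for one subject.

    All draws come from the subject's own stream in a fixed order, so
    adding or removing other subjects never perturbs this one.
    """
    gender = "female" if rng.random() < config.female_fraction else "male"
    eth_names = [e for e, _ in config.ethnicity_probs]
    eth_p = np.array([p for _, p in config.ethnicity_probs])
    ethnicity = str(rng.choice(eth_names, p=eth_p / eth_p.sum()))
    age = round(_truncnorm_scalar(rng, config.age_mean, config.age_sd, *config.age_range), 1)

    archetype = str(rng.choice(ARCHETYPES, p=np.asarray(config.cluster_weights)))
    sigma_ln = np.sqrt(np.log1p(config.daily_steps_cv**2))
    daily_total = float(
        config.daily_steps_mean * np.exp(rng.normal(0.0, sigma_ln) - sigma_ln**2 / 2)
    )
    rhr = float(
        rng.normal(config.hr_baseline_mean, config.hr_baseline_sd)
        + config.hr_per_1000_steps * (daily_total - config.daily_steps_mean) / 1000.0
    )

    jitter = float(rng.normal(0.0, config.timing_jitter_sd))
    sleep_offset = float(rng.normal(0.0, config.sleep_between_sd))
    _, _, sleep_base, wake_base = ARCHETYPE_SHAPE[archetype]
    n_days = int(rng.choice(np.arange(2, 7), p=np.asarray(config.tracking_days_probs)))
    partial_last = bool(rng.random() < config.partial_last_day_prob)
    height = round(float(rng.normal(160.0, 6.0) if gender == "female" else rng.normal(172.0, 6.5)), 1)

    return {
        "subject_id": f"S{index:04d}",
        "gender": gender,
        "ethnicity": ethnicity,
        "age": age,
        "archetype": archetype,
        "daily_total_true": daily_total,
        "rhr_true": rhr,
        "jitter_h": jitter,
        "sleep_hour_true": sleep_base + jitter + sleep_offset,
        "wake_hour_true": wake_base + jitter + sleep_offset,
        "n_days": n_days,
        "partial_last": partial_last,
        "height": height,
    }


def _marker_row(config: SynthConfig, rng: np.random.Generator, lat: dict) -> dict:
    """Risk flags from the configured logistic links, then continuous marker
    values drawn conditional on each flag (truncated normals around the
    cohort-typical means), so dichotomisation reproduces the links."""
    male = 1.0 if lat["gender"] == "male" else 0.0
    age_c = lat["age"] - config.age_mean
    rhr_c = lat["rhr_true"] - config.hr_baseline_mean
    steps_k_c = (lat["daily_total_true"] - config.daily_steps_mean) / 1000.0

    out = {}
    for marker, (col, cut, op, (mu_f, mu_m, sd)) in MARKER_SPECS.items():
        or_rhr, or_int = config.risk_links[marker]
        mu = mu_m if male else mu_f
        cutoff = (cut["male"] if male else cut["female"]) if isinstance(cut, dict) else cut
        # intercept chosen so marginal prevalence matches the tail mass of
        # the continuous distribution at the threshold
        if op == ">":
            p_base = 1.0 - stats.norm.cdf(cutoff, mu, sd)
        else:
            p_base = stats.norm.cdf(cutoff, mu, sd)
        logit = (
            np.log(p_base / (1.0 - p_base))
            + np.log(or_rhr) * rhr_c
            + config.risk_age_beta * age_c
            + np.log(or_int) * steps_k_c * male
        )
        flag = rng.random() < 1.0 / (1.0 + np.exp(-logit))
        above = flag if op == ">" else not flag
        lo, hi = (cutoff, np.inf) if above else (-np.inf, cutoff)
        out[col] = round(_truncnorm_scalar(rng, mu, sd, lo, hi), 2)
    return out


_GPPAQ_OCCUPATIONS = ("sedentary", "standing", "physical", "heavy_manual")
_GPPAQ_OCC_PROBS = (0.58, 0.24, 0.13, 0.05)


def _questionnaire_row(config: SynthConfig, rng: np.random.Generator, lat: dict) -> dict:
    occupation = str(rng.choice(_GPPAQ_OCCUPATIONS, p=_GPPAQ_OCC_PROBS))
    steps_z = (lat["daily_total_true"] - config.daily_steps_mean) / (
        config.daily_steps_mean * config.daily_steps_cv
    )
    latent = 0.8 * steps_z + rng.normal(0.0, 0.8)
    exercise_band = int(np.digitize(latent, [-0.55, 0.25, 0.95]))
    cycling_band = int(rng.choice([0, 1, 2, 3], p=[0.75, 0.12, 0.08, 0.05]))
    return {"occupation": occupation, "exercise_band": exercise_band, "cycling_band": cycling_band}


def _intraday(config: SynthConfig, rng: np.random.Generator, lat: dict) -> SubjectData:
    """Simulate one subject's step, HR and sleep streams."""
    base = pd.Timestamp(config.start_date)
    n_days = int(lat["n_days"])
    curve = archetype_curve(lat["archetype"], jitter_h=lat["jitter_h"],
                            asleep_intensity=config.asleep_intensity)
    mu_full = curve * lat["daily_total_true"]

    wear_start = base + pd.Timedelta(hours=float(rng.uniform(10.0, 16.0)))
    last_day = base + pd.Timedelta(days=n_days - 1)
    if lat["partial_last"]:
        wear_end = last_day + pd.Timedelta(hours=float(rng.uniform(8.0, 14.0)))
    else:
        wear_end = last_day + pd.Timedelta(hours=24.0)

    # 15-minute step grid over the wear window
    grid = pd.date_range(base, wear_end - pd.Timedelta(minutes=15), freq="15min")
    grid = grid[grid >= wear_start.floor("15min")]
    bin_idx = (grid.hour * 4 + grid.minute // 15).to_numpy()
    mu = mu_full[bin_idx]
    r = config.nb_dispersion
    steps_vals = rng.negative_binomial(r, r / (r + np.maximum(mu, 1e-9)))
    keep = rng.random(len(grid)) >= config.missing_interval_rate
    steps = pd.DataFrame({"start": grid[keep], "steps": steps_vals[keep].astype(int)})

    # 5-minute HR points over the same window
    hr_grid = pd.date_range(base, wear_end - pd.Timedelta(minutes=5), freq="5min")
    hr_grid = hr_grid[hr_grid >= wear_start.floor("5min")]
    hour = hr_grid.hour.to_numpy() + hr_grid.minute.to_numpy() / 60.0
    circ = config.circadian_amplitude * np.cos(
        2 * np.pi * (hour - config.circadian_peak_hour) / 24.0
    )
    hr_bin = (hr_grid.hour * 4 + hr_grid.minute // 15).to_numpy()
    # couple HR to the realised concurrent step count of the same clock bin/day
    step_lookup = dict(zip((grid.dayofyear * N_BINS + bin_idx)[keep], steps_vals[keep]))
    hr_keys = hr_grid.dayofyear.to_numpy() * N_BINS + hr_bin
    concurrent = np.array([step_lookup.get(k, 0) for k in hr_keys], dtype=float)
    hr_vals = (
        lat["rhr_true"] + circ + config.hr_step_coupling * concurrent
        + rng.normal(0.0, config.hr_noise_sd, len(hr_grid))
    )
    conf = np.where(rng.random(len(hr_grid)) < config.invalid_conf_rate, -1, 2)
    hr = pd.DataFrame(
        {
            "timestamp": hr_grid,
            "hr_bpm": np.round(np.maximum(hr_vals, 35.0), 1),
            "confidence": conf.astype(int),
        }
    )

    # one sleep session per night fully inside the wear window
    sessions = []
    for d in range(n_days - 1):
        onset = float(lat["sleep_hour_true"] + rng.normal(0.0, config.sleep_within_sd))
        wake = float(lat["wake_hour_true"] + rng.normal(0.0, config.sleep_within_sd))
        start = base + pd.Timedelta(days=d, hours=onset)
        end = base + pd.Timedelta(days=d + 1, hours=wake)
        if end <= start:  # degenerate draw; skip the night
            continue
        sessions.append((start.floor("min"), end.floor("min")))
    sleep = pd.DataFrame(sessions, columns=["start", "end"]) if sessions else pd.DataFrame(
        {"start": pd.Series(dtype="datetime64[ns]"), "end": pd.Series(dtype="datetime64[ns]")}
    )
    return SubjectData(subject_id=lat["subject_id"], steps=steps, hr=hr, sleep=sleep)


def _cardiac_row(config: SynthConfig, rng: np.random.Generator, lat: dict,
                 markers: dict, weight: float) -> dict:
    from .cardiac import dubois_bsa

    male = lat["gender"] == "male"
    steps_k_c = (lat["daily_total_true"] - config.daily_steps_mean) / 1000.0
    sbp_c = markers["sbp"] - 128.0
    bsa = dubois_bsa(weight, lat["height"])

    out = {"subject_id": lat["subject_id"], "weight": weight, "height": lat["height"]}
    for param, (mu_f, mu_m, sd, beta) in config.cardiac_links.items():
        mu = mu_m if male else mu_f
        value = mu + beta * steps_k_c + config.cardiac_sbp_beta * sbp_c + rng.normal(0.0, sd)
        if param == "aof":
            value += 0.15 * (weight - 65.0) + 0.05 * (lat["height"] - 166.0)
            raw = value  # AoF is analysed raw
        else:
            raw = value * bsa  # stored raw; the pipeline re-indexes by BSA
        available = rng.random() < config.cardiac_availability[param]
        out[param] = round(max(raw, 1.0), 1) if available else np.nan
    return out


_ALL_LIPID_SPECIES: list[str] = (
    list(TRUE_LIPID_SPECIES) + NULL_LIPID_SPECIES + ODD_CHAIN_SPECIES + HIGH_MISSING_SPECIES
)


def _lipid_row(config: SynthConfig, rng: np.random.Generator, lat: dict,
               markers: dict, batch: str) -> dict:
    steps_k_c = (lat["daily_total_true"] - config.daily_steps_mean) / 1000.0
    bmi_c = markers["bmi"] - 23.5
    fbg_c = markers["fbg"] - 5.3
    # affine raw scale per batch keeps abundances positive (pmol) and makes
    # the within-batch z-score recover the latent value exactly
    scale, shift = (20.0, 150.0) if batch == "B1" else (32.0, 240.0)

    out = {"subject_id": lat["subject_id"], "batch": batch}
    for sp in _ALL_LIPID_SPECIES:
        b_steps, b_fbg = TRUE_LIPID_SPECIES.get(sp, (0.0, 0.0))
        z = (
            b_steps * steps_k_c + b_fbg * fbg_c + config.lipid_bmi_beta * bmi_c
            + rng.normal(0.0, config.lipid_noise_sd)
        )
        raw = shift + scale * z
        miss_rate = (config.lipid_high_missing_rate if sp in HIGH_MISSING_SPECIES
                     else config.lipid_missing_rate)
        out[sp] = np.nan if rng.random() < miss_rate else round(max(raw, 0.0), 2)
    return out


def generate_cohort(config: SynthConfig | None = None, outdir: str | Path | None = None) -> SynthCohort:
    """Generate a full cohort; optionally write it to ``outdir`` as CSV files.

    Layout on disk: ``subjects/<id>/steps_intraday.csv|hr_intraday.csv|
    sleep.csv`` plus ``clinical.csv``, ``cardiac.csv``, ``lipids.csv`` and
    ``truth.csv``. Identical config and seed give byte-identical output; the
    randomness is split one stream per subject, each consumed in a fixed
    order (latents, markers, questionnaire, clinic HR, intraday, cardiac,
    lipids).
    """
    config = config or SynthConfig()
    root_ss = np.random.SeedSequence(config.seed)
    _, *subject_ss = root_ss.spawn(1 + config.n_subjects)

    subjects: dict[str, SubjectData] = {}
    clin_rows, cardiac_rows, lipid_rows, truth_rows = [], [], [], []
    for i, ss in enumerate(subject_ss):
        rng = np.random.default_rng(ss)
        lat = _draw_subject_latents(config, rng, i)
        markers = _marker_row(config, rng, lat)
        quest = _questionnaire_row(config, rng, lat)
        weight = round(markers["bmi"] * (lat["height"] / 100.0) ** 2, 1)
        ecg_hr = round(lat["rhr_true"] + config.ecg_hr_offset + rng.normal(0.0, config.ecg_hr_sd))
        abpm_hr = round(ecg_hr + config.abpm_hr_offset + rng.normal(0.0, config.abpm_hr_sd))

        sub = _intraday(config, rng, lat)
        subjects[sub.subject_id] = sub

        cardiac_rows.append(_cardiac_row(config, rng, lat, markers, weight))
        if i < config.lipid_subset:
            batch = "B1" if i < config.lipid_subset // 2 else "B2"
            lipid_rows.append(_lipid_row(config, rng, lat, markers, batch))

        clin_rows.append(
            {k: lat[k] for k in ("subject_id", "gender", "ethnicity", "age", "height")}
            | markers | quest
            | {"weight": weight, "ecg_hr": ecg_hr, "abpm_hr": abpm_hr}
        )
        truth_rows.append(lat | {"active_true": lat["daily_total_true"] > 8000.0})

    clinical = pd.DataFrame(clin_rows)
    cardiac = pd.DataFrame(cardiac_rows)
    lipids = pd.DataFrame(lipid_rows)
    truth = pd.DataFrame(truth_rows)
    truth["hr_per_1000_steps"] = config.hr_per_1000_steps

    cohort = SynthCohort(config=config, subjects=subjects, clinical=clinical,
                         cardiac=cardiac, lipids=lipids, truth=truth)
    if outdir is not None:
        write_cohort(cohort, outdir)
    return cohort


def write_cohort(cohort: SynthCohort, outdir: str | Path) -> None:
    """Write a cohort to disk in the input schemas the ingest module reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sid, sub in cohort.subjects.items():
        d = outdir / "subjects" / sid
        d.mkdir(parents=True, exist_ok=True)
        steps = sub.steps.rename(columns={"start": "timestamp"})
        steps.to_csv(d / "steps_intraday.csv", index=False)
        hr = sub.hr.rename(columns={"hr_bpm": "bpm"})
        hr[["timestamp", "bpm", "confidence"]].to_csv(d / "hr_intraday.csv", index=False)
        sub.sleep.to_csv(d / "sleep.csv", index=False)
    cohort.clinical.to_csv(outdir / "clinical.csv", index=False)
    cohort.cardiac.to_csv(outdir / "cardiac.csv", index=False)
    cohort.lipids.to_csv(outdir / "lipids.csv", index=False)
    cohort.truth.to_csv(outdir / "truth.csv", index=False)


def read_cohort(indir: str | Path) -> SynthCohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    from . import ingest

    indir = Path(indir)
    subjects = {}
    for d in sorted((indir / "subjects").iterdir()):
        steps = ingest.read_intraday_steps(d / "steps_intraday.csv")
        hr = ingest.read_intraday_hr(d / "hr_intraday.csv")
        sleep = ingest.read_sleep_sessions(d / "sleep.csv")
        subjects[d.name] = SubjectData(subject_id=d.name, steps=steps, hr=hr, sleep=sleep)
    return SynthCohort(
        config=SynthConfig(),
        subjects=subjects,
        clinical=pd.read_csv(indir / "clinical.csv"),
        cardiac=pd.read_csv(indir / "cardiac.csv"),
        lipids=pd.read_csv(indir / "lipids.csv"),
        truth=pd.read_csv(indir / "truth.csv") if (indir / "truth.csv").exists() else pd.DataFrame(),
    )


# ---------------------------------------------------------------------------
# light-weight simulators for parameter-recovery tests (no intraday streams)

def simulate_interaction_cohort(
    n: int,
    interaction_or: float,
    rng: np.random.Generator,
    *,
    base_prevalence: float = 0.2,
) -> pd.DataFrame:
    """Binary marker from the steps interaction logistic model, for recovery tests."""
    male = rng.random(n) < 0.45
    age = rng.uniform(21, 69, n)
    steps_k = rng.normal(10.85, 3.9, n)
    logit = (
        np.log(base_prevalence / (1 - base_prevalence))
        + 0.02 * (age - 46.0) + 0.3 * male
        - 0.02 * (steps_k - 10.85)
        + np.log(interaction_or) * (steps_k - 10.85) * male
    )
    flag = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))
    return pd.DataFrame(
        {
            "flag": flag.astype(float),
            "gender": np.where(male, "male", "female"),
            "age": age,
            "daily_steps": steps_k * 1000.0,
        }
    )


def simulate_cardiac_cohort(
    n: int, beta_per_1000: float, rng: np.random.Generator, *, outcome_sd: float = 7.0
) -> pd.DataFrame:
    """Indexed cardiac outcome with a configured per-1,000-steps slope."""
    male = rng.random(n) < 0.45
    age = rng.uniform(21, 69, n)
    sbp = rng.normal(128.0, 17.0, n)
    steps_k = rng.normal(10.85, 3.9, n)
    outcome = (
        np.where(male, 56.0, 40.0) + beta_per_1000 * (steps_k - 10.85)
        + 0.08 * (sbp - 128.0) + 0.05 * (age - 46.0)
        + rng.normal(0.0, outcome_sd, n)
    )
    return pd.DataFrame(
        {
            "gender": np.where(male, "male", "female"),
            "age": age,
            "sbp": sbp,
            "daily_steps": steps_k * 1000.0,
            "resting_hr": rng.normal(69.7, 6.5, n),
            "lvm_i": outcome,
        }
    )


def simulate_lipid_panel(
    n: int,
    rng: np.random.Generator,
    *,
    n_true: int = 8,
    n_null: int = 40,
    beta_true: float = -0.06,
    noise_sd: float = 0.95,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Panel + covariates with a configured steps slope in the true species.

    Returns (raw panel, covariate table, names of the true species). Raw
    abundances are affine in the latent z per batch, so the within-batch
    z-score recovers the latent signal.
    """
    age = rng.uniform(21, 69, n)
    male = rng.random(n) < 0.45
    bmi = rng.normal(23.5, 3.9, n)
    steps_k = rng.normal(10.85, 3.9, n)
    fbg = rng.normal(5.3, 0.5, n)
    batch = np.where(np.arange(n) < n // 2, "B1", "B2")
    scale = np.where(batch == "B1", 20.0, 32.0)
    shift = np.where(batch == "B1", 150.0, 240.0)

    panel = {"subject_id": [f"S{i:04d}" for i in range(n)], "batch": batch}
    true_names = [f"Cer(d18:1/{c}:0)" for c in (16, 18, 20, 22, 24, 26, 28, 30)][:n_true]
    null_names = (
        [f"SM({c}:{d})" for c in (34, 36, 38, 40, 42) for d in (0, 1, 2)]
        + [f"GlcCer(d18:1/{c}:0)" for c in (16, 18, 20, 22, 24)]
        + [f"LacCer(d18:1/{c}:0)" for c in (16, 18, 20, 22, 24)]
        + [f"Cer(d18:0/{c}:0)" for c in (16, 18, 20, 22, 24)]
        + [f"Cer(d18:1/{c}:1(15Z))" for c in (24, 26)]
        + [f"SM({c}:3)" for c in (36, 38, 40, 42)]
        + ["SM(44:1)", "SM(44:2)", "SM(44:3)", "Cer(d18:0/26:0)"]
    )[:n_null]
    for nm in true_names:
        z = beta_true * (steps_k - 10.85) + rng.normal(0.0, noise_sd, n)
        panel[nm] = shift + scale * z
    for nm in null_names:
        panel[nm] = shift + scale * rng.normal(0.0, noise_sd, n)
    covariates = pd.DataFrame(
        {
            "subject_id": panel["subject_id"],
            "age": age,
            "gender": np.where(male, "male", "female"),
            "bmi": bmi,
            "daily_steps": steps_k * 1000.0,
            "fbg": fbg,
        }
    )
    return pd.DataFrame(panel), covariates, true_names


def simulate_high_lvm_cohort(n: int, upper_q_or: float, rng: np.random.Generator) -> pd.DataFrame:
    """Indexed-LVM logistic data with a configured upper-quartile odds ratio."""
    male = rng.random(n) < 0.45
    steps = rng.normal(10850.0, 3900.0, n)
    upper = steps > np.quantile(steps, 0.75)
    logit = np.log(0.08 / 0.92) + np.log(upper_q_or) * upper
    high = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))
    cutoff = np.where(male, 70.0, 50.0)
    lvm_i = np.where(high, cutoff + np.abs(rng.normal(4.0, 3.0, n)) + 0.1,
                     cutoff - np.abs(rng.normal(8.0, 5.0, n)))
    return pd.DataFrame(
        {
            "gender": np.where(male, "male", "female"),
            "ethnicity": "Chinese",
            "daily_steps": steps,
            "lvm_i": lvm_i,
        }
    )
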