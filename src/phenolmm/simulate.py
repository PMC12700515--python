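"""Seeded synthetic cohorts of smartwatch streams and monthly symptom scores.

The study data this pipeline targets (psychotic-disorder outpatients wearing
a smartwatch continuously, with monthly PANSS interviews) are not publicly
deposited, so every downstream stage is exercised against cohorts generated
here.  The generator is the analysis's own largest model run forward:
monthly PANSS dimension scores follow a linear mixed model with per-patient
random intercepts and slopes (unstructured 2x2 covariance) over a monthly
phenotype, plus AR(1) residuals; the raw 5-minute sensor windows beneath the
phenotypes carry a circadian wake/sleep structure, state-dependent motility
and cardiac targets, and device non-wear missingness.

Defaults mirror the cohort the analysis was designed around: 38 patients,
follow-up lengths in [1, 26] months with mean 11.8 (SD 7.2), ~16 h wake /
~8 h sleep per day, monthly visits, 5-minute windows on a half-open grid.

Randomness is partitioned per patient via ``numpy`` seed sequences, so
adding a patient never perturbs the streams of existing patients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats, optimize

from .exceptions import ConfigError, DataError

PANSS_DIMENSIONS = (
    "positive",
    "negative",
    "cognitive_disorganization",
    "depression_anxiety",
    "excitement_hostility",
)

#: Dimension floors = item counts of the standard five-factor PANSS model
#: (each item scores at least 1).
DIMENSION_FLOORS = {
    "positive": 3,
    "negative": 6,
    "cognitive_disorganization": 3,
    "depression_anxiety": 3,
    "excitement_hostility": 4,
}

#: Base window features measured per state.  Entries are
#: (grand mean, between-patient SD, between-month SD, within-window SD).
#: Scales chosen to resemble wrist-worn actigraphy/PPG: accelerometer energy
#: O(1) (unitless), gyroscope energy O(10^3), ~300-360 NN intervals and
#: 30-45 ms RMSSD per 5-minute window, higher vagal tone and lower motility
#: in sleep.
DEFAULT_FEATURE_TARGETS: dict[tuple[str, str], tuple[float, float, float, float]] = {
    ("acc_ste", "wake"): (3.0, 0.6, 0.30, 1.2),
    ("acc_ste", "sleep"): (0.5, 0.10, 0.05, 0.25),
    ("gyro_ste", "wake"): (2000.0, 400.0, 200.0, 800.0),
    ("gyro_ste", "sleep"): (300.0, 60.0, 30.0, 150.0),
    ("nn_count", "wake"): (360.0, 25.0, 10.0, 30.0),
    ("nn_count", "sleep"): (300.0, 20.0, 8.0, 20.0),
    ("rmssd", "wake"): (30.0, 8.0, 3.0, 10.0),
    ("rmssd", "sleep"): (45.0, 10.0, 4.0, 12.0),
}

#: Mean steps per 5-minute wake window (Poisson); sleep windows step 0.
STEPS_PER_WAKE_WINDOW = 35.0

WINDOWS_PER_DAY = 288
DAYS_PER_MONTH = 30
BASE_DATE = pd.Timestamp("2021-01-04")

#: The 20 monthly digital phenotypes, in roster order.
PHENOTYPE_COLUMNS = tuple(
    f"{feat}_{state}_{stat}"
    for feat in ("acc_ste", "gyro_ste", "nn_count", "rmssd")
    for state in ("wake", "sleep")
    for stat in ("mean", "sd")
) + (
    "sleep_wake_ratio_mean",
    "sleep_wake_ratio_sd",
    "steps_per_minute_mean",
    "steps_per_minute_sd",
)


@dataclass
class SimulationTruth:
    """Planted generative parameters for one synthetic cohort.

    ``fixed_slopes`` maps ``(phenotype, dimension)`` to the fixed slope
    beta1 (score units per phenotype unit); phenotypes named there also get
    the per-patient random slope (SD ``random_slope_sd``).  Missingness has
    three knobs: per-window drop, whole-day non-wear, and missed monthly
    visits.
    """

    n_patients: int = 38
    followup_months_per_patient: Sequence[int] | None = None
    mean_followup: float = 11.8
    sd_followup: float = 7.2
    fixed_intercepts: Mapping[str, float] = field(
        default_factory=lambda: {
            "positive": 8.0,
            "negative": 12.0,
            "cognitive_disorganization": 7.0,
            "depression_anxiety": 8.0,
            "excitement_hostility": 7.0,
        }
    )
    fixed_slopes: Mapping[tuple[str, str], float] = field(default_factory=dict)
    random_intercept_sd: float = 2.0
    random_slope_sd: float = 0.0
    intercept_slope_corr: float = 0.0
    residual_sd: float = 1.5
    ar1_rho: float = 0.3
    missingness: Mapping[str, float] = field(
        default_factory=lambda: {
            "window_drop_prob": 0.05,
            "nonwear_day_prob": 0.05,
            "month_visit_miss_prob": 0.05,
        }
    )
    wake_hours_mean: float = 16.0
    sleep_hours_mean: float = 8.0
    feature_targets: Mapping = field(default_factory=lambda: dict(DEFAULT_FEATURE_TARGETS))
    dimension_floors: Mapping[str, float] = field(default_factory=lambda: dict(DIMENSION_FLOORS))
    clip_at_floor: bool = True
    round_scores: bool = False
    artifact_prob: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.followup_months_per_patient is not None:
            fl = list(self.followup_months_per_patient)
            if len(fl) != self.n_patients:
                raise ConfigError("followup_months_per_patient length must equal n_patients")
            if any(not (1 <= m <= 26) for m in fl):
                raise ConfigError("followup_months_per_patient entries must lie in [1, 26]")
        for name in ("random_intercept_sd", "random_slope_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not abs(self.ar1_rho) < 1:
            raise ConfigError("ar1_rho must satisfy |rho| < 1")
        if not abs(self.intercept_slope_corr) <= 1:
            raise ConfigError("intercept_slope_corr must lie in [-1, 1]")
        for key in ("window_drop_prob", "nonwear_day_prob", "month_visit_miss_prob"):
            v = self.missingness.get(key, 0.0)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"missingness[{key!r}] must lie in [0, 1]")
        if self.wake_hours_mean <= 0 or self.sleep_hours_mean <= 0:
            raise ConfigError("wake_hours_mean and sleep_hours_mean must be positive")
        if self.wake_hours_mean + self.sleep_hours_mean > 24.0 + 1e-9:
            raise ConfigError("wake_hours_mean + sleep_hours_mean cannot exceed 24 h")
        for dim in self.fixed_intercepts:
            if dim not in PANSS_DIMENSIONS:
                raise ConfigError(f"unknown dimension in fixed_intercepts: {dim!r}")
        for (pheno, dim) in self.fixed_slopes:
            if dim not in PANSS_DIMENSIONS:
                raise ConfigError(f"unknown dimension in fixed_slopes: {dim!r}")
            if pheno not in PHENOTYPE_COLUMNS:
                raise ConfigError(f"unknown phenotype in fixed_slopes: {pheno!r}")

    def to_json(self) -> str:
        d = asdict(self)
        d["fixed_slopes"] = {f"{p}::{dim}": v for (p, dim), v in self.fixed_slopes.items()}
        d["feature_targets"] = {f"{f}::{s}": list(v) for (f, s), v in self.feature_targets.items()}
        if d["followup_months_per_patient"] is not None:
            d["followup_months_per_patient"] = [int(m) for m in d["followup_months_per_patient"]]
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationTruth":
        d = dict(d)
        if "fixed_slopes" in d and d["fixed_slopes"]:
            fs = {}
            for k, v in dict(d["fixed_slopes"]).items():
                if isinstance(k, str):
                    p, dim = k.split("::")
                    fs[(p, dim)] = v
                else:
                    fs[tuple(k)] = v
            d["fixed_slopes"] = fs
        if "feature_targets" in d and d["feature_targets"]:
            ft = {}
            for k, v in dict(d["feature_targets"]).items():
                if isinstance(k, str):
                    f, s = k.split("::")
                    ft[(f, s)] = tuple(v)
                else:
                    ft[tuple(k)] = tuple(v)
            d["feature_targets"] = ft
        return cls(**d)


@dataclass
class CohortBundle:
    """Everything one synthetic cohort produces: raw windows, the monthly
    clinical table, and the planted truth."""

    windows: pd.DataFrame
    clinical: pd.DataFrame
    truth: SimulationTruth


# ---------------------------------------------------------------------------
# helpers


def _patient_rng(seed: int, patient_index: int, stream: int) -> np.random.Generator:
    """Independent per-patient stream; stream ids separate sensor/PANSS/covariate draws."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream), int(patient_index)]))


def _followup_parent_mean(target: float, sd: float, lo: float = 1.0, hi: float = 26.0) -> float:
    """Parent normal mean whose [lo, hi]-truncation has the target mean.

    Follow-up lengths are drawn from a rounded truncated normal; solving for
    the parent mean keeps the realized cohort mean at the stated 11.8 months
    despite the asymmetric truncation.
    """

    def trunc_mean(mu):
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return stats.truncnorm.mean(a, b, loc=mu, scale=sd) - target

    return float(optimize.brentq(trunc_mean, target - 2 * sd, target + 2 * sd))


def draw_followup_months(truth: SimulationTruth, rng: np.random.Generator) -> np.ndarray:
    if truth.followup_months_per_patient is not None:
        return np.asarray(list(truth.followup_months_per_patient), dtype=int)
    mu = _followup_parent_mean(truth.mean_followup, truth.sd_followup)
    a, b = (1.0 - mu) / truth.sd_followup, (26.0 - mu) / truth.sd_followup
    draws = stats.truncnorm.rvs(a, b, loc=mu, scale=truth.sd_followup,
                                size=truth.n_patients, random_state=rng)
    return np.clip(np.rint(draws), 1, 26).astype(int)


def _patient_effects(truth: SimulationTruth, rng: np.random.Generator) -> dict:
    """Per-patient feature offsets and a latent monthly symptom factor seed."""
    eff = {}
    for (feat, state), (mu, sd_p, sd_m, sd_w) in truth.feature_targets.items():
        eff[(feat, state)] = rng.normal(0.0, sd_p)
    return eff


def _month_effects(truth, rng, n_months):
    """Between-month deviations: half shared latent symptom factor, half
    feature-specific, so phenotypes co-vary month to month as real
    behavioral streams do."""
    shared = rng.normal(0.0, 1.0, size=n_months)
    out = {}
    w = np.sqrt(0.5)
    for (feat, state), (mu, sd_p, sd_m, sd_w) in truth.feature_targets.items():
        specific = rng.normal(0.0, 1.0, size=n_months)
        out[(feat, state)] = sd_m * (w * shared + w * specific)
    return out


def _draw_covariates(truth: SimulationTruth, rng: np.random.Generator) -> dict:
    """Patient-level clinical covariates with cohort-like marginals
    (24% female, balanced diagnosis groups, ~90% on antipsychotics with
    chlorpromazine-equivalent doses around 500 mg/day, ~45% on
    antidepressants with fluoxetine equivalents up to 60 mg/day)."""
    on_ap = rng.random() < 0.895
    cpz = float(np.clip(rng.gamma(1.3, 450.0), 0, 2000)) if on_ap else 0.0
    on_ad = rng.random() < 0.447
    flx = float(np.clip(rng.gamma(1.2, 15.0), 0, 60)) if on_ad else 0.0
    return {
        "gender": int(rng.random() < 9 / 38),
        "diagnosis_group": int(rng.random() < 0.5),
        "chlorpromazine_equivalents": cpz,
        "fluoxetine_equivalents": flx,
    }


def _sleep_mask_for_day(truth, rng, day_minutes=24 * 60):
    """Boolean per-window sleep mask for one day; one consolidated sleep
    block starting near 23:00 with jittered onset and duration."""
    onset_h = rng.normal(23.0, 0.5)
    dur_h = float(np.clip(rng.normal(truth.sleep_hours_mean, 0.5), 2.0, 14.0))
    start = int(round(onset_h * 12))  # in 5-min windows from midnight
    length = int(round(dur_h * 12))
    mask = np.zeros(WINDOWS_PER_DAY, dtype=bool)
    idx = (start + np.arange(length)) % WINDOWS_PER_DAY
    mask[idx] = True
    return mask


# ---------------------------------------------------------------------------
# PANSS generation: the step-3 model run forward


def simulate_panss_from_lmm(
    monthly_phenotypes: pd.DataFrame,
    truth: SimulationTruth,
    rng_factory=None,
) -> pd.DataFrame:
    """Monthly PANSS dimension scores from the planted mixed model.

    For each dimension d:
    ``score_it = beta0_d + b0_i + sum_p (beta1_pd + b1_ip) x_itp + eps_it``
    with ``(b0_i, b1_ip)`` drawn from the 2x2 covariance implied by the SDs
    and ``intercept_slope_corr`` (slopes for different phenotypes share the
    intercept correlation, hence correlate at r^2 with each other), and
    ``eps`` a stationary AR(1) process with parameter ``ar1_rho`` and
    marginal SD ``residual_sd``.  Scores are clipped at the dimension floor
    and rounded to integers only when the truth says so.
    """
    need = {"patient_id", "month_index"}
    if not need <= set(monthly_phenotypes.columns):
        raise DataError(f"monthly phenotype table needs columns {sorted(need)}")
    slope_phenos = sorted({p for (p, _d) in truth.fixed_slopes})
    for p in slope_phenos:
        if p not in monthly_phenotypes.columns:
            raise DataError(f"phenotype column {p!r} missing from monthly table")
        if not np.all(np.isfinite(monthly_phenotypes[p].to_numpy(float))):
            raise DataError(f"non-finite values in phenotype column {p!r}")
    if rng_factory is None:
        rng_factory = lambda i: _patient_rng(truth.seed, i, stream=2)

    pids = sorted(monthly_phenotypes["patient_id"].unique())
    r = truth.intercept_slope_corr
    k = len(slope_phenos)
    if k and abs(r) > 0 and k * r * r > 1.0 + 1e-12:
        raise ConfigError(
            f"intercept_slope_corr={r} with {k} slope phenotypes does not give a "
            "positive-semidefinite random-effect covariance"
        )
    rows = []
    for i, pid in enumerate(pids):
        sub = monthly_phenotypes[monthly_phenotypes["patient_id"] == pid].sort_values("month_index")
        n = len(sub)
        rng = rng_factory(i)
        rec = {"patient_id": pid, "month_index": sub["month_index"].to_numpy()}
        for dim in PANSS_DIMENSIONS:
            z0 = rng.normal()
            b0 = truth.random_intercept_sd * z0
            score = np.full(n, truth.fixed_intercepts.get(dim, 0.0) + b0, dtype=float)
            for p in slope_phenos:
                beta1 = truth.fixed_slopes.get((p, dim), 0.0)
                zp = rng.normal()
                b1 = truth.random_slope_sd * (r * z0 + np.sqrt(max(0.0, 1 - r * r)) * zp)
                if (p, dim) in truth.fixed_slopes:
                    score += (beta1 + b1) * sub[p].to_numpy(float)
            eps = np.empty(n)
            if n:
                rho = truth.ar1_rho
                eps[0] = rng.normal(0.0, truth.residual_sd)
                innov_sd = truth.residual_sd * np.sqrt(max(0.0, 1 - rho * rho))
                for t in range(1, n):
                    eps[t] = rho * eps[t - 1] + rng.normal(0.0, innov_sd)
            score = score + eps
            floor = truth.dimension_floors.get(dim, 0.0)
            if truth.clip_at_floor:
                score = np.maximum(score, floor)
            if truth.round_scores:
                score = np.rint(score)
            rec[dim] = score
        df = pd.DataFrame(rec)
        rows.append(df)
    if not rows:
        return pd.DataFrame(columns=["patient_id", "month_index", *PANSS_DIMENSIONS])
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# window-level generation


def _raw_payload(rng, n_rows, acc, gyro, nn, rmssd, artifact_prob, samples_per_window=60):
    """Raw 3-axis blocks and interpulse lists matching the window targets.

    Norm samples are rescaled so the short-time energy reproduces the
    target exactly; interpulse intervals are a jittered renewal process
    whose count and successive-difference SD hit the NN/RMSSD targets,
    with occasional out-of-band artifact intervals for the cleaning rule
    to remove.
    """
    acc_xyz, gyro_xyz, ipis = [], [], []
    for j in range(n_rows):
        for target, store in ((acc[j], acc_xyz), (gyro[j], gyro_xyz)):
            xyz = rng.normal(size=(3, samples_per_window))
            e = float(np.sum(xyz * xyz))
            scale = np.sqrt(target / e) if e > 0 and target > 0 else 0.0
            store.append((xyz * scale).astype(np.float32))
        count = max(int(round(nn[j])), 0)
        m = 300_000.0 / count if count else 800.0
        m = float(np.clip(m, 320.0, 1980.0))
        jitter_sd = max(rmssd[j], 0.0) / np.sqrt(2.0)
        iv = rng.normal(m, jitter_sd, size=count)
        iv = np.clip(iv, 305.0, 1995.0)
        n_art = rng.binomial(count, artifact_prob) if count else 0
        if n_art:
            pos = rng.integers(0, count, size=n_art)
            iv = np.insert(iv, pos, rng.choice([150.0, 5000.0], size=n_art))
        ipis.append(iv.astype(np.float32))
    return acc_xyz, gyro_xyz, ipis


def generate_cohort(truth: SimulationTruth, raw_streams: bool = False) -> CohortBundle:
    """Generate one synthetic cohort, deterministically from ``truth.seed``.

    Returns raw (or precomputed-feature) 5-minute windows with wake/sleep
    labels on the half-open midnight-aligned grid, plus the monthly clinical
    table.  With ``raw_streams`` the windows carry 3-axis sample blocks and
    interpulse-interval lists instead of precomputed features (intended for
    small cohorts; a cohort-month is ~8,600 windows).
    """
    truth.validate()
    meta_rng = np.random.default_rng(np.random.SeedSequence([int(truth.seed), 0]))
    followups = draw_followup_months(truth, meta_rng)
    drop_w = truth.missingness.get("window_drop_prob", 0.0)
    drop_d = truth.missingness.get("nonwear_day_prob", 0.0)
    miss_v = truth.missingness.get("month_visit_miss_prob", 0.0)

    frames = []
    clin_rows = []
    for i in range(truth.n_patients):
        pid = f"P{i + 1:03d}"
        rng = _patient_rng(truth.seed, i, stream=1)
        eff = _patient_effects(truth, rng)
        n_months = int(followups[i])
        month_eff = _month_effects(truth, rng, n_months)
        cov = _draw_covariates(truth, _patient_rng(truth.seed, i, stream=3))

        for m in range(1, n_months + 1):
            keep_days = rng.random(DAYS_PER_MONTH) >= drop_d
            sleep_masks = [_sleep_mask_for_day(truth, rng) for _ in range(DAYS_PER_MONTH)]
            day_idx = np.repeat(np.arange(DAYS_PER_MONTH), WINDOWS_PER_DAY)
            win_in_day = np.tile(np.arange(WINDOWS_PER_DAY), DAYS_PER_MONTH)
            sleep = np.concatenate(sleep_masks)
            keep = keep_days[day_idx] & (rng.random(sleep.size) >= drop_w)
            if not keep.any():
                continue
            day_idx, win_in_day, sleep = day_idx[keep], win_in_day[keep], sleep[keep]
            n_rows = sleep.size
            start = BASE_DATE + pd.to_timedelta(
                ((m - 1) * DAYS_PER_MONTH + day_idx) * 24 * 60 + win_in_day * 5, unit="m"
            )
            vals = {}
            for feat in ("acc_ste", "gyro_ste", "nn_count", "rmssd"):
                v = np.empty(n_rows)
                for state, mask in (("wake", ~sleep), ("sleep", sleep)):
                    mu, sd_p, sd_m, sd_w = truth.feature_targets[(feat, state)]
                    loc = mu + eff[(feat, state)] + month_eff[(feat, state)][m - 1]
                    v[mask] = rng.normal(loc, sd_w, size=int(mask.sum()))
                if feat == "nn_count":
                    v = np.clip(np.rint(v), 0, 1100)
                else:
                    v = np.maximum(v, 0.0)
                vals[feat] = v
            steps = np.where(
                sleep, 0, rng.poisson(STEPS_PER_WAKE_WINDOW, size=n_rows)
            ).astype(int)
            frame = pd.DataFrame(
                {
                    "patient_id": pid,
                    "window_start": start,
                    "state": np.where(sleep, "sleep", "wake"),
                    "steps": steps,
                }
            )
            if raw_streams:
                acc_xyz, gyro_xyz, ipis = _raw_payload(
                    rng, n_rows, vals["acc_ste"], vals["gyro_ste"],
                    vals["nn_count"], vals["rmssd"], truth.artifact_prob,
                )
                frame["acc_norm"] = [np.sqrt(np.sum(b * b, axis=0)) for b in acc_xyz]
                frame["gyro_norm"] = [np.sqrt(np.sum(b * b, axis=0)) for b in gyro_xyz]
                frame["ipi_ms"] = ipis
            else:
                frame["acc_ste"] = vals["acc_ste"]
                frame["gyro_ste"] = vals["gyro_ste"]
                frame["nn_count"] = vals["nn_count"].astype(int)
                frame["rmssd"] = vals["rmssd"]
            frames.append(frame)
        clin_rows.append(
            pd.DataFrame(
                {
                    "patient_id": pid,
                    "month_index": np.arange(1, n_months + 1),
                    "enrollment_date": BASE_DATE,
                    "followup_month": np.arange(1, n_months + 1),
                    **{k: v for k, v in cov.items()},
                }
            )
        )

    windows = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["patient_id", "window_start", "state", "steps"]
    )
    clinical = pd.concat(clin_rows, ignore_index=True)

    # PANSS scores from the monthly aggregates of the generated windows, so
    # the analysis table downstream recovers exactly the x that generated y.
    from .aggregate import aggregate_months

    if raw_streams:
        from .features import extract_window_features

        feat_windows = extract_window_features(windows)
    else:
        feat_windows = windows
    monthly = aggregate_months(feat_windows, enrollment={pid: BASE_DATE for pid in clinical["patient_id"].unique()})
    panss = simulate_panss_from_lmm(monthly, truth)
    clinical = clinical.merge(panss, on=["patient_id", "month_index"], how="inner")

    # missed monthly visits
    if miss_v > 0:
        keep_rows = []
        pids = sorted(clinical["patient_id"].unique())
        for i, pid in enumerate(pids):
            rng = _patient_rng(truth.seed, i, stream=4)
            sub = clinical[clinical["patient_id"] == pid]
            keep_rows.append(sub[rng.random(len(sub)) >= miss_v])
        clinical = pd.concat(keep_rows, ignore_index=True)

    return CohortBundle(windows=windows, clinical=clinical, truth=truth)


# ---------------------------------------------------------------------------
# monthly-panel fast path


def generate_monthly_panel(truth: SimulationTruth) -> pd.DataFrame:
    """Directly emit the monthly modelling table implied by the truth.

    Skips the 5-minute window grid: monthly phenotype means are drawn from
    their generative law (patient offset + between-month deviation + a
    small aggregation-noise term matching the window counts the full grid
    would average over), monthly SD columns from the window-noise scale.
    Used for Monte-Carlo studies where thousands of cohorts are needed;
    the full path and this panel share the same PANSS-generation code.
    """
    truth.validate()
    meta_rng = np.random.default_rng(np.random.SeedSequence([int(truth.seed), 0]))
    followups = draw_followup_months(truth, meta_rng)
    n_eff = {"wake": truth.wake_hours_mean * 12 * DAYS_PER_MONTH,
             "sleep": truth.sleep_hours_mean * 12 * DAYS_PER_MONTH}
    rows = []
    for i in range(truth.n_patients):
        pid = f"P{i + 1:03d}"
        rng = _patient_rng(truth.seed, i, stream=1)
        eff = _patient_effects(truth, rng)
        n_months = int(followups[i])
        month_eff = _month_effects(truth, rng, n_months)
        cov = _draw_covariates(truth, _patient_rng(truth.seed, i, stream=3))
        rec = {"patient_id": pid, "month_index": np.arange(1, n_months + 1)}
        for (feat, state), (mu, sd_p, sd_m, sd_w) in truth.feature_targets.items():
            loc = mu + eff[(feat, state)] + month_eff[(feat, state)]
            agg_noise = sd_w / np.sqrt(n_eff[state])
            rec[f"{feat}_{state}_mean"] = loc + rng.normal(0, agg_noise, n_months)
            rec[f"{feat}_{state}_sd"] = np.abs(rng.normal(sd_w, 0.05 * sd_w, n_months))
        ratio = truth.sleep_hours_mean / truth.wake_hours_mean
        rec["sleep_wake_ratio_mean"] = ratio + rng.normal(0, 0.02 * ratio, n_months)
        rec["sleep_wake_ratio_sd"] = np.abs(rng.normal(0.05 * ratio, 0.01 * ratio, n_months))
        spm = STEPS_PER_WAKE_WINDOW / 5.0 * (truth.wake_hours_mean / 24.0)
        rec["steps_per_minute_mean"] = spm + rng.normal(0, 0.02 * spm, n_months)
        rec["steps_per_minute_sd"] = np.abs(rng.normal(0.1 * spm, 0.02 * spm, n_months))
        for k, v in cov.items():
            rec[k] = v
        rec["followup_month"] = np.arange(1, n_months + 1)
        rows.append(pd.DataFrame(rec))
    panel = pd.concat(rows, ignore_index=True)
    panss = simulate_panss_from_lmm(panel, truth)
    panel = panel.merge(panss, on=["patient_id", "month_index"], how="inner")
    panel["included"] = True
    return panel
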