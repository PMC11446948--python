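"""Synthetic EMR bundles with the longitudinal structure the analysis assumes.

Real diabetes-register EMR data are rarely openly available, so this module
generates four EMR-style tables (demographics, BMI observations, HbA1c
observations, dispensing episodes) from a generative model that mirrors the
analysis model, making parameter recovery a meaningful test of the fitting
code:

* each individual follows a latent piecewise-linear BMI trajectory with
  knots at -0.5 and +1 years relative to diagnosis (pre / peri / post
  slopes drawn per individual, optionally shifted by banded covariates);
* the active drug regimen adds a step offset (kg/m2) and the HbA1c change
  category adds a further offset, both coded with exactly the rules the
  exposure module applies at analysis time;
* measurement errors are Gaussian with within-individual correlation
  rho**|t - s| (spatial power), decaying with the time gap in years;
* visit times follow a Poisson process thinned by a missingness
  probability; HbA1c follows an individual random walk whose drift responds
  to treatment.

Internal simulation times are fractional years relative to diagnosis and are
emitted as calendar dates at 365.25 days/year.  A truth ledger (per
individual and per observation) is attached for recovery tests and written
to separate files never read by the analysis modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import cohort as _cohort
from .cohort import YEARS_PER_DAY, age_band, calendar_band_post, calendar_band_pre
from .exposures import DRUG_CLASSES, hba1c_category, pair_hba1c, regimen_at

__all__ = [
    "SimConfig", "EmrBundle", "SchemaError",
    "generate_bundle", "write_bundle", "read_bundle", "latent_bmi",
]

# Horizon of simulated measurement processes (years relative to diagnosis);
# slightly wider than the -3..+5 study window so window edges are populated.
BMI_TIME_SPAN = (-3.2, 5.2)
HBA1C_TIME_SPAN = (-1.0, 5.4)
RX_EPISODE_END = 5.3

#: Simulation-input effect magnitudes (kg/m2).  These are plausible values
#: for a realistic synthetic cohort, not reproduction targets.
DEFAULT_DRUG_EFFECTS: dict[str, float] = {
    "mono:metformin": -0.32,
    "mono:sulfonylurea": 0.31,
    "mono:thiazolidinedione": 1.22,
    "insulin_any": 0.29,
    "dual:metformin+sglt2i": -1.04,
    "dual:glp1ra+metformin": -0.79,
    "dual:dpp4i+metformin": -0.39,
}

DEFAULT_HBA1C_EFFECTS: dict[str, float] = {
    "no_change": 0.0,
    "dec_0_10": -0.15,
    "dec_ge10": -0.43,
    "inc_0_10": 0.15,
    "inc_ge10": 0.48,
}

#: Additive slope shifts (kg/m2/year) by banded covariate, keyed
#: "<period>:<covariate>:<level>" with period in {pre, peri, post} and
#: covariate in {age_band, sex, deprivation, calendar_band}.
DEFAULT_COVARIATE_SLOPE_EFFECTS: dict[str, float] = {
    "pre:age_band:<50": 0.38,
    "pre:age_band:50-<60": 0.27,
    "pre:age_band:60-<70": 0.16,
    "pre:deprivation:1": 0.15,
    "pre:deprivation:2": 0.15,
    "post:age_band:<50": 0.08,
    "post:age_band:50-<60": 0.14,
    "post:age_band:60-<70": 0.11,
    "post:sex:F": -0.08,
}

_SUPPORTED_EFFECT_COVARIATES = {"age_band", "sex", "deprivation", "calendar_band"}

# (scenario probability, drug classes in start order)
TREATMENT_SCENARIOS: list[tuple[float, tuple[str, ...]]] = [
    (0.30, ()),
    (0.30, ("metformin",)),
    (0.06, ("sulfonylurea",)),
    (0.08, ("thiazolidinedione",)),
    (0.06, ("metformin", "insulin")),
    (0.06, ("metformin", "sglt2i")),
    (0.05, ("metformin", "glp1ra")),
    (0.09, ("metformin", "dpp4i")),
]


class SchemaError(ValueError):
    """Raised when a bundle table violates its schema; names offending rows."""


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.  Defaults describe the emulated study conditions."""

    n_individuals: int = 1000
    seed: int = 0
    diagnosis_year_range: tuple[int, int] = (2003, 2014)
    #: (mean years, sd years, floor) — floor enforced by resampling
    age_at_diagnosis_dist: tuple[float, float, float] = (65.6, 10.1, 35.0)
    sex_ratio: float = 0.43  # proportion female
    deprivation_probs: tuple[float, ...] = (0.21, 0.23, 0.19, 0.17, 0.20)
    deprivation_missing_prob: float = 0.02
    #: (mean, sd, floor) of the latent BMI at +1 year (kg/m2)
    baseline_bmi_dist: tuple[float, float, float] = (33.0, 5.9, 25.0)
    slope_pre: tuple[float, float] = (0.25, 0.50)    # (mean, sd) kg/m2/year
    slope_peri: tuple[float, float] = (-0.25, 0.75)
    slope_post: tuple[float, float] = (-0.14, 0.45)
    covariate_slope_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_SLOPE_EFFECTS))
    drug_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DRUG_EFFECTS))
    hba1c_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HBA1C_EFFECTS))
    resid_sd: float = 0.8        # kg/m2
    resid_rho: float = 0.5       # correlation per unit year gap, in [0, 1)
    visit_rate: float = 1.7      # expected BMI measurements / year
    hba1c_rate: float = 2.0      # expected HbA1c measurements / year
    missing_prob: float = 0.1    # probability a scheduled measurement is dropped

    def validate(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if abs(sum(self.deprivation_probs) - 1.0) > 1e-9:
            raise ValueError("deprivation_probs must sum to 1")
        for name in ("sex_ratio", "deprivation_missing_prob", "missing_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if any(p < 0 for p in self.deprivation_probs):
            raise ValueError("deprivation_probs must be non-negative")
        if not 0.0 <= self.resid_rho < 1.0:
            raise ValueError(
                "resid_rho must be in [0,1): the spatial-power correlation "
                "rho**|dt| is undefined for negative rho at fractional gaps")
        if self.resid_sd <= 0:
            raise ValueError("resid_sd must be positive")
        if self.visit_rate <= 0 or self.hba1c_rate <= 0:
            raise ValueError("measurement rates must be positive")
        ylo, yhi = self.diagnosis_year_range
        if ylo > yhi:
            raise ValueError("diagnosis_year_range must be (lo, hi) with lo <= hi")
        for key in self.covariate_slope_effects:
            parts = key.split(":")
            if len(parts) != 3 or parts[0] not in ("pre", "peri", "post") \
                    or parts[1] not in _SUPPORTED_EFFECT_COVARIATES:
                raise ValueError(
                    f"covariate_slope_effects key {key!r} not of form "
                    "'<pre|peri|post>:<age_band|sex|deprivation|calendar_band>:<level>'")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class EmrBundle:
    """The four raw tables, plus (when simulated) the truth ledger."""

    demographics: pd.DataFrame   # id, sex, birth_date, diagnosis_date, deprivation_quintile
    bmi_obs: pd.DataFrame        # id, date, bmi
    hba1c_obs: pd.DataFrame      # id, date, hba1c
    rx_episodes: pd.DataFrame    # id, drug_class, start_date, end_date
    truth: Optional[pd.DataFrame] = None       # per individual
    truth_obs: Optional[pd.DataFrame] = None   # per BMI observation

    def validate(self) -> None:
        _validate_bundle(self)


def latent_bmi(t, base_1y, slope_pre, slope_peri, slope_post):
    """Latent piecewise-linear BMI with knots at -0.5 and +1 years.

    ``base_1y`` anchors the line at t = +1; the peri segment spans
    [-0.5, 1) and the pre segment extends leftward from -0.5.
    """
    t = np.asarray(t, dtype=float)
    post = base_1y + slope_post * (t - 1.0)
    peri = base_1y - slope_peri * (1.0 - t)
    pre = base_1y - 1.5 * slope_peri + slope_pre * (t + 0.5)
    return np.where(t >= 1.0, post, np.where(t >= -0.5, peri, pre))


def _truncated_normal(rng, mean, sd, floor, size):
    x = rng.normal(mean, sd, size)
    while True:
        bad = x < floor
        if not bad.any():
            return x
        x[bad] = rng.normal(mean, sd, bad.sum())


def _poisson_times(rng, rate, span, missing_prob):
    lo, hi = span
    n = rng.poisson(rate * (hi - lo))
    t = np.sort(rng.uniform(lo, hi, n))
    if missing_prob > 0 and n:
        t = t[rng.random(n) >= missing_prob]
    return t


def _slope_effect(effects, period, attrs):
    total = 0.0
    for cov, level in attrs.items():
        total += effects.get(f"{period}:{cov}:{level}", 0.0)
    return total


def _to_date(dx_date: pd.Timestamp, t: float) -> pd.Timestamp:
    return dx_date + pd.Timedelta(days=round(t / YEARS_PER_DAY))


def generate_bundle(config: SimConfig) -> EmrBundle:
    """Simulate an EMR bundle under ``config``.  Same seed, same bundle."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_individuals

    ids = [f"P{i:06d}" for i in range(1, n + 1)]
    sex = np.where(rng.random(n) < config.sex_ratio, "F", "M")
    ylo, yhi = config.diagnosis_year_range
    dx_year = rng.integers(ylo, yhi + 1, n)
    dx_day = rng.integers(0, 365, n)
    dx_dates = pd.to_datetime([f"{y}-01-01" for y in dx_year]) + pd.to_timedelta(dx_day, unit="D")
    mean_a, sd_a, floor_a = config.age_at_diagnosis_dist
    age_dx = _truncated_normal(rng, mean_a, sd_a, floor_a, n)
    birth_dates = dx_dates - pd.to_timedelta(np.round(age_dx / YEARS_PER_DAY), unit="D")

    dep = np.array([float(d) for d in rng.choice(
        [1, 2, 3, 4, 5], size=n, p=np.asarray(config.deprivation_probs, dtype=float)
        / sum(config.deprivation_probs))])
    dep[rng.random(n) < config.deprivation_missing_prob] = np.nan

    mean_b, sd_b, floor_b = config.baseline_bmi_dist
    base_1y = _truncated_normal(rng, mean_b, sd_b, floor_b, n)

    scen_p = np.array([p for p, _ in TREATMENT_SCENARIOS])
    scen_idx = rng.choice(len(TREATMENT_SCENARIOS), size=n, p=scen_p / scen_p.sum())

    demo_rows, bmi_rows, hba1c_rows, rx_rows = [], [], [], []
    truth_rows, truth_obs_rows = [], []
    eff = config.covariate_slope_effects

    for i in range(n):
        pid = ids[i]
        dx = dx_dates[i]
        attrs_post = {
            "age_band": age_band(age_dx[i]),
            "sex": str(sex[i]),
            "deprivation": _cohort.deprivation_level(dep[i]),
            "calendar_band": calendar_band_post(int(dx_year[i])) if 2003 <= dx_year[i] <= 2014 else "other",
        }
        attrs_pre = dict(attrs_post)
        attrs_pre["age_band"] = age_band(age_dx[i] - 3.0)
        attrs_pre["calendar_band"] = calendar_band_pre(int(dx_year[i]) - 3)

        s_pre = rng.normal(*config.slope_pre) + _slope_effect(eff, "pre", attrs_pre)
        s_peri = rng.normal(*config.slope_peri) + _slope_effect(eff, "peri", attrs_post)
        s_post = rng.normal(*config.slope_post) + _slope_effect(eff, "post", attrs_post)

        # dispensing episodes
        _, classes = TREATMENT_SCENARIOS[scen_idx[i]]
        episodes = []
        t_start = None
        for j, cls in enumerate(classes):
            if j == 0:
                t_start = rng.uniform(0.2, 2.5)
            else:
                t_start = t_start + rng.uniform(0.5, 2.0)
            episodes.append((cls, float(t_start), RX_EPISODE_END))
            rx_rows.append({
                "id": pid, "drug_class": cls,
                "start_date": _to_date(dx, t_start), "end_date": _to_date(dx, RX_EPISODE_END),
            })

        # HbA1c series: random walk, drift responds to active treatment
        h_times = _poisson_times(rng, config.hba1c_rate, HBA1C_TIME_SPAN, config.missing_prob)
        h_values = np.empty_like(h_times)
        level = max(rng.normal(52.0, 11.0), 27.0)
        prev_t = HBA1C_TIME_SPAN[0]
        for k, tk in enumerate(h_times):
            dt = tk - prev_t
            treated = any(start <= tk <= end for _, start, end in episodes)
            drift = -3.0 if treated else 1.2
            level = max(level + drift * dt + rng.normal(0.0, 4.0 * np.sqrt(max(dt, 1e-9))), 20.0)
            h_values[k] = level
            prev_t = tk
        for tk, vk in zip(h_times, h_values):
            hba1c_rows.append({"id": pid, "date": _to_date(dx, tk), "hba1c": float(vk)})

        # BMI observations with correlated errors
        b_times = _poisson_times(rng, config.visit_rate, BMI_TIME_SPAN, config.missing_prob)
        m = len(b_times)
        if m:
            D = np.abs(b_times[:, None] - b_times[None, :])
            cov = (config.resid_sd ** 2) * (config.resid_rho ** D)
            cov[np.diag_indices(m)] += 1e-12  # guard against coincident times
            errors = np.linalg.cholesky(cov) @ rng.standard_normal(m)
        else:
            errors = np.empty(0)

        post_baseline = h_times >= 1.0
        if post_baseline.any():
            baseline_h = float(h_values[post_baseline][np.argmin(h_times[post_baseline])])
            ht_b, hv_b = h_times[post_baseline], h_values[post_baseline]
        else:
            baseline_h, ht_b, hv_b = None, np.empty(0), np.empty(0)

        latent = latent_bmi(b_times, base_1y[i], s_pre, s_peri, s_post)
        for k, tk in enumerate(b_times):
            reg = regimen_at(episodes, float(tk))
            if tk >= 1.0 and baseline_h is not None:
                paired = pair_hba1c(ht_b, hv_b, float(tk), 90.0 * YEARS_PER_DAY)
                cat = "no_change" if paired is None else hba1c_category(baseline_h, paired)
            else:
                cat = "no_change"
            value = (latent[k]
                     + config.drug_effects.get(reg, 0.0)
                     + config.hba1c_effects.get(cat, 0.0)
                     + errors[k])
            bmi_rows.append({"id": pid, "date": _to_date(dx, tk), "bmi": float(value)})
            truth_obs_rows.append({
                "id": pid, "time": float(tk), "latent_bmi": float(latent[k]),
                "regimen": reg, "hba1c_category": cat, "error": float(errors[k]),
            })

        demo_rows.append({
            "id": pid, "sex": str(sex[i]),
            "birth_date": birth_dates[i], "diagnosis_date": dx,
            "deprivation_quintile": dep[i],
        })
        truth_rows.append({
            "id": pid, "latent_bmi_1y": float(base_1y[i]),
            "slope_pre": float(s_pre), "slope_peri": float(s_peri),
            "slope_post": float(s_post),
            "treatment_classes": "+".join(classes) if classes else "none",
        })

    bundle = EmrBundle(
        demographics=pd.DataFrame(demo_rows, columns=[
            "id", "sex", "birth_date", "diagnosis_date", "deprivation_quintile"]),
        bmi_obs=pd.DataFrame(bmi_rows, columns=["id", "date", "bmi"]),
        hba1c_obs=pd.DataFrame(hba1c_rows, columns=["id", "date", "hba1c"]),
        rx_episodes=pd.DataFrame(rx_rows, columns=[
            "id", "drug_class", "start_date", "end_date"]),
        truth=pd.DataFrame(truth_rows, columns=[
            "id", "latent_bmi_1y", "slope_pre", "slope_peri", "slope_post",
            "treatment_classes"]),
        truth_obs=pd.DataFrame(truth_obs_rows, columns=[
            "id", "time", "latent_bmi", "regimen", "hba1c_category", "error"]),
    )
    bundle.validate()
    return bundle


# --- schema validation and CSV round-trip ---------------------------------

_REQUIRED_COLUMNS = {
    "demographics": ["id", "sex", "birth_date", "diagnosis_date", "deprivation_quintile"],
    "bmi_obs": ["id", "date", "bmi"],
    "hba1c_obs": ["id", "date", "hba1c"],
    "rx_episodes": ["id", "drug_class", "start_date", "end_date"],
}


def _offending(rows) -> str:
    idx = list(rows[:10])
    more = "" if len(rows) <= 10 else f" (+{len(rows) - 10} more)"
    return f"rows {idx}{more}"


def _validate_bundle(bundle: EmrBundle) -> None:
    for name, cols in _REQUIRED_COLUMNS.items():
        df = getattr(bundle, name)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise SchemaError(f"{name}: missing column(s) {missing}")
    known = set(bundle.demographics["id"])
    if bundle.demographics["id"].duplicated().any():
        dup = bundle.demographics.index[bundle.demographics["id"].duplicated()].tolist()
        raise SchemaError(f"demographics: duplicate id at {_offending(dup)}")
    for name in ("bmi_obs", "hba1c_obs", "rx_episodes"):
        df = getattr(bundle, name)
        bad = df.index[~df["id"].isin(known)].tolist()
        if bad:
            raise SchemaError(f"{name}: column 'id' has unknown ids at {_offending(bad)}")
    bad = bundle.bmi_obs.index[bundle.bmi_obs["bmi"] <= 0].tolist()
    if bad:
        raise SchemaError(f"bmi_obs: column 'bmi' non-positive at {_offending(bad)}")
    bad = bundle.hba1c_obs.index[bundle.hba1c_obs["hba1c"] <= 0].tolist()
    if bad:
        raise SchemaError(f"hba1c_obs: column 'hba1c' non-positive at {_offending(bad)}")
    rx = bundle.rx_episodes
    if len(rx):
        start = pd.to_datetime(rx["start_date"])
        end = pd.to_datetime(rx["end_date"])
        bad = rx.index[end < start].tolist()
        if bad:
            raise SchemaError(
                f"rx_episodes: column 'end_date' earlier than 'start_date' at {_offending(bad)}")
        unknown = rx.index[~rx["drug_class"].isin(DRUG_CLASSES)].tolist()
        if unknown:
            raise SchemaError(
                f"rx_episodes: column 'drug_class' has unknown classes at {_offending(unknown)}")


_DATE_COLUMNS = {
    "demographics": ["birth_date", "diagnosis_date"],
    "bmi_obs": ["date"],
    "hba1c_obs": ["date"],
    "rx_episodes": ["start_date", "end_date"],
}

_TABLE_FILES = {
    "demographics": "demographics.csv",
    "bmi_obs": "bmi_obs.csv",
    "hba1c_obs": "hba1c_obs.csv",
    "rx_episodes": "rx_episodes.csv",
    "truth": "truth.csv",
    "truth_obs": "truth_obs.csv",
}


def write_bundle(bundle: EmrBundle, directory) -> list[Path]:
    """Write the bundle as CSV files (ISO-8601 dates, lossless floats).

    Missing deprivation is written as an empty field.  The truth ledger goes
    to separate files that the analysis modules never read.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, fname in _TABLE_FILES.items():
        df = getattr(bundle, name)
        if df is None:
            continue
        out = df.copy()
        for col in _DATE_COLUMNS.get(name, []):
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
        if name == "demographics":
            out["deprivation_quintile"] = out["deprivation_quintile"].map(
                lambda q: "" if pd.isna(q) else str(int(q)))
        path = directory / fname
        out.to_csv(path, index=False)
        written.append(path)
    return written


def read_bundle(directory) -> EmrBundle:
    """Read a bundle written by :func:`write_bundle`; validates the schema."""
    directory = Path(directory)
    tables = {}
    for name, fname in _TABLE_FILES.items():
        path = directory / fname
        if not path.exists():
            if name in ("truth", "truth_obs"):
                tables[name] = None
                continue
            raise FileNotFoundError(f"missing required bundle file: {path}")
        df = pd.read_csv(path)
        for col in _DATE_COLUMNS.get(name, []):
            if col in df.columns:
                try:
                    df[col] = pd.to_datetime(df[col], format="%Y-%m-%d")
                except (ValueError, TypeError) as exc:
                    raise SchemaError(f"{name}: column '{col}' has unparseable dates ({exc})")
        if name == "demographics" and "deprivation_quintile" in df.columns:
            df["deprivation_quintile"] = pd.to_numeric(
                df["deprivation_quintile"], errors="coerce")
        tables[name] = df
    bundle = EmrBundle(**tables)
    bundle.validate()
    return bundle
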