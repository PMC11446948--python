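"""Cohort construction: study windows, anchor measurements and eligibility.

The study design follows individuals from 3 years before to 5 years after
clinical diagnosis of type 2 diabetes.  Eligibility requires four anchor BMI
measurements — the observation closest to a target time within a fixed
window on the diagnosis-relative time axis:

====== =============== ==============
anchor target (years)  window (years)
====== =============== ==============
BMI-3      -3.0          [-3, -2]
BMI-0.5    -0.5          [-1.5, -0.5]
BMI1       +1.0          [1, 2]
BMI5       +5.0          [4, 5]
====== =============== ==============

plus diagnosis at age >= 35 within the configured calendar range, BMI1 >= 25
kg/m2, and at least one HbA1c measurement in the [1, 2) year window after
diagnosis.  The peri-diagnosis period (-0.5 to +1 years) is excluded from
both trajectory models and summarised by a simple annualised rate,
``(BMI1 - BMI-0.5) / (t1 - t-0.5)``.

All categorical covariates use fixed, pre-specified cut-points (never
recomputed quantiles).  Window endpoints are closed on both sides except the
HbA1c eligibility window, which is [1, 2) so that year-bins stay disjoint.
Anchor ties (two in-window observations equidistant from the target) resolve
to the earlier observation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

YEARS_PER_DAY = 1.0 / 365.25
DEFAULT_DIAGNOSIS_YEARS = (2003, 2014)
MIN_AGE_AT_DIAGNOSIS = 35.0
MIN_BMI_1 = 25.0

#: (target time, window lo, window hi), years relative to diagnosis
ANCHOR_SPECS = {
    "bmi_m3": (-3.0, -3.0, -2.0),
    "bmi_m05": (-0.5, -1.5, -0.5),
    "bmi_1": (1.0, 1.0, 2.0),
    "bmi_5": (5.0, 4.0, 5.0),
}

PRE_WINDOW = (-3.0, -0.5)
PERI_WINDOW = (-0.5, 1.0)
POST_WINDOW = (1.0, 5.0)
HBA1C_ELIG_WINDOW = (1.0, 2.0)  # [lo, hi)

# --- fixed bands -----------------------------------------------------------

AGE_BAND_LEVELS = ["<50", "50-<60", "60-<70", ">=70"]
BMI_BAND_PRE_LEVELS = ["<30", "30-<35", "35-<40", ">=40"]
BMI_BAND_POST_LEVELS = ["25-<30", "30-<35", "35-<40", ">=40"]
HBA1C_BAND_LEVELS = ["<43", "43-<48", "48-<54", ">=54"]
CALENDAR_BAND_PRE_LEVELS = ["<2006", "2006-2007", "2008-2009", ">=2010"]
CALENDAR_BAND_POST_LEVELS = ["2003-2008", "2009-2010", "2011-2012", "2013-2014"]
DEPRIVATION_LEVELS = ["1", "2", "3", "4", "5", "missing"]
SEX_LEVELS = ["F", "M"]

RATE_CATEGORIES = [
    "rapid loss",
    "moderate loss",
    "slow loss",
    "stable",
    "slow gain",
    "moderate gain",
    "rapid gain",
]


def age_band(age: float) -> str:
    """Age band (years): <50, 50-<60, 60-<70, >=70."""
    if age < 50:
        return "<50"
    if age < 60:
        return "50-<60"
    if age < 70:
        return "60-<70"
    return ">=70"


def bmi_band_pre(bmi: float) -> str:
    if bmi < 30:
        return "<30"
    if bmi < 35:
        return "30-<35"
    if bmi < 40:
        return "35-<40"
    return ">=40"


def bmi_band_post(bmi: float) -> str:
    """Post-diagnosis BMI band; only defined for BMI >= 25 (eligibility floor)."""
    if bmi < 25:
        raise ValueError(f"post-diagnosis BMI band undefined below 25 (got {bmi})")
    if bmi < 30:
        return "25-<30"
    if bmi < 35:
        return "30-<35"
    if bmi < 40:
        return "35-<40"
    return ">=40"


def hba1c_band(value: float) -> str:
    """HbA1c (mmol/mol) quartile band at ~1 year after diagnosis."""
    if value < 43:
        return "<43"
    if value < 48:
        return "43-<48"
    if value < 54:
        return "48-<54"
    return ">=54"


def calendar_band_pre(year: int) -> str:
    """Calendar band at the BMI-3 anchor.  The final band is open-ended so the
    banding stays exhaustive for diagnoses through the end of the study range."""
    if year < 2006:
        return "<2006"
    if year <= 2007:
        return "2006-2007"
    if year <= 2009:
        return "2008-2009"
    return ">=2010"


def calendar_band_post(year: int) -> str:
    """Calendar band of the diagnosis year (diagnoses restricted to 2003-2014)."""
    if year < 2003 or year > 2014:
        raise ValueError(f"diagnosis year {year} outside supported range 2003-2014")
    if year <= 2008:
        return "2003-2008"
    if year <= 2010:
        return "2009-2010"
    if year <= 2012:
        return "2011-2012"
    return "2013-2014"


def deprivation_level(q) -> str:
    """Deprivation quintile 1 (most deprived) .. 5, or 'missing'."""
    if q is None or (isinstance(q, float) and math.isnan(q)) or pd.isna(q):
        return "missing"
    qi = int(q)
    if not 1 <= qi <= 5:
        raise ValueError(f"deprivation quintile must be 1-5, got {q}")
    return str(qi)


def categorize_rate(rate: float) -> str:
    """Map an annual BMI-change rate (kg/m2/year) to the 7-level category.

    Stable is the closed band [-0.1, 0.1]; slow is (0.1, 0.3], moderate
    (0.3, 0.5] and rapid (0.5, inf) in absolute value, signed loss/gain.
    """
    if not math.isfinite(rate):
        raise ValueError(f"rate must be finite, got {rate}")
    a = abs(rate)
    if a <= 0.1:
        return "stable"
    if a <= 0.3:
        mag = "slow"
    elif a <= 0.5:
        mag = "moderate"
    else:
        mag = "rapid"
    return f"{mag} {'gain' if rate > 0 else 'loss'}"


# --- anchors ---------------------------------------------------------------


def select_anchor(times, values, target: float, window: tuple[float, float]):
    """Observation closest to ``target`` within the closed ``window``.

    Returns ``(time, value)`` or ``None`` when no observation falls in the
    window.  Equidistant in-window observations resolve to the earlier one.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError(f"window must satisfy lo < hi, got {window}")
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    inside = (times >= lo) & (times <= hi)
    if not inside.any():
        return None
    t_in, v_in = times[inside], values[inside]
    dist = np.abs(t_in - target)
    best = dist.min()
    cand = np.flatnonzero(dist == best)
    # tie: earlier time wins
    k = cand[np.argmin(t_in[cand])]
    return float(t_in[k]), float(v_in[k])


def peri_change(t_m05: float, bmi_m05: float, t_1: float, bmi_1: float) -> float:
    """Annualised peri-diagnosis weight change (BMI1 - BMI-0.5) / (t1 - t-0.5)."""
    dt = t_1 - t_m05
    if dt == 0:
        raise ValueError("anchor times coincide; peri-diagnosis rate undefined")
    return (bmi_1 - bmi_m05) / dt


# --- cohort assembly -------------------------------------------------------

EXCLUSION_FILTERS = [
    "diagnosis year outside range",
    "age at diagnosis < 35",
    "missing pre-diagnosis anchors",
    "missing post-diagnosis anchors",
    "BMI_1 < 25",
    "no HbA1c in [1,2) years",
]

COHORT_COLUMNS = [
    "id", "sex", "age_at_diagnosis", "deprivation",
    "age_band_pre", "age_band_post",
    "calendar_band_pre", "calendar_band_post",
    "bmi_band_pre", "bmi_band_post", "hba1c_band",
    "t_bmi_m3", "bmi_m3", "t_bmi_m05", "bmi_m05",
    "t_bmi_1", "bmi_1", "t_bmi_5", "bmi_5",
    "hba1c_1y", "peri_change", "peri_category",
]


@dataclass
class CohortResult:
    cohort: pd.DataFrame      # one row per eligible individual (COHORT_COLUMNS)
    exclusions: pd.DataFrame  # (filter, count), sequential


def relative_years(dates: pd.Series, diagnosis_date) -> np.ndarray:
    """Diagnosis-relative time in years (365.25-day years)."""
    delta = pd.to_datetime(dates) - pd.to_datetime(diagnosis_date)
    return delta.dt.days.to_numpy(dtype=float) * YEARS_PER_DAY


def build_cohort(bundle, diagnosis_year_range=DEFAULT_DIAGNOSIS_YEARS) -> CohortResult:
    """Apply the sequential eligibility filters and assemble cohort records.

    Filters run in a fixed order and each individual is logged against the
    first filter that excludes them, so the exclusion counts sum to the total
    number excluded (flow-chart style).
    """
    demo = bundle.demographics
    bmi_by_id = dict(tuple(bundle.bmi_obs.groupby("id", sort=False)))
    hba1c_by_id = dict(tuple(bundle.hba1c_obs.groupby("id", sort=False)))

    counts = {name: 0 for name in EXCLUSION_FILTERS}
    records = []
    ylo, yhi = diagnosis_year_range

    for row in demo.itertuples(index=False):
        dx_date = pd.Timestamp(row.diagnosis_date)
        if not ylo <= dx_date.year <= yhi:
            counts["diagnosis year outside range"] += 1
            continue
        age_dx = (dx_date - pd.Timestamp(row.birth_date)).days * YEARS_PER_DAY
        if age_dx < MIN_AGE_AT_DIAGNOSIS:
            counts["age at diagnosis < 35"] += 1
            continue

        obs = bmi_by_id.get(row.id)
        if obs is None or len(obs) == 0:
            counts["missing pre-diagnosis anchors"] += 1
            continue
        t = relative_years(obs["date"], dx_date)
        v = obs["bmi"].to_numpy(dtype=float)

        anchors = {}
        for name, (target, lo, hi) in ANCHOR_SPECS.items():
            anchors[name] = select_anchor(t, v, target, (lo, hi))
        if anchors["bmi_m3"] is None or anchors["bmi_m05"] is None:
            counts["missing pre-diagnosis anchors"] += 1
            continue
        if anchors["bmi_1"] is None or anchors["bmi_5"] is None:
            counts["missing post-diagnosis anchors"] += 1
            continue
        t1, bmi1 = anchors["bmi_1"]
        if bmi1 < MIN_BMI_1:
            counts["BMI_1 < 25"] += 1
            continue

        hobs = hba1c_by_id.get(row.id)
        hba1c_1y = None
        if hobs is not None and len(hobs):
            ht = relative_years(hobs["date"], dx_date)
            hv = hobs["hba1c"].to_numpy(dtype=float)
            lo, hi = HBA1C_ELIG_WINDOW
            inside = (ht >= lo) & (ht < hi)
            if inside.any():
                hti, hvi = ht[inside], hv[inside]
                dist = np.abs(hti - 1.0)
                cand = np.flatnonzero(dist == dist.min())
                k = cand[np.argmin(hti[cand])]
                hba1c_1y = float(hvi[k])
        if hba1c_1y is None:
            counts["no HbA1c in [1,2) years"] += 1
            continue

        tm3, bm3 = anchors["bmi_m3"]
        tm05, bm05 = anchors["bmi_m05"]
        t5, bmi5 = anchors["bmi_5"]
        peri = peri_change(tm05, bm05, t1, bmi1)
        year_m3 = (dx_date + pd.Timedelta(days=round(tm3 / YEARS_PER_DAY))).year
        records.append({
            "id": row.id,
            "sex": row.sex,
            "age_at_diagnosis": age_dx,
            "deprivation": deprivation_level(row.deprivation_quintile),
            "age_band_pre": age_band(age_dx + tm3),
            "age_band_post": age_band(age_dx),
            "calendar_band_pre": calendar_band_pre(year_m3),
            "calendar_band_post": calendar_band_post(dx_date.year),
            "bmi_band_pre": bmi_band_pre(bm3),
            "bmi_band_post": bmi_band_post(bmi1),
            "hba1c_band": hba1c_band(hba1c_1y),
            "t_bmi_m3": tm3, "bmi_m3": bm3,
            "t_bmi_m05": tm05, "bmi_m05": bm05,
            "t_bmi_1": t1, "bmi_1": bmi1,
            "t_bmi_5": t5, "bmi_5": bmi5,
            "hba1c_1y": hba1c_1y,
            "peri_change": peri,
            "peri_category": categorize_rate(peri),
        })

    cohort = pd.DataFrame.from_records(records, columns=COHORT_COLUMNS)
    exclusions = pd.DataFrame(
        {"filter": EXCLUSION_FILTERS, "count": [counts[f] for f in EXCLUSION_FILTERS]}
    )
    return CohortResult(cohort=cohort, exclusions=exclusions)
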