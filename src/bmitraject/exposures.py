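"""Time-varying exposure coding for the post-diagnosis trajectory model.

Each post-diagnosis BMI observation carries two exposure states, fitted as
fixed-effect offsets (kg/m2) in the mixed model:

* the diabetes-drug regimen active on the observation date, grouped by class
  (metformin, sulfonylurea, thiazolidinedione, DPP4i, GLP-1RA, SGLT2i,
  insulin) and then by therapy pattern — none (reference, before any drug is
  started), monotherapy, dual/triple combinations, insulin with anything;
* the HbA1c change category: percentage change of the paired HbA1c
  measurement from the individual's baseline (the first HbA1c after 1 year
  from diagnosis), in five groups — no change (reference), >0 to <10%
  decrease, >=10% decrease, >0 to <10% increase, >=10% increase.

Any regimen containing insulin is coded ``insulin_any`` regardless of
co-therapy.  Class sets are order-normalised alphabetically so each
combination has exactly one spelling; four or more non-insulin classes pool
into ``quad_plus``.

HbA1c pairing uses the most recent measurement at or before the BMI date,
falling back to the nearest within a configurable window (default 90 days);
observations with no pairable measurement carry the reference category and
are flagged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import POST_WINDOW, YEARS_PER_DAY, relative_years

DRUG_CLASSES = [
    "dpp4i", "glp1ra", "insulin", "metformin",
    "sglt2i", "sulfonylurea", "thiazolidinedione",
]
NON_INSULIN_CLASSES = [c for c in DRUG_CLASSES if c != "insulin"]

HBA1C_CATEGORIES = ["no_change", "dec_0_10", "dec_ge10", "inc_0_10", "inc_ge10"]

REGIMEN_NONE = "none"
REGIMEN_INSULIN = "insulin_any"
REGIMEN_QUAD_PLUS = "quad_plus"

DESIGN_POST_COLUMNS = ["id", "time", "bmi", "regimen", "hba1c_category", "hba1c_unpaired"]


def regimen_label(active_classes) -> str:
    """Canonical regimen label for a set of active drug classes."""
    classes = set(active_classes)
    unknown = classes - set(DRUG_CLASSES)
    if unknown:
        raise ValueError(f"unknown drug class(es): {sorted(unknown)}")
    if "insulin" in classes:
        return REGIMEN_INSULIN
    if not classes:
        return REGIMEN_NONE
    ordered = sorted(classes)
    if len(ordered) == 1:
        return f"mono:{ordered[0]}"
    if len(ordered) == 2:
        return "dual:" + "+".join(ordered)
    if len(ordered) == 3:
        return "triple:" + "+".join(ordered)
    return REGIMEN_QUAD_PLUS


def regimen_at(episodes, t: float, grace_years: float = 0.0) -> str:
    """Regimen active at diagnosis-relative time ``t``.

    ``episodes`` is an iterable of ``(drug_class, start_t, end_t)`` with times
    in years relative to diagnosis; an episode covers ``[start, end + grace]``.
    """
    active = {
        cls for cls, start, end in episodes
        if start <= t <= end + grace_years
    }
    return regimen_label(active)


def hba1c_category(baseline: float, current: float) -> str:
    """Five-level percentage-change category vs the post-1-year baseline.

    Zero change is the reference; the +/-10% boundaries belong to the >=10%
    categories.
    """
    if baseline <= 0:
        raise ValueError(f"baseline HbA1c must be positive, got {baseline}")
    p = 100.0 * (current - baseline) / baseline
    if p == 0:
        return "no_change"
    if p <= -10:
        return "dec_ge10"
    if p < 0:
        return "dec_0_10"
    if p >= 10:
        return "inc_ge10"
    return "inc_0_10"


def pair_hba1c(h_times, h_values, t: float, window_years: float):
    """HbA1c value paired to a BMI observation at time ``t``.

    Most recent measurement at or before ``t``; otherwise the nearest within
    ``window_years``; otherwise ``None``.
    """
    h_times = np.asarray(h_times, dtype=float)
    h_values = np.asarray(h_values, dtype=float)
    if h_times.size == 0:
        return None
    before = h_times <= t
    if before.any():
        k = np.flatnonzero(before)[np.argmax(h_times[before])]
        return float(h_values[k])
    dist = np.abs(h_times - t)
    k = int(np.argmin(dist))
    if dist[k] <= window_years:
        return float(h_values[k])
    return None


def episodes_relative(rx: pd.DataFrame, diagnosis_date) -> list[tuple[str, float, float]]:
    """Convert an individual's dispensing episodes to diagnosis-relative years."""
    if rx is None or len(rx) == 0:
        return []
    start = relative_years(rx["start_date"], diagnosis_date)
    end = relative_years(rx["end_date"], diagnosis_date)
    return list(zip(rx["drug_class"], start, end))


def attach_exposures(
    bundle,
    cohort: pd.DataFrame,
    grace_days: float = 0.0,
    pairing_window_days: float = 90.0,
    post_window: tuple[float, float] = POST_WINDOW,
) -> pd.DataFrame:
    """Stack post-window BMI observations with regimen and HbA1c-change codes.

    Returns one row per BMI observation with time in ``post_window`` (closed)
    for each cohort individual: id, time, bmi, regimen, hba1c_category and a
    flag for observations whose HbA1c category fell back to the reference
    because no measurement was pairable.
    """
    grace = grace_days * YEARS_PER_DAY
    pair_window = pairing_window_days * YEARS_PER_DAY
    lo, hi = post_window

    demo = bundle.demographics.set_index("id")
    bmi_by_id = dict(tuple(bundle.bmi_obs.groupby("id", sort=False)))
    hba1c_by_id = dict(tuple(bundle.hba1c_obs.groupby("id", sort=False)))
    rx_by_id = dict(tuple(bundle.rx_episodes.groupby("id", sort=False)))

    rows = []
    for pid in cohort["id"]:
        dx = pd.Timestamp(demo.loc[pid, "diagnosis_date"])
        obs = bmi_by_id.get(pid)
        if obs is None or len(obs) == 0:
            continue
        t = relative_years(obs["date"], dx)
        v = obs["bmi"].to_numpy(dtype=float)
        inside = (t >= lo) & (t <= hi)
        if not inside.any():
            continue
        episodes = episodes_relative(rx_by_id.get(pid), dx)

        hobs = hba1c_by_id.get(pid)
        if hobs is not None and len(hobs):
            ht = relative_years(hobs["date"], dx)
            hv = hobs["hba1c"].to_numpy(dtype=float)
        else:
            ht = np.empty(0)
            hv = np.empty(0)
        post_baseline = ht >= 1.0
        if not post_baseline.any():
            # cannot occur for eligible individuals (HbA1c in [1,2) required)
            raise ValueError(f"individual {pid} has no baseline HbA1c after 1 year")
        k0 = np.flatnonzero(post_baseline)[np.argmin(ht[post_baseline])]
        baseline = float(hv[k0])
        ht_b, hv_b = ht[post_baseline], hv[post_baseline]

        for ti, vi in zip(t[inside], v[inside]):
            paired = pair_hba1c(ht_b, hv_b, ti, pair_window)
            if paired is None:
                cat, unpaired = "no_change", True
            else:
                cat, unpaired = hba1c_category(baseline, paired), False
            rows.append({
                "id": pid,
                "time": float(ti),
                "bmi": float(vi),
                "regimen": regimen_at(episodes, float(ti), grace),
                "hba1c_category": cat,
                "hba1c_unpaired": unpaired,
            })

    return pd.DataFrame(rows, columns=DESIGN_POST_COLUMNS)
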