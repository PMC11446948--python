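"""The two trajectory analyses: pre-diagnosis and exposure-adjusted post-diagnosis.

Each analysis follows the same recipe:

1. fit the *base* mixed model (fixed intercept + time; the post-diagnosis
   base model additionally carries the time-varying regimen and
   HbA1c-change indicator offsets), with a single studentised-residual
   outlier pass (|t| > 3, remove, refit once);
2. derive each individual's annual BMI-change rate as the fixed time slope
   plus their BLUP slope deviation, and its 7-level weight-change category;
3. expand to covariate models — one univariable covariate-at-a-time model
   with a covariate-by-time interaction, then one multivariable model
   containing every covariate with a significant (p < alpha) interaction in
   its univariable model plus the always-retained confounders.

The outlier pass runs once on the base model; covariate models reuse the
cleaned observation set, so every model of an analysis uses the same rows.
Coefficients are differences in annual slope (kg/m2/year) versus the
reference level; exposure offsets are level differences in kg/m2.
Peri-diagnosis observations are never modelled, only summarised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import lmm
from .cohort import (
    AGE_BAND_LEVELS,
    BMI_BAND_POST_LEVELS,
    BMI_BAND_PRE_LEVELS,
    CALENDAR_BAND_POST_LEVELS,
    CALENDAR_BAND_PRE_LEVELS,
    DEPRIVATION_LEVELS,
    HBA1C_BAND_LEVELS,
    PRE_WINDOW,
    RATE_CATEGORIES,
    SEX_LEVELS,
    CohortResult,
    build_cohort,
    categorize_rate,
    relative_years,
)
from .exposures import HBA1C_CATEGORIES, attach_exposures

__all__ = [
    "AnalysisConfig", "PreResult", "PostResult", "PipelineResult",
    "run_pre_analysis", "run_post_analysis", "summarize_categories",
    "run_pipeline", "write_outputs",
]


@dataclass(frozen=True)
class AnalysisConfig:
    alpha: float = 0.05
    always_retain: tuple[str, ...] = ("age_band", "sex")
    min_regimen_obs: int = 30
    outlier_threshold: float = 3.0
    covariance: str = "sp_pow"
    reml: bool = True
    grace_days: float = 0.0
    pairing_window_days: float = 90.0
    diagnosis_year_range: tuple[int, int] = (2003, 2014)


# covariate name -> (cohort column, level order, reference level)
PRE_COVARIATES: dict[str, tuple[str, list[str], str]] = {
    "sex": ("sex", SEX_LEVELS, "M"),
    "age_band": ("age_band_pre", AGE_BAND_LEVELS, ">=70"),
    "bmi_band": ("bmi_band_pre", BMI_BAND_PRE_LEVELS, "<30"),
    "deprivation": ("deprivation", DEPRIVATION_LEVELS, "5"),
    "calendar_band": ("calendar_band_pre", CALENDAR_BAND_PRE_LEVELS, ">=2010"),
}

POST_COVARIATES: dict[str, tuple[str, list[str], str]] = {
    "sex": ("sex", SEX_LEVELS, "M"),
    "age_band": ("age_band_post", AGE_BAND_LEVELS, ">=70"),
    "bmi_band": ("bmi_band_post", BMI_BAND_POST_LEVELS, "25-<30"),
    "deprivation": ("deprivation", DEPRIVATION_LEVELS, "5"),
    "calendar_band": ("calendar_band_post", CALENDAR_BAND_POST_LEVELS, "2013-2014"),
    "hba1c_band": ("hba1c_band", HBA1C_BAND_LEVELS, "<43"),
    "pre_category": ("pre_category", RATE_CATEGORIES, "rapid gain"),
    "peri_category": ("peri_category", RATE_CATEGORIES, "rapid loss"),
}

COEF_TABLE_COLUMNS = [
    "covariate", "level", "reference", "n",
    "unadj_coef", "unadj_lo", "unadj_hi", "unadj_p",
    "adj_coef", "adj_lo", "adj_hi",
]


@dataclass
class PreResult:
    estimates: pd.DataFrame       # id, period, rate, category
    coef_table: pd.DataFrame
    base_fit: lmm.LmmFit
    cleaned: pd.DataFrame         # post-outlier-pass observation rows
    selected_covariates: list[str]


@dataclass
class PostResult:
    estimates: pd.DataFrame
    coef_table: pd.DataFrame
    exposure_table: pd.DataFrame
    base_fit: lmm.LmmFit
    cleaned: pd.DataFrame
    selected_covariates: list[str]
    pooled_regimens: list[str]


@dataclass
class PipelineResult:
    cohort_result: CohortResult
    design_post: pd.DataFrame
    pre: PreResult
    post: PostResult
    summary: pd.DataFrame


def observations_with_time(bundle, ids, window) -> pd.DataFrame:
    """BMI observations for ``ids`` with diagnosis-relative time in ``window``."""
    demo = bundle.demographics.set_index("id")
    rows = []
    lo, hi = window
    for pid, obs in bundle.bmi_obs.groupby("id", sort=False):
        if pid not in ids:
            continue
        t = relative_years(obs["date"], demo.loc[pid, "diagnosis_date"])
        v = obs["bmi"].to_numpy(dtype=float)
        inside = (t >= lo) & (t <= hi)
        for ti, vi in zip(t[inside], v[inside]):
            rows.append({"id": pid, "time": float(ti), "bmi": float(vi)})
    return pd.DataFrame(rows, columns=["id", "time", "bmi"])


def _add_dummies(df: pd.DataFrame, values: pd.Series, name: str,
                 levels, ref: str, with_time: bool):
    """Indicator (and optionally indicator-by-time) columns for non-reference levels."""
    cols: list[str] = []
    inter: list[str] = []
    tvec = df["time"].to_numpy(dtype=float)
    for lvl in levels:
        if lvl == ref:
            continue
        ind = (values == lvl).to_numpy(dtype=float)
        if ind.sum() == 0:
            continue
        col = f"{name}[{lvl}]"
        df[col] = ind
        cols.append(col)
        if with_time:
            icol = f"{col}:time"
            df[icol] = ind * tvec
            cols.append(icol)
            inter.append(icol)
    return cols, inter


def _coef_row(fitres: Optional[lmm.LmmFit], col: str):
    if fitres is None or col not in fitres.beta.index:
        return (np.nan, np.nan, np.nan, np.nan)
    return (fitres.beta[col], fitres.ci_low[col], fitres.ci_high[col],
            fitres.pvalues[col])


def _covariate_models(cleaned: pd.DataFrame, covariates: dict, config: AnalysisConfig,
                      base_cols: list[str], fit_kwargs: dict):
    """Univariable then multivariable covariate-by-time models on the cleaned rows."""
    uni_fits: dict[str, lmm.LmmFit] = {}
    for cov, (column, levels, ref) in covariates.items():
        df = cleaned.copy()
        cols, inter = _add_dummies(df, df[column], cov, levels, ref, with_time=True)
        if not inter:
            continue
        data = lmm.from_dataframe(df, fixed_cols=base_cols + cols,
                                  interaction_cols=inter)
        try:
            uni_fits[cov] = lmm.fit(data, **fit_kwargs)
        except lmm.ConvergenceError as exc:
            raise lmm.ConvergenceError(
                f"univariable model for covariate {cov!r} did not converge: {exc}",
                best=exc.best)

    selected = []
    for cov, f in uni_fits.items():
        ps = [f.pvalues[c] for c in f.data.interaction_cols if c.startswith(f"{cov}[")]
        if ps and min(ps) < config.alpha:
            selected.append(cov)
    for cov in config.always_retain:
        if cov in uni_fits and cov not in selected:
            selected.append(cov)
    selected = [c for c in covariates if c in selected]  # canonical order

    multi_fit = None
    if selected:
        df = cleaned.copy()
        all_cols: list[str] = []
        all_inter: list[str] = []
        for cov in selected:
            column, levels, ref = covariates[cov]
            cols, inter = _add_dummies(df, df[column], cov, levels, ref, with_time=True)
            all_cols += cols
            all_inter += inter
        data = lmm.from_dataframe(df, fixed_cols=base_cols + all_cols,
                                  interaction_cols=all_inter)
        try:
            multi_fit = lmm.fit(data, **fit_kwargs)
        except lmm.ConvergenceError as exc:
            raise lmm.ConvergenceError(
                f"multivariable model did not converge: {exc}", best=exc.best)

    rows = []
    level_counts = {
        cov: cleaned.drop_duplicates("id")[column].value_counts()
        for cov, (column, _, _) in covariates.items()
    }
    for cov, (column, levels, ref) in covariates.items():
        if cov not in uni_fits:
            continue
        for lvl in levels:
            n_lvl = int(level_counts[cov].get(lvl, 0))
            if n_lvl == 0:
                continue
            if lvl == ref:
                rows.append({
                    "covariate": cov, "level": lvl, "reference": True, "n": n_lvl,
                    "unadj_coef": np.nan, "unadj_lo": np.nan, "unadj_hi": np.nan,
                    "unadj_p": np.nan, "adj_coef": np.nan, "adj_lo": np.nan,
                    "adj_hi": np.nan,
                })
                continue
            icol = f"{cov}[{lvl}]:time"
            u = _coef_row(uni_fits[cov], icol)
            a = _coef_row(multi_fit if cov in selected else None, icol)
            rows.append({
                "covariate": cov, "level": lvl, "reference": False, "n": n_lvl,
                "unadj_coef": u[0], "unadj_lo": u[1], "unadj_hi": u[2], "unadj_p": u[3],
                "adj_coef": a[0], "adj_lo": a[1], "adj_hi": a[2],
            })
    table = pd.DataFrame(rows, columns=COEF_TABLE_COLUMNS)
    return table, selected, uni_fits, multi_fit


def _estimates_from_fit(base_fit: lmm.LmmFit, period: str) -> pd.DataFrame:
    traj = lmm.trajectories(base_fit)
    traj["period"] = period
    traj["category"] = [categorize_rate(r) for r in traj["rate"]]
    return traj[["id", "period", "rate", "category"]]


def run_pre_analysis(bundle, cohort: pd.DataFrame,
                     config: AnalysisConfig = AnalysisConfig()) -> PreResult:
    """Pre-diagnosis trajectory model on all BMI observations in [-3, -0.5] years."""
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    obs = observations_with_time(bundle, set(cohort["id"]), PRE_WINDOW)
    fit_kwargs = dict(covariance=config.covariance, reml=config.reml)
    data = lmm.from_dataframe(obs)
    base_fit = lmm.fit_with_outlier_pass(data, threshold=config.outlier_threshold,
                                         **fit_kwargs)
    estimates = _estimates_from_fit(base_fit, "pre")

    cleaned = pd.DataFrame({
        "id": base_fit.data.ids, "time": base_fit.data.time, "bmi": base_fit.data.y})
    cleaned = cleaned.merge(
        cohort[["id", "sex", "age_band_pre", "bmi_band_pre", "deprivation",
                "calendar_band_pre"]], on="id", how="left")
    table, selected, _, _ = _covariate_models(
        cleaned, PRE_COVARIATES, config, base_cols=[], fit_kwargs=fit_kwargs)
    return PreResult(estimates=estimates, coef_table=table, base_fit=base_fit,
                     cleaned=cleaned, selected_covariates=selected)


def pool_rare_regimens(design_post: pd.DataFrame, min_obs: int):
    """Pool regimen levels with fewer than ``min_obs`` observations into 'other'."""
    counts = design_post["regimen"].value_counts()
    pooled = [lbl for lbl, c in counts.items() if lbl != "none" and c < min_obs]
    out = design_post.copy()
    out["regimen"] = out["regimen"].where(~out["regimen"].isin(pooled), "other")
    return out, pooled


def _post_base_design(design_post: pd.DataFrame):
    """Design rows + exposure indicator columns for the adjusted post base model."""
    df = design_post.copy()
    regimen_levels = ["none"] + sorted(set(df["regimen"]) - {"none"})
    reg_cols, _ = _add_dummies(df, df["regimen"], "regimen", regimen_levels,
                               "none", with_time=False)
    h_cols, _ = _add_dummies(df, df["hba1c_category"], "hba1c_change",
                             HBA1C_CATEGORIES, "no_change", with_time=False)
    return df, reg_cols + h_cols


def fit_post_base(design_post: pd.DataFrame, config: AnalysisConfig = AnalysisConfig()):
    """Exposure-adjusted post-diagnosis base model with the outlier pass.

    Returns (fit, cleaned rows, exposure column names, pooled labels).
    """
    pooled_df, pooled = pool_rare_regimens(design_post, config.min_regimen_obs)
    df, exp_cols = _post_base_design(pooled_df)
    data = lmm.from_dataframe(df, fixed_cols=exp_cols)
    base_fit = lmm.fit_with_outlier_pass(
        data, threshold=config.outlier_threshold,
        covariance=config.covariance, reml=config.reml)
    cleaned = pooled_df.loc[base_fit.kept_mask].reset_index(drop=True)
    cleaned = cleaned[cleaned["id"].isin(set(base_fit.blups["id"]))].reset_index(drop=True)
    return base_fit, cleaned, exp_cols, pooled


def run_post_analysis(bundle, cohort: pd.DataFrame, design_post: pd.DataFrame,
                      config: AnalysisConfig = AnalysisConfig()) -> PostResult:
    """Post-diagnosis trajectory model, time-dependently exposure-adjusted.

    ``cohort`` should carry a ``pre_category`` column (the categorised
    pre-diagnosis trajectory); individuals without one are treated as the
    reference level in that covariate model.
    """
    if len(design_post) == 0:
        raise ValueError("post-diagnosis design is empty")
    base_fit, cleaned, exp_cols, pooled = fit_post_base(design_post, config)
    estimates = _estimates_from_fit(base_fit, "post")

    # exposure effect table (offsets in kg/m2 vs reference)
    exp_rows = []
    obs_counts_reg = cleaned["regimen"].value_counts()
    obs_counts_h = cleaned["hba1c_category"].value_counts()
    for col in exp_cols:
        kind, lvl = col.split("[", 1)
        lvl = lvl.rstrip("]")
        n_obs = int((obs_counts_reg if kind == "regimen" else obs_counts_h).get(lvl, 0))
        c, lo, hi, p = _coef_row(base_fit, col)
        exp_rows.append({"kind": kind, "level": lvl, "n_obs": n_obs,
                         "coef": c, "ci_low": lo, "ci_high": hi, "p": p})
    exposure_table = pd.DataFrame(
        exp_rows, columns=["kind", "level", "n_obs", "coef", "ci_low", "ci_high", "p"])

    cov_cols = ["id", "sex", "age_band_post", "bmi_band_post", "deprivation",
                "calendar_band_post", "hba1c_band", "peri_category"]
    if "pre_category" in cohort.columns:
        cov_cols.append("pre_category")
    merged = cleaned.merge(cohort[cov_cols], on="id", how="left")
    if "pre_category" not in merged.columns:
        merged["pre_category"] = np.nan

    # rebuild exposure dummies on the merged frame so covariate models stay adjusted
    df, exp_cols2 = _post_base_design(merged)
    fit_kwargs = dict(covariance=config.covariance, reml=config.reml)
    table, selected, _, _ = _covariate_models(
        df, POST_COVARIATES, config, base_cols=exp_cols2, fit_kwargs=fit_kwargs)
    return PostResult(estimates=estimates, coef_table=table,
                      exposure_table=exposure_table, base_fit=base_fit,
                      cleaned=cleaned, selected_covariates=selected,
                      pooled_regimens=pooled)


def summarize_categories(estimates: pd.DataFrame) -> pd.DataFrame:
    """Category frequencies plus direction shares and the median (IQR) rate.

    Long format: one row per (period, item) with a single ``value`` column —
    ``count:<category>`` and ``pct:<category>`` rows for the 7 categories,
    then n, pct_gaining, pct_losing, median_rate, iqr_low, iqr_high.
    """
    if len(estimates) == 0:
        raise ValueError("no trajectory estimates to summarise")
    rows = []
    for period, grp in estimates.groupby("period", sort=False):
        rates = grp["rate"].to_numpy(dtype=float)
        n = len(grp)
        counts = grp["category"].value_counts()
        for cat in RATE_CATEGORIES:
            c = int(counts.get(cat, 0))
            rows.append({"period": period, "item": f"count:{cat}", "value": c})
            rows.append({"period": period, "item": f"pct:{cat}",
                         "value": 100.0 * c / n})
        q1, med, q3 = np.percentile(rates, [25, 50, 75])
        rows += [
            {"period": period, "item": "n", "value": n},
            {"period": period, "item": "pct_gaining", "value": 100.0 * (rates > 0).mean()},
            {"period": period, "item": "pct_losing", "value": 100.0 * (rates < 0).mean()},
            {"period": period, "item": "median_rate", "value": med},
            {"period": period, "item": "iqr_low", "value": q1},
            {"period": period, "item": "iqr_high", "value": q3},
        ]
    return pd.DataFrame(rows, columns=["period", "item", "value"])


def run_pipeline(bundle, config: AnalysisConfig = AnalysisConfig()) -> PipelineResult:
    """Cohort -> pre analysis -> exposure coding -> post analysis -> summaries."""
    cohort_result = build_cohort(bundle, config.diagnosis_year_range)
    cohort = cohort_result.cohort
    if len(cohort) == 0:
        raise ValueError("no eligible individuals after filtering; see exclusion log")
    pre = run_pre_analysis(bundle, cohort, config)
    pre_cat = pre.estimates.rename(columns={"category": "pre_category"})
    cohort = cohort.merge(pre_cat[["id", "pre_category"]], on="id", how="left")
    design_post = attach_exposures(
        bundle, cohort, grace_days=config.grace_days,
        pairing_window_days=config.pairing_window_days)
    post = run_post_analysis(bundle, cohort, design_post, config)

    peri = pd.DataFrame({
        "id": cohort["id"], "period": "peri",
        "rate": cohort["peri_change"], "category": cohort["peri_category"]})
    summary = summarize_categories(
        pd.concat([pre.estimates, peri, post.estimates], ignore_index=True))
    return PipelineResult(cohort_result=cohort_result, design_post=design_post,
                          pre=pre, post=post, summary=summary)


OUTPUT_FLOAT_FORMAT = "%.8g"


def write_outputs(result: PipelineResult, outdir) -> dict[str, str]:
    """Write the standard CSV outputs; returns {filename: path}."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trajectories = pd.concat(
        [result.pre.estimates, result.post.estimates], ignore_index=True)
    tables = {
        "cohort.csv": result.cohort_result.cohort,
        "exclusions.csv": result.cohort_result.exclusions,
        "design_post.csv": result.design_post,
        "table1.csv": result.pre.coef_table,
        "table2.csv": result.post.coef_table,
        "exposure_effects.csv": result.post.exposure_table,
        "trajectories.csv": trajectories,
        "category_summary.csv": result.summary,
    }
    written = {}
    for fname, df in tables.items():
        path = outdir / fname
        df.to_csv(path, index=False, float_format=OUTPUT_FLOAT_FORMAT)
        written[fname] = str(path)
    return written
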