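"""Generator invariants: determinism, schema, the zero-noise limit and the
statistical structure (slopes, serial correlation) the analysis assumes."""

import numpy as np
import pandas as pd
import pytest

from bmitraject import EmrBundle, SchemaError, SimConfig, generate_bundle
from bmitraject.synthetic_emr import latent_bmi, read_bundle, write_bundle


def _assert_bundles_equal(a: EmrBundle, b: EmrBundle):
    for name in ("demographics", "bmi_obs", "hba1c_obs", "rx_episodes"):
        pd.testing.assert_frame_equal(
            getattr(a, name).reset_index(drop=True),
            getattr(b, name).reset_index(drop=True),
            check_dtype=False,
        )


def test_construction_and_seed_determinism():
    cfg = SimConfig(n_individuals=100, seed=1)
    b1 = generate_bundle(cfg)
    assert len(b1.demographics) == 100
    years = pd.to_datetime(b1.demographics["diagnosis_date"]).dt.year
    lo, hi = cfg.diagnosis_year_range
    assert years.between(lo, hi).all()
    ages = (pd.to_datetime(b1.demographics["diagnosis_date"])
            - pd.to_datetime(b1.demographics["birth_date"])).dt.days / 365.25
    assert (ages >= 35).all()
    b2 = generate_bundle(SimConfig(n_individuals=100, seed=1))
    _assert_bundles_equal(b1, b2)
    pd.testing.assert_frame_equal(b1.truth, b2.truth)


@pytest.mark.parametrize("bad", [
    {"n_individuals": 0},
    {"missing_prob": 1.5},
    {"resid_rho": -0.2},
    {"resid_sd": 0.0},
    {"deprivation_probs": (0.5, 0.5, 0.2, 0.0, 0.0)},
    {"covariate_slope_effects": {"pre:unknown:<50": 0.1}},
])
def test_invalid_configs_rejected(bad):
    with pytest.raises(ValueError):
        SimConfig(**bad).validate()


def test_zero_noise_limit_lies_on_latent_line():
    cfg = SimConfig(
        n_individuals=40, seed=3, resid_sd=1e-9, missing_prob=0.0,
        drug_effects={}, hba1c_effects={}, covariate_slope_effects={})
    b = generate_bundle(cfg)
    truth = b.truth.set_index("id")
    for pid, grp in b.truth_obs.groupby("id"):
        row = truth.loc[pid]
        t = grp["time"].to_numpy()
        # independent piecewise recomputation
        expected = np.where(
            t >= 1.0, row.latent_bmi_1y + row.slope_post * (t - 1.0),
            np.where(t >= -0.5,
                     row.latent_bmi_1y - row.slope_peri * (1.0 - t),
                     row.latent_bmi_1y - 1.5 * row.slope_peri + row.slope_pre * (t + 0.5)))
        observed = b.bmi_obs.loc[b.bmi_obs["id"] == pid, "bmi"].to_numpy()
        np.testing.assert_allclose(observed, expected, atol=1e-4)
        np.testing.assert_allclose(grp["latent_bmi"].to_numpy(), expected, atol=1e-9)


def test_population_mean_curve_piecewise_with_fixed_slopes():
    cfg = SimConfig(
        n_individuals=300, seed=11, resid_sd=0.3,
        slope_pre=(0.4, 0.0), slope_peri=(-0.6, 0.0), slope_post=(-0.2, 0.0),
        drug_effects={}, hba1c_effects={}, covariate_slope_effects={})
    b = generate_bundle(cfg)
    t = b.truth_obs["time"].to_numpy()
    latent = b.truth_obs["latent_bmi"].to_numpy()
    base = b.truth.set_index("id").loc[b.truth_obs["id"], "latent_bmi_1y"].to_numpy()
    centred = latent - base
    np.testing.assert_allclose(
        centred, latent_bmi(t, 0.0, 0.4, -0.6, -0.2), atol=1e-9)


def test_post_slope_recovery_against_per_subject_regression():
    """Mean of per-individual post-window OLS slopes ~ configured mean slope."""
    cfg = SimConfig(n_individuals=2000, seed=7,
                    drug_effects={}, hba1c_effects={}, covariate_slope_effects={})
    b = generate_bundle(cfg)
    slopes = []
    for _, grp in b.truth_obs.groupby("id"):
        post = grp[grp["time"] >= 1.0]
        t = post["time"].to_numpy()
        if len(post) < 2 or np.ptp(t) < 0.5:
            continue
        y = (post["latent_bmi"] + post["error"]).to_numpy()
        slopes.append(np.polyfit(t, y, 1)[0])
    slopes = np.asarray(slopes)
    mc_se = slopes.std(ddof=1) / np.sqrt(len(slopes))
    assert abs(slopes.mean() - cfg.slope_post[0]) < 2 * mc_se


def test_error_autocorrelation_decays_as_rho_power():
    cfg = SimConfig(n_individuals=800, seed=5, visit_rate=3.0)
    b = generate_bundle(cfg)
    pairs = {0.5: [], 1.0: [], 2.0: []}
    for _, grp in b.truth_obs.groupby("id"):
        t = grp["time"].to_numpy()
        e = grp["error"].to_numpy()
        gaps = np.abs(t[:, None] - t[None, :])
        for tau in pairs:
            jj, kk = np.nonzero(np.triu(np.abs(gaps - tau) < 0.1, k=1))
            pairs[tau].extend(zip(e[jj], e[kk]))
    for tau, pp in pairs.items():
        arr = np.asarray(pp)
        r = np.corrcoef(arr[:, 0], arr[:, 1])[0, 1]
        assert abs(r - cfg.resid_rho ** tau) < 0.06, (tau, r)


def test_csv_round_trip_lossless(tmp_path):
    cfg = SimConfig(n_individuals=60, seed=2, deprivation_missing_prob=0.1)
    b = generate_bundle(cfg)
    assert b.demographics["deprivation_quintile"].isna().any()
    write_bundle(b, tmp_path)
    b2 = read_bundle(tmp_path)
    _assert_bundles_equal(b, b2)
    # missingness markers survive the round trip
    assert (b.demographics["deprivation_quintile"].isna()
            == b2.demographics["deprivation_quintile"].isna()).all()


def test_schema_error_on_inverted_episode(tmp_path):
    b = generate_bundle(SimConfig(n_individuals=30, seed=4))
    rx = b.rx_episodes.copy()
    assert len(rx) > 0
    rx.loc[rx.index[0], ["start_date", "end_date"]] = (
        rx.loc[rx.index[0], "end_date"], rx.loc[rx.index[0], "start_date"])
    bad = EmrBundle(demographics=b.demographics, bmi_obs=b.bmi_obs,
                    hba1c_obs=b.hba1c_obs, rx_episodes=rx)
    with pytest.raises(SchemaError, match="rx_episodes"):
        bad.validate()
    write_bundle(bad, tmp_path)
    with pytest.raises(SchemaError, match="end_date"):
        read_bundle(tmp_path)


def test_unknown_id_rejected():
    b = generate_bundle(SimConfig(n_individuals=10, seed=9))
    bmi = pd.concat([b.bmi_obs, pd.DataFrame([
        {"id": "GHOST", "date": pd.Timestamp("2010-01-01"), "bmi": 30.0}])],
        ignore_index=True)
    bad = EmrBundle(demographics=b.demographics, bmi_obs=bmi,
                    hba1c_obs=b.hba1c_obs, rx_episodes=b.rx_episodes)
    with pytest.raises(SchemaError, match="unknown ids"):
        bad.validate()
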