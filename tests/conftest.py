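import numpy as np
import pandas as pd
import pytest

from bmitraject import SimConfig, generate_bundle
from bmitraject.recovery import simulate_lmm_design


@pytest.fixture(scope="session")
def small_bundle():
    """A default-condition synthetic bundle, small enough for fast tests."""
    return generate_bundle(SimConfig(n_individuals=150, seed=7))


@pytest.fixture(scope="session")
def small_design():
    """A direct draw from the mixed model (300 individuals, rho=0.5)."""
    return simulate_lmm_design(300, seed=42, rho=0.5, sigma=1.0, slope_sd=0.3)


@pytest.fixture()
def handmade_bundle_factory():
    """Bundles built row-by-row: every individual gets the four anchors and an
    HbA1c at 1.4 years unless the per-individual overrides say otherwise."""

    def make(n, bmi_1_values=None, skip_pre_anchor=()):
        from bmitraject import EmrBundle

        demo, bmi, hba1c = [], [], []
        for i in range(n):
            pid = f"H{i:03d}"
            dx = pd.Timestamp("2010-06-01")
            demo.append({
                "id": pid, "sex": "F" if i % 2 else "M",
                "birth_date": dx - pd.Timedelta(days=int(60 * 365.25)),
                "diagnosis_date": dx,
                "deprivation_quintile": float(1 + i % 5),
            })
            b1 = 30.0 if bmi_1_values is None else bmi_1_values[i]
            points = [(-2.5, 31.0), (-1.0, 30.5), (1.5, b1), (4.5, 29.0)]
            if i in skip_pre_anchor:
                points = points[2:]
            for t, v in points:
                bmi.append({
                    "id": pid,
                    "date": dx + pd.Timedelta(days=round(t * 365.25)),
                    "bmi": v,
                })
            hba1c.append({
                "id": pid,
                "date": dx + pd.Timedelta(days=round(1.4 * 365.25)),
                "hba1c": 50.0,
            })
        return EmrBundle(
            demographics=pd.DataFrame(demo, columns=[
                "id", "sex", "birth_date", "diagnosis_date", "deprivation_quintile"]),
            bmi_obs=pd.DataFrame(bmi, columns=["id", "date", "bmi"]),
            hba1c_obs=pd.DataFrame(hba1c, columns=["id", "date", "hba1c"]),
            rx_episodes=pd.DataFrame(columns=["id", "drug_class", "start_date", "end_date"]),
        )

    return make
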