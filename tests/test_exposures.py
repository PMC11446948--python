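"""Regimen labelling, HbA1c change categories and exposure attachment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bmitraject import EmrBundle, hba1c_category, regimen_at, regimen_label
from bmitraject.exposures import (
    HBA1C_CATEGORIES,
    NON_INSULIN_CLASSES,
    attach_exposures,
    pair_hba1c,
)


class TestRegimenLabel:
    @pytest.mark.parametrize("classes,expected", [
        ((), "none"),
        (("metformin",), "mono:metformin"),
        (("metformin", "insulin"), "insulin_any"),
        (("sglt2i", "metformin"), "dual:metformin+sglt2i"),
        (("sulfonylurea", "metformin", "dpp4i"), "triple:dpp4i+metformin+sulfonylurea"),
        (("metformin", "sglt2i", "dpp4i", "glp1ra"), "quad_plus"),
    ])
    def test_labelling(self, classes, expected):
        assert regimen_label(classes) == expected

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            regimen_label({"homeopathy"})

    @given(st.sets(st.sampled_from(NON_INSULIN_CLASSES), max_size=4),
           st.randoms(use_true_random=False))
    @settings(max_examples=100, deadline=None)
    def test_order_invariance_and_insulin_dominance(self, classes, rnd):
        ordered = list(classes)
        shuffled = list(ordered)
        rnd.shuffle(shuffled)
        assert regimen_label(ordered) == regimen_label(shuffled)
        assert regimen_label(set(ordered) | {"insulin"}) == "insulin_any"


class TestRegimenAt:
    EPISODES = [("metformin", 0.5, 2.0), ("metformin", 3.0, 5.0), ("sglt2i", 4.0, 5.0)]

    @pytest.mark.parametrize("t,expected", [
        (0.0, "none"),
        (1.0, "mono:metformin"),
        (2.5, "none"),              # uncovered gap between episodes
        (3.5, "mono:metformin"),
        (4.5, "dual:metformin+sglt2i"),
    ])
    def test_coverage(self, t, expected):
        assert regimen_at(self.EPISODES, t) == expected

    def test_grace_extends_episode_end(self):
        assert regimen_at(self.EPISODES, 2.1, grace_years=0.2) == "mono:metformin"


class TestHba1cCategory:
    @pytest.mark.parametrize("baseline,current,expected", [
        (50.0, 45.0, "dec_ge10"),    # exactly -10%
        (50.0, 50.0, "no_change"),
        (50.0, 56.0, "inc_ge10"),    # +12%
        (50.0, 55.0, "inc_ge10"),    # exactly +10%
        (50.0, 54.9, "inc_0_10"),
        (50.0, 45.1, "dec_0_10"),
        (53.3, 48.0, "dec_0_10"),    # -9.94%, just inside the 0-10% band
    ])
    def test_percentage_boundaries(self, baseline, current, expected):
        assert hba1c_category(baseline, current) == expected

    def test_non_positive_baseline_rejected(self):
        with pytest.raises(ValueError):
            hba1c_category(0.0, 45.0)

    @given(st.floats(20, 150))
    @settings(max_examples=200, deadline=None)
    def test_partition_single_valued(self, current):
        assert hba1c_category(50.0, current) in HBA1C_CATEGORIES


class TestPairing:
    def test_most_recent_at_or_before_preferred(self):
        assert pair_hba1c([1.1, 1.8, 2.5], [50, 48, 47], 2.0, 90 / 365.25) == 48

    def test_fallback_to_nearest_within_window(self):
        assert pair_hba1c([2.1], [47], 2.0, 90 / 365.25) == 47

    def test_none_when_out_of_window(self):
        assert pair_hba1c([3.0], [47], 2.0, 90 / 365.25) is None


def _one_person_bundle():
    dx = pd.Timestamp("2010-01-01")
    day = lambda t: dx + pd.Timedelta(days=round(t * 365.25))
    demo = pd.DataFrame([{"id": "A", "sex": "F", "birth_date": day(-50.0),
                          "diagnosis_date": dx, "deprivation_quintile": 3.0}])
    bmi = pd.DataFrame([{"id": "A", "date": day(t), "bmi": v} for t, v in
                        [(1.2, 33.0), (1.8, 32.5), (2.5, 32.0), (3.5, 32.2), (4.8, 31.9)]])
    hba1c = pd.DataFrame([{"id": "A", "date": day(t), "hba1c": v} for t, v in
                          [(1.1, 53.3), (1.9, 48.0), (3.4, 60.0)]])
    rx = pd.DataFrame([
        {"id": "A", "drug_class": "metformin", "start_date": day(1.5), "end_date": day(2.2)},
        {"id": "A", "drug_class": "metformin", "start_date": day(3.0), "end_date": day(5.0)},
        {"id": "A", "drug_class": "sglt2i", "start_date": day(4.0), "end_date": day(5.0)},
    ])
    return EmrBundle(demographics=demo, bmi_obs=bmi, hba1c_obs=hba1c, rx_episodes=rx)


class TestAttachExposures:
    def test_hand_listed_regimens_and_categories(self):
        bundle = _one_person_bundle()
        cohort = pd.DataFrame([{"id": "A"}])
        design = attach_exposures(bundle, cohort)
        assert len(design) == 5
        assert list(design["regimen"]) == [
            "none", "mono:metformin", "none", "mono:metformin",
            "dual:metformin+sglt2i"]
        # baseline = first HbA1c after 1y = 53.3; pairing is last at-or-before
        assert list(design["hba1c_category"]) == [
            "no_change",   # paired to baseline itself
            "no_change",   # bmi at 1.8 pairs to 1.1 measurement (baseline)
            "dec_0_10",    # pairs to 48.0 at 1.9 (-9.94%)
            "inc_ge10",    # pairs to 60.0 at 3.4 (+12.6%)
            "inc_ge10",
        ]
        assert not design["hba1c_unpaired"].any()

    def test_order_of_episode_rows_is_irrelevant(self):
        bundle = _one_person_bundle()
        shuffled = bundle.rx_episodes.iloc[[2, 0, 1]].reset_index(drop=True)
        bundle2 = EmrBundle(demographics=bundle.demographics, bmi_obs=bundle.bmi_obs,
                            hba1c_obs=bundle.hba1c_obs, rx_episodes=shuffled)
        cohort = pd.DataFrame([{"id": "A"}])
        d1 = attach_exposures(bundle, cohort)
        d2 = attach_exposures(bundle2, cohort)
        assert list(d1["regimen"]) == list(d2["regimen"])

    def test_window_restriction(self):
        bundle = _one_person_bundle()
        design = attach_exposures(bundle, pd.DataFrame([{"id": "A"}]))
        assert design["time"].between(1.0, 5.0).all()
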