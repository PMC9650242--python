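"""SOFA component scoring: worked examples, band-scan oracle, invariants."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import icusepsis as ic
from icusepsis.sofa import COMPONENTS, score_component, window_aggregates, worst_in_window

# ---------------------------------------------------------------------------
# independent oracle: explicit interval membership per component and score


def _respiration_band(score, ratio, ventilated, thr):
    c1, c2, c3, c4 = thr.pf_cutoffs
    raw = {
        0: ratio >= c1,
        1: c2 <= ratio < c1,
        2: c3 <= ratio < c2,
        3: c4 <= ratio < c3,
        4: ratio < c4,
    }
    raw_score = next(s for s, ok in raw.items() if ok)
    if raw_score >= thr.ventilation_required_from and not ventilated:
        raw_score = thr.ventilation_required_from - 1
    return raw_score == score


def _interval_low_bad(score, value, cuts, strict_below=True):
    c1, c2, c3, c4 = cuts
    bands = {0: value >= c1, 1: c2 <= value < c1, 2: c3 <= value < c2,
             3: c4 <= value < c3, 4: value < c4}
    return bands[score]


def _interval_high_bad(score, value, bounds):
    b1, b2, b3, b4 = bounds
    bands = {0: value < b1, 1: b1 <= value < b2, 2: b2 <= value < b3,
             3: b3 <= value < b4, 4: value >= b4}
    return bands[score]


def _cardio_oracle(agg, thr):
    vaso = agg.get("vasopressors") or {}
    mean_ap = agg.get("map")
    if not vaso and mean_ap is None:
        return None
    if vaso:
        dop = vaso.get("dopamine")
        nor_doses = [d for k, d in vaso.items() if k in ("norepinephrine", "epinephrine")]
        nor = max(nor_doses) if nor_doses else None
        if (dop is not None and dop > thr.dopamine_high) or (
            nor is not None and nor > thr.norepinephrine_cutoff
        ):
            return 4
        if (dop is not None and dop > thr.dopamine_low) or nor is not None:
            return 3
        return 2
    return 1 if mean_ap < thr.hypotension_map else 0


def _renal_oracle(agg, thr):
    creatinine, urine = agg.get("creatinine"), agg.get("urine_output")
    if creatinine is None and urine is None:
        return None
    candidates = [0]
    if creatinine is not None:
        candidates.append(
            next(s for s in range(5) if _interval_high_bad(s, creatinine, thr.creatinine_bounds))
        )
    if urine is not None:
        if urine < thr.urine_very_low:
            candidates.append(4)
        elif urine < thr.urine_low:
            candidates.append(3)
    return max(candidates)


def oracle_score(component, agg, thr):
    """Exhaustive band scan: the unique score whose band contains the value."""
    if component == "respiration":
        if agg.get("pao2") is None or agg.get("fio2") is None:
            return None
        fio2 = agg["fio2"]
        ratio = agg["pao2"] / (fio2 / 100.0 if fio2 > 1 else fio2)
        matches = [
            s for s in range(5)
            if _respiration_band(s, ratio, bool(agg.get("ventilated")), thr)
        ]
        assert len(matches) == 1
        return matches[0]
    if component == "coagulation":
        if agg.get("platelets") is None:
            return None
        matches = [s for s in range(5)
                   if _interval_low_bad(s, agg["platelets"], thr.platelet_cutoffs)]
        assert len(matches) == 1
        return matches[0]
    if component == "liver":
        if agg.get("bilirubin") is None:
            return None
        matches = [s for s in range(5)
                   if _interval_high_bad(s, agg["bilirubin"], thr.bilirubin_bounds)]
        assert len(matches) == 1
        return matches[0]
    if component == "cardiovascular":
        return _cardio_oracle(agg, thr)
    if component == "cns":
        if agg.get("gcs") is None:
            return None
        matches = [s for s in range(5)
                   if _interval_low_bad(s, agg["gcs"], thr.gcs_cutoffs)]
        assert len(matches) == 1
        return matches[0]
    if component == "renal":
        return _renal_oracle(agg, thr)
    raise AssertionError(component)


def random_aggregates(rng):
    agg = {c: None for c in ("pao2", "fio2", "platelets", "bilirubin", "map",
                             "gcs", "creatinine", "urine_output")}
    if rng.random() < 0.8:
        agg["pao2"] = float(rng.uniform(2, 60))
    if rng.random() < 0.8:
        agg["fio2"] = float(rng.uniform(0.21, 1.0)) if rng.random() < 0.5 else float(
            rng.uniform(21, 100)
        )
    if rng.random() < 0.8:
        agg["platelets"] = float(rng.uniform(1, 400))
    if rng.random() < 0.6:
        agg["bilirubin"] = float(rng.uniform(2, 400))
    if rng.random() < 0.8:
        agg["map"] = float(rng.uniform(30, 120))
    if rng.random() < 0.7:
        agg["gcs"] = float(rng.integers(3, 16))
    if rng.random() < 0.8:
        agg["creatinine"] = float(rng.uniform(30, 700))
    if rng.random() < 0.4:
        agg["urine_output"] = float(rng.uniform(10, 4000))
    vaso = {}
    if rng.random() < 0.3:
        vaso["norepinephrine"] = float(rng.uniform(0.005, 0.6))
    if rng.random() < 0.2:
        vaso["dopamine"] = float(rng.uniform(0.2, 25))
    if rng.random() < 0.1:
        vaso["dobutamine"] = float(rng.uniform(1, 10))
    agg["vasopressors"] = vaso
    agg["ventilated"] = bool(rng.random() < 0.4)
    return agg


class TestScoreComponent:
    @pytest.mark.parametrize(
        "component, agg, expected",
        [
            ("coagulation", {"platelets": 90.0}, 2),  # 50-99 band
            ("coagulation", {"platelets": 150.0}, 0),
            ("cns", {"gcs": 15.0}, 0),
            ("cns", {"gcs": 5.0}, 4),
            ("liver", {}, None),  # no bilirubin in window -> missing
            ("cardiovascular", {"vasopressors": {"norepinephrine": 0.2}}, 4),
            ("cardiovascular", {"vasopressors": {"norepinephrine": 0.05}}, 3),
            ("cardiovascular", {"vasopressors": {"dopamine": 3.0}}, 2),
            ("cardiovascular", {"map": 65.0, "vasopressors": {}}, 1),
            ("cardiovascular", {"map": 80.0, "vasopressors": {}}, 0),
            ("renal", {"creatinine": 90.0, "urine_output": 450.0}, 3),  # urine override
            ("respiration", {"pao2": 12.0, "fio2": 0.6, "ventilated": True}, 3),
            ("respiration", {"pao2": 12.0, "fio2": 0.6, "ventilated": False}, 2),  # capped
        ],
    )
    def test_worked_examples(self, component, agg, expected, thresholds):
        assert score_component(component, agg, thresholds) == expected

    def test_unknown_component_rejected(self, thresholds):
        with pytest.raises(ValueError, match="unknown SOFA component"):
            score_component("cardiac", {}, thresholds)

    def test_agrees_with_band_scan_oracle(self, thresholds):
        """10,000 random windows: implementation equals the exhaustive band scan."""
        rng = np.random.default_rng(20220315)
        for _ in range(10_000):
            agg = random_aggregates(rng)
            for component in COMPONENTS:
                assert score_component(component, agg, thresholds) == oracle_score(
                    component, agg, thresholds
                ), (component, agg)


class TestWorstInWindow:
    def test_directions(self):
        events = pd.DataFrame(
            {
                "concept": ["platelets", "platelets", "bilirubin", "bilirubin"],
                "day": [0, 0, 0, 0],
                "value": [120.0, 80.0, 30.0, 110.0],
            }
        )
        assert worst_in_window(events, "platelets", 0) == 80.0  # min is worst
        assert worst_in_window(events, "bilirubin", 0) == 110.0  # max is worst
        assert worst_in_window(events, "creatinine", 0) is None


class TestDailySofa:
    def test_totals_are_sum_of_non_missing(self, random_cohort_250):
        sofa = random_cohort_250.sofa
        components = [c for c in sofa.columns if c.startswith("sofa_") and c.endswith("_score")
                      and c != "sofa_total_score"]
        recomputed = sofa[components].sum(axis=1, skipna=True).astype(int)
        assert (sofa["sofa_total_score"] == recomputed).all()
        assert sofa["sofa_total_score"].between(0, 24).all()
        assert (sofa["n_missing"] == sofa[components].isna().sum(axis=1)).all()

    def test_event_order_is_irrelevant(self, worked_example, thresholds):
        store = worked_example.store
        shuffled = ic.EventStore(
            admissions=store.admissions,
            events=store.events.sample(frac=1.0, random_state=5).reset_index(drop=True),
        )
        a = ic.daily_sofa(store, thresholds, (-3, 1))
        b = ic.daily_sofa(shuffled, thresholds, (-3, 1))
        pd.testing.assert_frame_equal(a, b)

    def test_day_zero_always_present(self, random_cohort_250):
        sofa = random_cohort_250.sofa
        with_day0 = set(sofa.loc[sofa["time"] == 0, "admissionid"])
        assert with_day0 == set(random_cohort_250.store.admission_ids())

    def test_no_admissions_gives_empty_frame(self, thresholds):
        store = ic.EventStore(
            admissions=pd.DataFrame(columns=["admissionid", "patientid", "admittedat",
                                             "urgency", "surgical", "location",
                                             "is_first_admission"]),
            events=pd.DataFrame(columns=["admissionid", "concept", "item", "value",
                                         "text", "route", "measuredat", "day"]),
        )
        assert len(ic.daily_sofa(store, thresholds, (-1, 7))) == 0

    def test_day_range_must_contain_zero(self, worked_example, thresholds):
        with pytest.raises(ValueError, match="contain 0"):
            ic.daily_sofa(worked_example.store, thresholds, (1, 5))
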