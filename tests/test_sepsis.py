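"""Delta rule, sepsis-episode logic, septic shock and pipeline determinism."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

import icusepsis as ic
from icusepsis.schema_io import SEPSIS_COLUMNS
from icusepsis.sepsis import delta_rule


class TestDeltaRule:
    def test_brute_force_all_triples(self):
        """All (prev, cur, next) totals in [0,24]^3 against a pairwise oracle."""
        rng_range = range(0, 25)
        for a, b, c in itertools.product(rng_range, rng_range, rng_range):
            totals = {-1: a, 0: b, 1: c}
            expected = (b - a >= 2) or (c - a >= 2) or (c - b >= 2)
            assert delta_rule(totals, 0, (-1, 1)) is expected

    def test_pre_admission_rise(self):
        # totals 0 -> 1 -> 6: the previous-to-subsequent rise fires at the middle day
        assert delta_rule({-2: 0, -1: 1, 0: 6}, -1, (-2, 0)) is True

    def test_flat_trajectory_is_false(self):
        assert delta_rule({0: 5, 1: 5, 2: 5}, 1, (0, 2)) is False

    def test_boundary_skips_missing_neighbour(self):
        # no day d+1 in range: only the previous-to-current clause applies
        assert delta_rule({1: 0, 2: 2}, 2, (0, 2)) is True
        assert delta_rule({1: 0, 2: 1}, 2, (0, 2)) is False
        # no day d-1 in range: only the current-to-subsequent clause applies
        assert delta_rule({0: 0, 1: 2}, 0, (0, 2)) is True

    def test_days_without_rows_count_zero(self):
        # day -2 absent from totals but inside the range -> total 0
        assert delta_rule({-1: 0, 0: 3}, -1, (-3, 1)) is True

    def test_day_outside_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            delta_rule({}, 5, (-1, 2))


class TestWorkedExampleFlags:
    """The documented four-admission example, cell by cell."""

    @pytest.fixture(autouse=True)
    def _flags(self, worked_example):
        self.flags = worked_example.flags.set_index(["admissionid", "time"])

    def row(self, admission, day):
        return self.flags.loc[(admission, day)]

    def test_pre_admission_sepsis_with_mostly_missing_components(self):
        # admission 2, day -1: escalation amid a 0 -> 1 -> 6 total trajectory
        row = self.row(2, -1)
        assert row["antibiotic_escalation"] is True
        assert not row["prophylaxis"]
        assert row["infection"] and row["sepsis_episode"] and not row["septic_shock"]

    def test_elective_surgery_escalation_is_prophylactic(self):
        row = self.row(0, -1)
        assert row["antibiotic_escalation"] is True
        assert row["prophylaxis"]
        assert not row["infection"] and not row["sepsis_episode"]

    def test_continuing_regimen_is_not_escalation(self):
        assert self.row(0, 0)["antibiotic_escalation"] is False
        assert self.row(3, 0)["antibiotic_escalation"] is False

    def test_no_antibiotics_gives_undefined_escalation(self):
        assert pd.isna(self.row(0, 1)["antibiotic_escalation"])
        assert pd.isna(self.row(2, -2)["antibiotic_escalation"])

    def test_antibiotic_only_window_appears_with_zero_total(self):
        row = self.row(3, -1)
        assert row["sofa_total_score"] == 0
        assert row["sepsis_episode"]


def _run(store, day_range):
    return ic.run_pipeline(
        store, ic.default_thresholds(), ic.default_rank_map(),
        ic.default_shock_criteria(), day_range=day_range,
    )


class TestElectiveSuppression:
    def _cohort(self, tmp_path, urgency, surgical):
        scenario = ic.AdmissionScenario(
            admission_id=0, patient_id=0, urgency=urgency, surgical=surgical,
            component_scores={
                -1: {"coagulation": 0, "renal": 0, "cns": 0, "cardiovascular": 0},
                0: {"respiration": 2, "coagulation": 2, "cns": 0,
                    "cardiovascular": 0, "renal": 0},
                2: {"coagulation": 0, "renal": 0, "cns": 0, "cardiovascular": 0},
                3: {"respiration": 2, "coagulation": 2, "cns": 0,
                    "cardiovascular": 0, "renal": 0},
            },
            antibiotics=[("cefazolin", 0, "iv"), ("cefazolin", 1, "iv"),
                         ("meropenem", 3, "iv")],
        )
        spec = ic.ScenarioSpec(admissions=[scenario], day_range=(-1, 4), rng_seed=1)
        tables, _ = ic.generate(spec, out_dir=tmp_path)
        return ic.read_tables(
            {n: tmp_path / f"{n}.csv" for n in tables}, ic.default_concept_map()
        )

    def test_elective_admission_suppresses_first_two_windows_only(self, tmp_path):
        store = self._cohort(tmp_path / "elective", urgency=False, surgical=True)
        _, flags = _run(store, (-1, 4))
        flags = flags.set_index("time")
        # escalation at day 0 with a >=2 SOFA rise: suppressed as prophylaxis
        assert flags.loc[0, "antibiotic_escalation"] is True
        assert flags.loc[0, "prophylaxis"] and not flags.loc[0, "sepsis_episode"]
        assert not flags.loc[1, "sepsis_episode"]
        # a later escalation (new reserve agent, day 3) still qualifies
        assert flags.loc[3, "antibiotic_escalation"] is True
        assert not flags.loc[3, "prophylaxis"]
        assert flags.loc[3, "sepsis_episode"]

    def test_urgent_admission_is_not_suppressed(self, tmp_path):
        store = self._cohort(tmp_path / "urgent", urgency=True, surgical=True)
        _, flags = _run(store, (-1, 4))
        flags = flags.set_index("time")
        assert not flags.loc[0, "prophylaxis"]
        assert flags.loc[0, "sepsis_episode"]


class TestMissingnessDiscard:
    def _store(self, tmp_path, day0_components):
        scenario = ic.AdmissionScenario(
            admission_id=0, patient_id=0, urgency=True, surgical=False,
            component_scores={0: day0_components},
            antibiotics=[("meropenem", 0, "iv")],
        )
        spec = ic.ScenarioSpec(admissions=[scenario], day_range=(-1, 1), rng_seed=1)
        tables, _ = ic.generate(spec, out_dir=tmp_path)
        return ic.read_tables(
            {n: tmp_path / f"{n}.csv" for n in tables}, ic.default_concept_map()
        )

    def test_three_missing_components_discard_identification(self, tmp_path):
        # escalation + big SOFA rise, but only 2 components observed on day 0
        store = self._store(tmp_path, {"respiration": 3, "coagulation": 2})
        _, flags = _run(store, (-1, 1))
        day0 = flags.set_index("time").loc[0]
        assert day0["infection"]
        assert not day0["sepsis_episode"]
        assert day0["indeterminate"]

    def test_enough_components_identify_sepsis(self, tmp_path):
        store = self._store(
            tmp_path,
            {"respiration": 3, "coagulation": 2, "cns": 0, "renal": 0},
        )
        _, flags = _run(store, (-1, 1))
        day0 = flags.set_index("time").loc[0]
        assert day0["sepsis_episode"] and not day0["indeterminate"]


class TestSepticShock:
    def _flags(self, tmp_path, cardiovascular, lactate):
        comps = {"respiration": 2, "coagulation": 2, "cns": 0, "renal": 0}
        if cardiovascular is not None:
            comps["cardiovascular"] = cardiovascular
        scenario = ic.AdmissionScenario(
            admission_id=0, patient_id=0, urgency=True, surgical=False,
            component_scores={
                -1: {"coagulation": 0, "renal": 0, "cns": 0, "cardiovascular": 0},
                0: comps,
            },
            antibiotics=[("meropenem", 0, "iv")],
            lactate={0: lactate} if lactate is not None else {},
        )
        spec = ic.ScenarioSpec(admissions=[scenario], day_range=(-1, 1), rng_seed=1)
        tables, _ = ic.generate(spec, out_dir=tmp_path)
        store = ic.read_tables(
            {n: tmp_path / f"{n}.csv" for n in tables}, ic.default_concept_map()
        )
        _, flags = _run(store, (-1, 1))
        return flags.set_index("time").loc[0]

    def test_vasopressors_and_high_lactate(self, tmp_path):
        row = self._flags(tmp_path, cardiovascular=4, lactate=3.1)
        assert row["sepsis_episode"] and row["septic_shock"]

    def test_low_cardiovascular_score_fails(self, tmp_path):
        row = self._flags(tmp_path, cardiovascular=2, lactate=5.0)
        assert row["sepsis_episode"] and not row["septic_shock"]

    def test_missing_lactate_fails(self, tmp_path):
        row = self._flags(tmp_path, cardiovascular=4, lactate=None)
        assert row["sepsis_episode"] and not row["septic_shock"]

    def test_shock_monotone_in_lactate_and_cardio(self, tmp_path):
        # weakening either criterion can only switch shock off, never on
        base = self._flags(tmp_path / "a", cardiovascular=3, lactate=2.5)
        weaker_lactate = self._flags(tmp_path / "b", cardiovascular=3, lactate=1.0)
        weaker_cardio = self._flags(tmp_path / "c", cardiovascular=1, lactate=2.5)
        assert base["septic_shock"]
        assert not weaker_lactate["septic_shock"]
        assert not weaker_cardio["septic_shock"]


class TestLogicalChain:
    @pytest.mark.parametrize("cohort_fixture", ["worked_example", "random_cohort_250",
                                                "matched_cohort"])
    def test_implication_chain_holds_everywhere(self, cohort_fixture, request):
        flags = request.getfixturevalue(cohort_fixture).flags
        for row in flags.itertuples():
            if row.septic_shock:
                assert row.sepsis_episode
            if row.sepsis_episode:
                assert row.infection
            if row.infection:
                assert row.antibiotic_escalation is True and not row.prophylaxis


class TestPipeline:
    def test_reruns_are_byte_identical(self, worked_example, tmp_path):
        for run in ("one", "two"):
            ic.run_pipeline(
                worked_example.store, ic.default_thresholds(), ic.default_rank_map(),
                ic.default_shock_criteria(), day_range=(-3, 1),
                out_dir=tmp_path / run,
            )
        for name in ("sofa.csv", "sepsis.csv"):
            assert (tmp_path / "one" / name).read_bytes() == (
                tmp_path / "two" / name
            ).read_bytes()

    def test_empty_store_gives_header_only_outputs(self, tmp_path):
        spec = ic.ScenarioSpec(admissions=[], day_range=(-1, 1), rng_seed=0)
        tables, _ = ic.generate(spec, out_dir=tmp_path / "tables")
        store = ic.read_tables(
            {n: tmp_path / "tables" / f"{n}.csv" for n in tables},
            ic.default_concept_map(),
        )
        ic.run_pipeline(
            store, ic.default_thresholds(), ic.default_rank_map(),
            ic.default_shock_criteria(), day_range=(-1, 1), out_dir=tmp_path / "out",
        )
        assert (tmp_path / "out" / "sofa.csv").read_text().count("\n") == 1
        assert (tmp_path / "out" / "sepsis.csv").read_text().count("\n") == 1
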