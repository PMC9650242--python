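"""Synthetic ICU cohorts with planted, independently derived ground truth.

The generator emits the four input CSV tables (admissions, drugitems,
numericitems, listitems) in the documented synthetic vocabulary, from a
scenario that plants per-window SOFA component *scores* and an antibiotic
schedule.  Raw values are drawn uniformly inside the score band implied by
the active thresholds, kept away from band edges by a configurable margin,
so the intended component score is recoverable without threshold-edge
ambiguity.

Ground truth (expected SOFA rows and sepsis flags) is computed here by a
second, direct application of the scoring/escalation/episode rules to the
planted scenario — deliberately *not* by calling the pipeline — so that the
label-recovery test is a genuine two-implementation cross-check.

What this emulates: the relational structure of AmsterdamUMCdb-shaped
tables, worst-in-window score recovery, escalation patterns (new IV starts,
continuations, SDD decontamination, elective perioperative prophylaxis) and
shock physiology at the level of score bands.  What it does not emulate:
realistic physiological dynamics, measurement frequency, unit heterogeneity
or the real item vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    AntibioticRankMap,
    ShockCriteria,
    SofaThresholds,
    default_rank_map,
    default_shock_criteria,
    default_thresholds,
)
from .schema_io import MS_PER_DAY, SEPSIS_COLUMNS, SOFA_COLUMNS
from .sofa import COMPONENTS

__all__ = [
    "AdmissionScenario",
    "ScenarioSpec",
    "GroundTruth",
    "generate",
    "tables23_fixture",
    "random_cohort",
]

_NUMERIC_ITEM = {
    "pao2": "pao2",
    "fio2": "fio2",
    "platelets": "platelets",
    "bilirubin": "bilirubin",
    "map": "mean_abp",
    "gcs": "gcs_total",
    "creatinine": "creatinine",
    "urine_output": "urine_output_24h",
    "lactate": "lactate",
}

_ITEM_UNIT = {
    "pao2": "kPa",
    "fio2": "fraction",
    "platelets": "1e9/L",
    "bilirubin": "umol/L",
    "mean_abp": "mmHg",
    "gcs_total": "points",
    "creatinine": "umol/L",
    "urine_output_24h": "mL/day",
    "lactate": "mmol/L",
}


@dataclass
class AdmissionScenario:
    """Planted course of one admission.

    ``component_scores`` maps day -> {component: score}; a component absent
    from a day's dict is missing in that window.  ``antibiotics`` is a list of
    (drug name, day, route) administrations; ``lactate`` maps day -> mmol/L.
    """

    admission_id: int
    patient_id: int
    urgency: bool = True
    surgical: bool = False
    location: str = "ICU"
    is_first_admission: bool = True
    component_scores: dict = field(default_factory=dict)
    antibiotics: list = field(default_factory=list)
    lactate: dict = field(default_factory=dict)
    admission_form_sepsis: bool = False
    admission_diagnosis: str | None = None
    culture_hours: list = field(default_factory=list)


@dataclass
class ScenarioSpec:
    """A synthetic cohort: admissions, observation day range and RNG seed."""

    admissions: list
    day_range: tuple[int, int] = (-1, 7)
    rng_seed: int = 0
    band_margin: float = 0.01


@dataclass
class GroundTruth:
    """Expected pipeline output, derived from the scenario by construction."""

    sofa: pd.DataFrame
    sepsis: pd.DataFrame
    admission_labels: pd.DataFrame  # admissionid, sepsis3_at_admission


# ---------------------------------------------------------------------------
# score-band inversion


def _draw(rng: np.random.Generator, lo: float, hi: float, margin: float) -> float:
    width = hi - lo
    return float(rng.uniform(lo + margin * width, hi - margin * width))


def _band_edges(score: int, descending_cutoffs, top: float, bottom: float):
    """[lo, hi) interval of a 'low is bad' input for a given score."""
    cuts = list(descending_cutoffs)
    if score == 0:
        return cuts[0], top
    if score == len(cuts):
        return bottom, cuts[-1]
    return cuts[score], cuts[score - 1]


def _band_edges_ascending(score: int, bounds, bottom: float, top: float):
    """[lo, hi) interval of a 'high is bad' input for a given score."""
    bds = list(bounds)
    if score == 0:
        return bottom, bds[0]
    if score == len(bds):
        return bds[-1], top
    return bds[score - 1], bds[score]


def _plant_component(
    rng: np.random.Generator,
    component: str,
    score: int,
    thresholds: SofaThresholds,
    margin: float,
):
    """Raw (item, value) events realising a planted component score."""
    if not 0 <= score <= 4:
        raise ValueError(f"planted score {score} out of range for {component}")
    events = []
    if component == "respiration":
        lo, hi = _band_edges(score, thresholds.pf_cutoffs, 80.0, 3.0)
        fio2 = 0.6
        ratio = _draw(rng, lo, hi, margin)
        events.append(("pao2", ratio * fio2))
        events.append(("fio2", fio2))
        if score >= thresholds.ventilation_required_from:
            events.append(("__ventilated__", 1.0))
    elif component == "coagulation":
        lo, hi = _band_edges(score, thresholds.platelet_cutoffs, 350.0, 2.0)
        events.append(("platelets", _draw(rng, lo, hi, margin)))
    elif component == "liver":
        lo, hi = _band_edges_ascending(score, thresholds.bilirubin_bounds, 2.0, 400.0)
        events.append(("bilirubin", _draw(rng, lo, hi, margin)))
    elif component == "cardiovascular":
        if score == 0:
            events.append(("mean_abp", _draw(rng, thresholds.hypotension_map, 100.0, margin)))
        elif score == 1:
            events.append(("mean_abp", _draw(rng, 45.0, thresholds.hypotension_map, margin)))
        elif score == 2:
            events.append(("__vasopressor__dopamine", _draw(rng, 0.5, thresholds.dopamine_low, margin)))
        elif score == 3:
            events.append(
                ("__vasopressor__norepinephrine",
                 _draw(rng, 0.01, thresholds.norepinephrine_cutoff, margin))
            )
        else:
            events.append(
                ("__vasopressor__norepinephrine",
                 _draw(rng, thresholds.norepinephrine_cutoff * 1.05, 0.5, margin))
            )
    elif component == "cns":
        bands = {0: (15, 15), 1: (13, 14), 2: (10, 12), 3: (6, 9), 4: (3, 5)}
        lo, hi = bands[score]
        events.append(("gcs_total", float(rng.integers(lo, hi + 1))))
    elif component == "renal":
        lo, hi = _band_edges_ascending(score, thresholds.creatinine_bounds, 40.0, 700.0)
        events.append(("creatinine", _draw(rng, lo, hi, margin)))
        if rng.random() < 0.3:  # consistent urine output, never raising the score
            if score == 4:
                events.append(("urine_output_24h", _draw(rng, 50.0, thresholds.urine_very_low, margin)))
            elif score == 3:
                events.append(
                    ("urine_output_24h",
                     _draw(rng, thresholds.urine_very_low, thresholds.urine_low, margin))
                )
            else:
                events.append(("urine_output_24h", _draw(rng, thresholds.urine_low * 1.4, 2500.0, margin)))
    else:
        raise ValueError(f"unknown component {component!r}")
    return events


# ---------------------------------------------------------------------------
# independent ground-truth derivation


def _truth_regimens(
    scenario: AdmissionScenario, rank_map: AntibioticRankMap, day_range
) -> tuple[dict, set]:
    """Per-day retained agent sets after SDD exclusion, and SDD-only days."""
    d_min, d_max = day_range
    all_days: set[int] = set()
    retained_days: set[int] = set()
    kept_by_day: dict[int, set] = {}
    for name, day, route in scenario.antibiotics:
        if not d_min <= day <= d_max:
            continue
        canon, rank = rank_map.resolve(name)
        all_days.add(day)
        if canon in rank_map.sdd_drugs and day in rank_map.sdd_days:
            continue
        retained_days.add(day)
        if rank is not None:
            kept_by_day.setdefault(day, set()).add((canon, rank, route.casefold()))
    sdd_only = all_days - retained_days
    return kept_by_day, sdd_only


def _strength(agents: set) -> tuple[int, int]:
    if not agents:
        return (0, 0)
    top = max(rank for _, rank, _ in agents)
    return (top, len({name for name, rank, _ in agents if rank == top}))


def _truth_escalation(kept_by_day: dict, day_range) -> dict:
    d_min, d_max = day_range
    out = {}
    for day in range(d_min, d_max + 1):
        agents = kept_by_day.get(day, set())
        if not agents:
            out[day] = None
        elif not any(route == "iv" for _, _, route in agents):
            out[day] = False
        else:
            out[day] = _strength(agents) > _strength(kept_by_day.get(day - 1, set()))
    return out


def _truth_delta(totals: dict, day: int, day_range) -> bool:
    # any ordered pair (earlier, later) within the in-range neighbourhood
    d_min, d_max = day_range
    days = [d for d in (day - 1, day, day + 1) if d_min <= d <= d_max]
    return any(
        totals.get(b, 0) - totals.get(a, 0) >= 2
        for i, a in enumerate(days)
        for b in days[i + 1:]
    )


def _truth_for_admission(
    scenario: AdmissionScenario,
    rank_map: AntibioticRankMap,
    shock: ShockCriteria,
    day_range,
) -> tuple[list, list, bool]:
    d_min, d_max = day_range
    kept, sdd_only = _truth_regimens(scenario, rank_map, day_range)
    escalation = _truth_escalation(kept, day_range)

    elective = (not scenario.urgency) and scenario.surgical
    span: set = set()
    if elective:
        at_admission = [d for d, e in escalation.items() if e is True and d <= 0]
        if at_admission:
            d0 = min(at_admission)
            span = {d0, d0 + 1}

    planted = {
        d: comps for d, comps in scenario.component_scores.items() if d_min <= d <= d_max
    }
    totals = {d: sum(comps.values()) for d, comps in planted.items()}
    ab_days = {d for _, d, _ in scenario.antibiotics if d_min <= d <= d_max}
    row_days = sorted(set(planted) | ab_days | {0})

    sofa_rows, sepsis_rows = [], []
    for day in row_days:
        comps = planted.get(day, {})
        n_missing = 6 - len(comps)
        total = int(totals.get(day, 0))
        if day in planted or day == 0:  # antibiotic-only days have no SOFA row
            row = {"admissionid": scenario.admission_id, "time": day}
            for c in COMPONENTS:
                row[f"sofa_{c}_score"] = comps.get(c)
            row["sofa_total_score"] = total
            row["n_missing"] = n_missing
            sofa_rows.append(row)

        esc = escalation[day]
        prophylaxis = day in sdd_only or (esc is True and day in span)
        infection = esc is True and not prophylaxis
        discard = day >= 0 and n_missing >= 3
        episode = infection and _truth_delta(totals, day, day_range) and not discard
        lactate = scenario.lactate.get(day)
        cardio = comps.get("cardiovascular")
        is_shock = bool(
            episode
            and cardio is not None
            and cardio >= shock.cardiovascular_min_score
            and lactate is not None
            and shock.lactate_meets(lactate)
        )
        sepsis_rows.append(
            {
                "admissionid": scenario.admission_id,
                "time": day,
                "sofa_total_score": total,
                "antibiotic_escalation": esc if esc is not None else np.nan,
                "prophylaxis": bool(prophylaxis),
                "infection": bool(infection),
                "sepsis_episode": bool(episode),
                "septic_shock": is_shock,
            }
        )

    at_admission_sepsis = any(
        r["sepsis_episode"] for r in sepsis_rows if r["time"] in (-1, 0)
    )
    return sofa_rows, sepsis_rows, at_admission_sepsis


# ---------------------------------------------------------------------------
# table assembly


def generate(
    spec: ScenarioSpec,
    thresholds: SofaThresholds | None = None,
    rank_map: AntibioticRankMap | None = None,
    shock: ShockCriteria | None = None,
    out_dir: str | Path | None = None,
) -> tuple[dict, GroundTruth]:
    """Materialise a scenario into the four input tables plus ground truth.

    Returns ``(tables, truth)`` where ``tables`` maps table name to DataFrame;
    with ``out_dir`` the tables and both ground-truth tables are also written
    as CSV.  Deterministic for a given spec and seed.
    """
    thresholds = thresholds or default_thresholds()
    rank_map = rank_map or default_rank_map()
    shock = shock or default_shock_criteria()
    rng = np.random.default_rng(spec.rng_seed)
    d_min, d_max = spec.day_range
    if not d_min <= 0 <= d_max:
        raise ValueError("day range must contain day 0")

    adm_rows, drug_rows, num_rows, list_rows = [], [], [], []
    sofa_rows, sepsis_rows, label_rows = [], [], []

    for scenario in spec.admissions:
        adm_rows.append(
            {
                "admissionid": scenario.admission_id,
                "patientid": scenario.patient_id,
                "admittedat": int(scenario.admission_id) * 1_000_000_000,
                "urgency": scenario.urgency,
                "surgical": scenario.surgical,
                "location": scenario.location,
                "is_first_admission": scenario.is_first_admission,
            }
        )

        for day, comps in sorted(scenario.component_scores.items()):
            for component in COMPONENTS:
                if component not in comps:
                    continue
                score = comps[component]
                for item, value in _plant_component(
                    rng, component, score, thresholds, spec.band_margin
                ):
                    at = day * MS_PER_DAY + int(rng.integers(0, MS_PER_DAY))
                    if item == "__ventilated__":
                        list_rows.append(
                            {
                                "admissionid": scenario.admission_id,
                                "item": "mechanical_ventilation",
                                "value": "True",
                                "measuredat": at,
                            }
                        )
                    elif item.startswith("__vasopressor__"):
                        drug_rows.append(
                            {
                                "admissionid": scenario.admission_id,
                                "item": item.removeprefix("__vasopressor__"),
                                "start": at,
                                "route": "iv",
                                "dose": round(value, 4),
                                "doseunit": "ug/kg/min",
                            }
                        )
                    else:
                        num_rows.append(
                            {
                                "admissionid": scenario.admission_id,
                                "item": item,
                                "value": round(value, 3),
                                "unit": _ITEM_UNIT[item],
                                "measuredat": at,
                            }
                        )

        for day, value in sorted(scenario.lactate.items()):
            num_rows.append(
                {
                    "admissionid": scenario.admission_id,
                    "item": "lactate",
                    "value": round(value, 3),
                    "unit": "mmol/L",
                    "measuredat": day * MS_PER_DAY + int(rng.integers(0, MS_PER_DAY)),
                }
            )

        for name, day, route in scenario.antibiotics:
            drug_rows.append(
                {
                    "admissionid": scenario.admission_id,
                    "item": name,
                    "start": day * MS_PER_DAY + int(rng.integers(0, MS_PER_DAY)),
                    "route": route,
                    "dose": 1000.0,
                    "doseunit": "mg",
                }
            )

        if scenario.admission_form_sepsis:
            list_rows.append(
                {
                    "admissionid": scenario.admission_id,
                    "item": "admission_form_sepsis",
                    "value": "1",
                    "measuredat": int(rng.integers(0, 3_600_000)),
                }
            )
        if scenario.admission_diagnosis:
            list_rows.append(
                {
                    "admissionid": scenario.admission_id,
                    "item": "admission_diagnosis",
                    "value": scenario.admission_diagnosis,
                    "measuredat": int(rng.integers(0, 3_600_000)),
                }
            )
        for hours in scenario.culture_hours:
            list_rows.append(
                {
                    "admissionid": scenario.admission_id,
                    "item": "culture_drawn",
                    "value": "1",
                    "measuredat": int(hours * 3_600_000),
                }
            )

        adm_sofa, adm_sepsis, s3_at_adm = _truth_for_admission(
            scenario, rank_map, shock, spec.day_range
        )
        sofa_rows.extend(adm_sofa)
        sepsis_rows.extend(adm_sepsis)
        label_rows.append(
            {"admissionid": scenario.admission_id, "sepsis3_at_admission": s3_at_adm}
        )

    tables = {
        "admissions": pd.DataFrame(
            adm_rows,
            columns=[
                "admissionid", "patientid", "admittedat", "urgency",
                "surgical", "location", "is_first_admission",
            ],
        ),
        "drugitems": pd.DataFrame(
            drug_rows, columns=["admissionid", "item", "start", "route", "dose", "doseunit"]
        ),
        "numericitems": pd.DataFrame(
            num_rows, columns=["admissionid", "item", "value", "unit", "measuredat"]
        ),
        "listitems": pd.DataFrame(
            list_rows, columns=["admissionid", "item", "value", "measuredat"]
        ),
    }

    truth_sofa = pd.DataFrame(sofa_rows, columns=[*SOFA_COLUMNS[:2], *SOFA_COLUMNS[2:8],
                                                  "sofa_total_score", "n_missing"])
    if len(truth_sofa):
        for col in SOFA_COLUMNS[2:8]:
            truth_sofa[col] = truth_sofa[col].astype("Int64")
        truth_sofa = truth_sofa.sort_values(["admissionid", "time"], kind="mergesort")
    truth_sepsis = pd.DataFrame(sepsis_rows, columns=SEPSIS_COLUMNS)
    if len(truth_sepsis):
        truth_sepsis = truth_sepsis.sort_values(["admissionid", "time"], kind="mergesort")
    truth = GroundTruth(
        sofa=truth_sofa.reset_index(drop=True),
        sepsis=truth_sepsis.reset_index(drop=True),
        admission_labels=pd.DataFrame(
            label_rows, columns=["admissionid", "sepsis3_at_admission"]
        ),
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out_dir / f"{name}.csv", index=False)
        from .schema_io import write_sepsis_table, write_sofa_table

        write_sofa_table(truth.sofa, out_dir / "ground_truth_sofa.csv")
        write_sepsis_table(truth.sepsis, out_dir / "ground_truth_sepsis.csv")
        truth.admission_labels.to_csv(out_dir / "ground_truth_admissions.csv", index=False)

    return tables, truth


# ---------------------------------------------------------------------------
# canned scenarios


def tables23_fixture() -> ScenarioSpec:
    """Four-admission scenario reproducing the documented worked example.

    Admissions 0 and 1 are elective surgical with perioperative IV cefazolin
    (escalation suppressed as prophylaxis); admissions 2 and 3 are unplanned
    with a new IV ceftriaxone start the day before admission and an acute
    SOFA rise, so both have a pre-admission sepsis window.
    """
    adm0 = AdmissionScenario(
        admission_id=0, patient_id=0, urgency=False, surgical=True,
        component_scores={
            -1: {"coagulation": 0, "renal": 0},
            0: {"respiration": 3, "coagulation": 0, "cardiovascular": 1, "cns": 0, "renal": 0},
            1: {"respiration": 2, "coagulation": 1, "cardiovascular": 2, "renal": 0},
        },
        antibiotics=[("cefazolin", -1, "iv"), ("cefazolin", 0, "iv")],
    )
    adm1 = AdmissionScenario(
        admission_id=1, patient_id=1, urgency=False, surgical=True,
        component_scores={
            -1: {"coagulation": 1, "renal": 0},
            0: {"respiration": 2, "coagulation": 0, "cardiovascular": 2, "cns": 0, "renal": 0},
            1: {"cardiovascular": 0, "renal": 0},
        },
        antibiotics=[("cefazolin", -1, "iv"), ("cefazolin", 0, "iv")],
    )
    adm2 = AdmissionScenario(
        admission_id=2, patient_id=2, urgency=True, surgical=False,
        component_scores={
            -2: {"coagulation": 0, "liver": 0, "renal": 0},
            -1: {"coagulation": 1},
            0: {"respiration": 2, "coagulation": 0, "cardiovascular": 4, "cns": 0, "renal": 0},
        },
        antibiotics=[("ceftriaxone", -1, "iv"), ("ceftriaxone", 0, "iv")],
        lactate={0: 1.4},
    )
    adm3 = AdmissionScenario(
        admission_id=3, patient_id=3, urgency=True, surgical=False,
        component_scores={
            -3: {"coagulation": 0, "renal": 1},
            0: {"respiration": 2, "coagulation": 0, "cardiovascular": 0, "renal": 1},
        },
        antibiotics=[("ceftriaxone", -1, "iv"), ("ceftriaxone", 0, "iv")],
    )
    return ScenarioSpec(admissions=[adm0, adm1, adm2, adm3], day_range=(-3, 1), rng_seed=2022)


def random_cohort(
    n_admissions: int,
    seed: int,
    day_range: tuple[int, int] = (-1, 5),
    baseline_mode: str = "independent",
) -> ScenarioSpec:
    """Random cohort mixing healthy, SDD, elective-prophylaxis, sepsis and shock courses.

    ``baseline_mode`` controls the legacy admission-form flag: ``independent``
    plants it haphazardly, ``match`` plants it exactly on admissions whose
    ground truth has a sepsis episode at day -1/0 (and suppresses every other
    legacy criterion), ``anti`` plants its complement.
    """
    if baseline_mode not in ("independent", "match", "anti"):
        raise ValueError(f"unknown baseline_mode {baseline_mode!r}")
    rng = np.random.default_rng(seed)
    d_min, d_max = day_range
    scenarios = []
    archetypes = rng.choice(
        ["healthy", "sdd", "elective", "sepsis", "shock"],
        size=n_admissions,
        p=[0.30, 0.15, 0.20, 0.25, 0.10],
    )
    for i, archetype in enumerate(archetypes):
        scenario = AdmissionScenario(
            admission_id=i,
            patient_id=i,
            urgency=True,
            surgical=False,
            location="ICU" if rng.random() < 0.8 else "MCU",
        )
        # baseline course: mild scores on the first few days
        for day in range(max(d_min, -1), min(2, d_max) + 1):
            comps = {}
            for component, p_present in [
                ("coagulation", 0.85), ("renal", 0.85), ("cns", 0.7),
                ("cardiovascular", 0.7), ("respiration", 0.5), ("liver", 0.4),
            ]:
                if rng.random() < p_present:
                    comps[component] = int(rng.integers(0, 2))
            scenario.component_scores[day] = comps

        if archetype == "sdd":
            scenario.antibiotics = [
                ("cefotaxime", d, "iv") for d in range(0, min(3, d_max) + 1) for _ in range(2)
            ]
        elif archetype == "elective":
            scenario.urgency = False
            scenario.surgical = True
            start = -1 if d_min <= -1 else 0
            scenario.antibiotics = [("cefazolin", start, "iv"), ("cefazolin", 0, "iv")]
        elif archetype in ("sepsis", "shock"):
            latest = min(3, d_max - 1)
            d_star = int(rng.integers(0, latest + 1)) if archetype == "shock" else int(
                rng.integers(max(d_min, -1), latest + 1)
            )
            deterioration = {
                "respiration": 2,
                "coagulation": int(rng.integers(1, 3)),
                "cns": int(rng.integers(0, 2)),
                "renal": int(rng.integers(0, 2)),
            }
            if archetype == "shock":
                deterioration["cardiovascular"] = 4
                scenario.lactate[d_star] = float(rng.uniform(2.3, 7.0))
            else:
                deterioration["cardiovascular"] = int(rng.integers(0, 2))
                if rng.random() < 0.5:
                    scenario.lactate[d_star] = float(rng.uniform(0.6, 1.8))
            if d_star < 0:
                # pre-admission escalation: sparse low window at d*, acute
                # rise into the admission window (delta fires on d* -> d*+1)
                scenario.component_scores[d_star] = {"coagulation": 1}
                scenario.component_scores[d_star + 1] = deterioration
            else:
                # quiet day before, acute multi-organ deterioration on d*
                if d_star - 1 >= d_min:
                    scenario.component_scores[d_star - 1] = {
                        "coagulation": 0, "renal": 0, "cns": 0, "cardiovascular": 0,
                    }
                scenario.component_scores[d_star] = deterioration
            antibiotic = str(rng.choice(["ceftriaxone", "piperacillin-tazobactam", "meropenem"]))
            scenario.antibiotics = [
                (antibiotic, d, "iv") for d in range(d_star, min(d_star + 2, d_max) + 1)
            ]
        else:  # healthy; occasionally an oral agent that can never escalate
            if rng.random() < 0.2:
                scenario.antibiotics = [("doxycycline", 1, "oral")] if d_max >= 1 else []

        if baseline_mode == "independent":
            if archetype in ("sepsis", "shock") and rng.random() < 0.5:
                scenario.admission_form_sepsis = True
            if rng.random() < 0.05:
                scenario.admission_diagnosis = "cholangitis"
            if rng.random() < 0.1:
                scenario.culture_hours = [float(rng.uniform(0.5, 5.5))]
        scenarios.append(scenario)

    spec = ScenarioSpec(
        admissions=scenarios, day_range=day_range, rng_seed=int(rng.integers(0, 2**31 - 1))
    )
    if baseline_mode in ("match", "anti"):
        rank_map = default_rank_map()
        shock = default_shock_criteria()
        for scenario in scenarios:
            _, _, s3 = _truth_for_admission(scenario, rank_map, shock, day_range)
            want = s3 if baseline_mode == "match" else not s3
            scenario.admission_form_sepsis = want
    return spec
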