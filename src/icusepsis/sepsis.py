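"""Sepsis-episode and septic-shock detection per 24 h window.

A sepsis episode in window ``d`` requires (i) an antibiotic escalation in
``d`` that is not prophylactic, and (ii) an acute rise in total SOFA of at
least two points between any ordered pair drawn from the previous, current
and subsequent windows.  Windows inside the computed day range with no
observations contribute a total of zero (the pre-admission zero assumption);
comparisons against windows outside the range are skipped.

Two prophylaxis rules suppress infection: SDD-only windows (see
:mod:`icusepsis.antibiotics`) and the elective-surgery rule — for admissions
after elective surgery (planned admission with surgical status), antibiotic
escalation accompanying admission (the earliest escalation in a window at or
before day 0) is prophylactic for that window and the subsequent one; any
later qualifying window still counts.

Post-admission windows with at least three missing SOFA components carry too
little information to adjudicate: sepsis is not identified there
(``sepsis_episode`` False in the output) and the window is marked
``indeterminate`` in the returned frame (not serialized).  Pre-admission
windows are exempt because their missing components are assumed zero.

Septic shock is the subset of sepsis windows with cardiovascular SOFA >= 3
(vasopressor support) and a worst-in-window lactate of at least 2 mmol/L.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .antibiotics import build_day_profiles, escalation_series, filter_sdd_prophylaxis
from .config import AntibioticRankMap, ShockCriteria, SofaThresholds
from .schema_io import EventStore, write_sepsis_table, write_sofa_table
from .sofa import daily_sofa

__all__ = [
    "delta_rule",
    "detect_sepsis",
    "detect_septic_shock",
    "run_pipeline",
]

MISSING_DISCARD = 3  # >= this many missing components discards identification


def delta_rule(totals: Mapping[int, int], day: int, day_range: tuple[int, int]) -> bool:
    """Acute-rise test: total SOFA increases by >= 2 across the day's neighbourhood.

    True iff ``S(d) - S(d-1) >= 2`` or ``S(d+1) - S(d-1) >= 2`` or
    ``S(d+1) - S(d) >= 2``, where days inside ``day_range`` missing from
    ``totals`` count 0 and clauses involving days outside the range are
    skipped.
    """
    d_min, d_max = day_range
    if not d_min <= day <= d_max:
        raise ValueError(f"day {day} outside computed range {day_range}")

    def total(d: int) -> int:
        return int(totals.get(d, 0))

    deltas = []
    if day - 1 >= d_min:
        deltas.append(total(day) - total(day - 1))
        if day + 1 <= d_max:
            deltas.append(total(day + 1) - total(day - 1))
    if day + 1 <= d_max:
        deltas.append(total(day + 1) - total(day))
    return any(delta >= 2 for delta in deltas)


def _is_elective_surgical(admission_row) -> bool:
    return (not bool(admission_row["urgency"])) and bool(admission_row["surgical"])


def _elective_span(escalation: Mapping[int, bool | None], elective: bool) -> set[int]:
    """Windows whose escalation is suppressed by the elective-surgery rule."""
    if not elective:
        return set()
    admission_escalations = [d for d, e in escalation.items() if e is True and d <= 0]
    if not admission_escalations:
        return set()
    d0 = min(admission_escalations)
    return {d0, d0 + 1}


def detect_sepsis(
    sofa_scores: pd.DataFrame,
    store: EventStore,
    rank_map: AntibioticRankMap,
    day_range: tuple[int, int],
) -> pd.DataFrame:
    """Combine SOFA trajectories and antibiotic escalation into per-window flags.

    Returns one row per window that has either a SOFA row or an antibiotic
    administration (plus day 0), with columns admissionid, time,
    sofa_total_score, antibiotic_escalation (ternary), prophylaxis, infection,
    sepsis_episode, septic_shock (False here; set by
    :func:`detect_septic_shock`) and indeterminate.
    """
    d_min, d_max = day_range
    in_range = store.events[(store.events["day"] >= d_min) & (store.events["day"] <= d_max)]
    retained, sdd_flags = filter_sdd_prophylaxis(in_range, rank_map)
    profiles, _unknown = build_day_profiles(retained, rank_map)
    sdd_only = {(row.admissionid, row.day) for row in sdd_flags.itertuples()}

    ab_events = store.events[
        (store.events["concept"] == "antibiotic")
        & (store.events["day"] >= d_min)
        & (store.events["day"] <= d_max)
    ]
    ab_days = ab_events.groupby("admissionid")["day"].apply(set).to_dict()

    sofa_by_adm: dict = {}
    for row in sofa_scores.itertuples():
        sofa_by_adm.setdefault(row.admissionid, {})[row.time] = (
            int(row.sofa_total_score),
            int(row.n_missing),
            row.sofa_cardiovascular_score,
        )

    rows = []
    for admission_row in store.admissions.itertuples():
        admission_id = admission_row.admissionid
        sofa_days = sofa_by_adm.get(admission_id, {})
        escalation = escalation_series(profiles, admission_id, day_range)
        span = _elective_span(escalation, _is_elective_surgical(admission_row._asdict()))
        totals = {d: v[0] for d, v in sofa_days.items()}
        row_days = sorted(set(sofa_days) | ab_days.get(admission_id, set()) | {0})
        for day in row_days:
            if not d_min <= day <= d_max:
                continue
            esc = escalation[day]
            prophylaxis = bool(
                (admission_id, day) in sdd_only or (esc is True and day in span)
            )
            infection = esc is True and not prophylaxis
            n_missing = sofa_days.get(day, (0, 6, None))[1]
            discard = day >= 0 and n_missing >= MISSING_DISCARD
            qualifies = infection and delta_rule(totals, day, day_range)
            rows.append(
                {
                    "admissionid": admission_id,
                    "time": int(day),
                    "sofa_total_score": int(totals.get(day, 0)),
                    "antibiotic_escalation": esc if esc is not None else np.nan,
                    "prophylaxis": prophylaxis,
                    "infection": bool(infection),
                    "sepsis_episode": bool(qualifies and not discard),
                    "septic_shock": False,
                    "indeterminate": bool(discard),
                }
            )

    columns = [
        "admissionid",
        "time",
        "sofa_total_score",
        "antibiotic_escalation",
        "prophylaxis",
        "infection",
        "sepsis_episode",
        "septic_shock",
        "indeterminate",
    ]
    df = pd.DataFrame(rows, columns=columns)
    return df.sort_values(["admissionid", "time"], kind="mergesort").reset_index(drop=True)


def detect_septic_shock(
    sepsis_flags: pd.DataFrame,
    sofa_scores: pd.DataFrame,
    store: EventStore,
    criteria: ShockCriteria,
) -> pd.DataFrame:
    """Set ``septic_shock`` on the subset of sepsis windows meeting shock criteria.

    Shock requires a cardiovascular SOFA score of at least
    ``criteria.cardiovascular_min_score`` (vasopressor support) and a maximum
    window lactate meeting ``criteria.lactate_threshold``; a missing
    cardiovascular score or missing lactate never qualifies.
    """
    cardio = {
        (row.admissionid, row.time): row.sofa_cardiovascular_score
        for row in sofa_scores.itertuples()
    }
    lact_events = store.events[store.events["concept"] == "lactate"].dropna(subset=["value"])
    lactate_max = lact_events.groupby(["admissionid", "day"])["value"].max().to_dict()

    out = sepsis_flags.copy()
    shock = []
    for row in out.itertuples():
        key = (row.admissionid, row.time)
        cv = cardio.get(key)
        lac = lactate_max.get(key)
        shock.append(
            bool(
                row.sepsis_episode
                and cv is not None
                and not pd.isna(cv)
                and int(cv) >= criteria.cardiovascular_min_score
                and lac is not None
                and criteria.lactate_meets(float(lac))
            )
        )
    out["septic_shock"] = shock
    return out


def run_pipeline(
    store: EventStore,
    thresholds: SofaThresholds,
    rank_map: AntibioticRankMap,
    shock_criteria: ShockCriteria,
    day_range: tuple[int, int] = (-1, 7),
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full pipeline: daily SOFA -> escalation -> sepsis/septic-shock flags.

    Returns ``(sofa_scores, sepsis_flags)``; if ``out_dir`` is given, also
    writes ``sofa.csv`` and ``sepsis.csv`` there in the canonical
    serialization.  Deterministic given inputs.
    """
    sofa_scores = daily_sofa(store, thresholds, day_range)
    flags = detect_sepsis(sofa_scores, store, rank_map, day_range)
    flags = detect_septic_shock(flags, sofa_scores, store, shock_criteria)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_sofa_table(sofa_scores, out_dir / "sofa.csv")
        write_sepsis_table(flags, out_dir / "sepsis.csv")
    return sofa_scores, flags
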