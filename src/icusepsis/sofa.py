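"""Daily SOFA scoring over 24 h windows.

Each of the six organ systems (respiration, coagulation, liver,
cardiovascular, central nervous system, renal) is scored 0-4 per
(admission, day) window from the *worst* value observed in that window:
minimum for PaO2/FiO2 ratio, platelets, mean arterial pressure, GCS and urine
output; maximum for bilirubin, creatinine and vasopressor dose.  A component
with no relevant observation in the window is missing; missing components
contribute 0 to the total (the pre-admission zero assumption extended to all
windows) and are counted in ``n_missing`` so that downstream sepsis logic can
discard windows with too little information.

Vasopressor use is inferred from the presence of a dose event, under the
assumption that vasopressors are only given to maintain a mean arterial
pressure of at least 65 mmHg: any dose event makes the cardiovascular score
at least 2, and the agent/dose rules decide 2-4.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .config import SofaThresholds
from .schema_io import EventStore

__all__ = [
    "COMPONENTS",
    "SOFA_INPUT_CONCEPTS",
    "AGG_DIRECTION",
    "worst_in_window",
    "window_aggregates",
    "score_component",
    "daily_sofa",
]

COMPONENTS = ("respiration", "coagulation", "liver", "cardiovascular", "cns", "renal")

_COMPONENT_COLUMN = {c: f"sofa_{c}_score" for c in COMPONENTS}

#: worst-in-window aggregation direction per numeric concept
AGG_DIRECTION: Mapping[str, str] = {
    "pao2": "min",
    "fio2": "max",
    "platelets": "min",
    "bilirubin": "max",
    "map": "min",
    "gcs": "min",
    "creatinine": "max",
    "urine_output": "min",
    "vasopressor": "max",
    "lactate": "max",
}

#: concepts whose presence makes a window a SOFA row
SOFA_INPUT_CONCEPTS = frozenset(
    {
        "pao2",
        "fio2",
        "platelets",
        "bilirubin",
        "map",
        "gcs",
        "creatinine",
        "urine_output",
        "vasopressor",
        "ventilated",
    }
)

_FALSY_TEXT = {"0", "0.0", "false", "no", "off"}


def worst_in_window(events: pd.DataFrame, concept: str, day: int, direction: str | None = None):
    """Extremum of ``concept`` values within window ``day``; None if no events."""
    if direction is None:
        direction = AGG_DIRECTION[concept]
    sel = events[(events["concept"] == concept) & (events["day"] == day)]["value"].dropna()
    if sel.empty:
        return None
    return float(sel.min() if direction == "min" else sel.max())


def _count_below(value: float, cutoffs) -> int:
    return int(sum(value < c for c in cutoffs))


def _count_at_least(value: float, bounds) -> int:
    return int(sum(value >= b for b in bounds))


def _normalize_fio2(value: float) -> float:
    # FiO2 recorded either as a fraction (0-1] or a percentage (1-100]
    return value / 100.0 if value > 1.0 else value


def window_aggregates(
    events: pd.DataFrame, thresholds: SofaThresholds
) -> dict:
    """Worst-in-window aggregates for one (admission, day) group of events.

    Returns a dict with the numeric concepts (value or None), ``ventilated``
    (bool) and ``vasopressors`` (agent class -> max dose in ug/kg/min).
    """
    agg: dict = {c: None for c in AGG_DIRECTION}
    numeric = events.dropna(subset=["value"])
    for concept, sub in numeric.groupby("concept"):
        if concept not in AGG_DIRECTION or concept == "vasopressor":
            continue
        vals = sub["value"]
        agg[concept] = float(vals.min() if AGG_DIRECTION[concept] == "min" else vals.max())

    vaso: dict[str, float] = {}
    vp = numeric[numeric["concept"] == "vasopressor"]
    for item, sub in vp.groupby("item"):
        klass = thresholds.vasopressor_classes.get(item, "other")
        dose = float(sub["value"].max())
        vaso[klass] = max(vaso.get(klass, 0.0), dose)
    agg["vasopressors"] = vaso

    vent = events[events["concept"] == "ventilated"]
    agg["ventilated"] = bool(
        len(vent) and (~vent["text"].astype(str).str.strip().str.casefold().isin(_FALSY_TEXT)).any()
    )
    return agg


def score_component(component: str, aggregates: Mapping, thresholds: SofaThresholds):
    """Score one SOFA component from worst-in-window aggregates.

    Returns an int 0-4, or None when every input the component needs is absent
    from the window.
    """
    if component == "respiration":
        pao2, fio2 = aggregates.get("pao2"), aggregates.get("fio2")
        if pao2 is None or fio2 is None:
            return None
        ratio = pao2 / _normalize_fio2(fio2)
        score = _count_below(ratio, thresholds.pf_cutoffs)
        if score >= thresholds.ventilation_required_from and not aggregates.get("ventilated"):
            score = thresholds.ventilation_required_from - 1
        return score

    if component == "coagulation":
        platelets = aggregates.get("platelets")
        return None if platelets is None else _count_below(platelets, thresholds.platelet_cutoffs)

    if component == "liver":
        bilirubin = aggregates.get("bilirubin")
        return None if bilirubin is None else _count_at_least(bilirubin, thresholds.bilirubin_bounds)

    if component == "cardiovascular":
        vaso = aggregates.get("vasopressors") or {}
        mean_ap = aggregates.get("map")
        if not vaso and mean_ap is None:
            return None
        if vaso:
            dop = vaso.get("dopamine")
            nor = max(
                (d for k, d in vaso.items() if k in ("norepinephrine", "epinephrine")),
                default=None,
            )
            if (dop is not None and dop > thresholds.dopamine_high) or (
                nor is not None and nor > thresholds.norepinephrine_cutoff
            ):
                return 4
            if (dop is not None and dop > thresholds.dopamine_low) or nor is not None:
                return 3
            return 2
        return 1 if mean_ap < thresholds.hypotension_map else 0

    if component == "cns":
        gcs = aggregates.get("gcs")
        return None if gcs is None else _count_below(gcs, thresholds.gcs_cutoffs)

    if component == "renal":
        creatinine = aggregates.get("creatinine")
        urine = aggregates.get("urine_output")
        if creatinine is None and urine is None:
            return None
        score = 0
        if creatinine is not None:
            score = _count_at_least(creatinine, thresholds.creatinine_bounds)
        if urine is not None:
            if urine < thresholds.urine_very_low:
                score = max(score, 4)
            elif urine < thresholds.urine_low:
                score = max(score, 3)
        return score

    raise ValueError(f"unknown SOFA component {component!r}")


def daily_sofa(
    store: EventStore,
    thresholds: SofaThresholds,
    day_range: tuple[int, int],
) -> pd.DataFrame:
    """Per-(admission, day) SOFA component and total scores.

    One row per window inside ``day_range`` that contains at least one
    SOFA-relevant event, plus day 0 for every admission.  The total is the sum
    of the non-missing components; ``n_missing`` counts missing components.
    """
    d_min, d_max = day_range
    if not d_min <= 0 <= d_max:
        raise ValueError(f"day range must contain 0, got {day_range!r}")

    events = store.events
    relevant = events[
        events["concept"].isin(SOFA_INPUT_CONCEPTS)
        & (events["day"] >= d_min)
        & (events["day"] <= d_max)
    ]
    grouped = {key: sub for key, sub in relevant.groupby(["admissionid", "day"], sort=False)}

    empty = relevant.iloc[0:0]
    rows = []
    for admission_id in store.admission_ids():
        days = sorted({d for (a, d) in grouped if a == admission_id} | {0})
        for day in days:
            agg = window_aggregates(grouped.get((admission_id, day), empty), thresholds)
            scores = {c: score_component(c, agg, thresholds) for c in COMPONENTS}
            row = {"admissionid": admission_id, "time": int(day)}
            row.update({_COMPONENT_COLUMN[c]: scores[c] for c in COMPONENTS})
            row["sofa_total_score"] = int(sum(s for s in scores.values() if s is not None))
            row["n_missing"] = int(sum(s is None for s in scores.values()))
            rows.append(row)

    columns = ["admissionid", "time", *(_COMPONENT_COLUMN[c] for c in COMPONENTS),
               "sofa_total_score", "n_missing"]
    df = pd.DataFrame(rows, columns=columns)
    for c in COMPONENTS:
        df[_COMPONENT_COLUMN[c]] = df[_COMPONENT_COLUMN[c]].astype("Int64")
    return df.sort_values(["admissionid", "time"], kind="mergesort").reset_index(drop=True)
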