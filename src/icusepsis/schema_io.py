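"""Relational data model, CSV readers/writers and 24 h windowing.

The pipeline works directly on long-format CSV tables shaped like the
AmsterdamUMCdb exports: an ``admissions`` table plus timestamped event tables
(``drugitems``, ``numericitems``, ``listitems``).  All timestamps are integer
milliseconds relative to the admission instant, so day ``d`` is the half-open
interval ``[d*24h, (d+1)*24h)`` and may be negative for events recorded before
ICU admission (emergency department, operating room).

Output tables use a fixed serialization: comma-separated, UTF-8, header row,
``NaN`` for missing cells and ``True``/``False`` for booleans, sorted by
(admissionid, time).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .config import ConceptMap, NUMERIC_CONCEPTS, normalize_name

__all__ = [
    "MS_PER_DAY",
    "SOFA_COLUMNS",
    "SEPSIS_COLUMNS",
    "SchemaError",
    "EventStore",
    "assign_window",
    "read_tables",
    "write_sofa_table",
    "write_sepsis_table",
    "read_sofa_table",
    "read_sepsis_table",
]

logger = logging.getLogger(__name__)

MS_PER_DAY = 86_400_000

SOFA_COLUMNS = [
    "admissionid",
    "time",
    "sofa_respiration_score",
    "sofa_coagulation_score",
    "sofa_liver_score",
    "sofa_cardiovascular_score",
    "sofa_cns_score",
    "sofa_renal_score",
    "sofa_total_score",
]

SEPSIS_COLUMNS = [
    "admissionid",
    "time",
    "sofa_total_score",
    "antibiotic_escalation",
    "prophylaxis",
    "infection",
    "sepsis_episode",
    "septic_shock",
]

_ADMISSION_COLUMNS = [
    "admissionid",
    "patientid",
    "admittedat",
    "urgency",
    "surgical",
    "location",
    "is_first_admission",
]

_EVENT_COLUMNS = ["admissionid", "concept", "item", "value", "text", "route", "measuredat", "day"]

_REQUIRED = {
    "admissions": _ADMISSION_COLUMNS,
    "drugitems": ["admissionid", "item", "start", "route", "dose"],
    "numericitems": ["admissionid", "item", "value", "unit", "measuredat"],
    "listitems": ["admissionid", "item", "value", "measuredat"],
}

_IV_ALIASES = {"iv", "i.v.", "intravenous", "intraveneus"}
_ORAL_ALIASES = {"oral", "po", "p.o.", "or", "enteral"}


class SchemaError(ValueError):
    """A table is missing a required column or violates an invariant."""


def assign_window(measured_at):
    """Map a millisecond offset (scalar or array) to its signed day index.

    Windows are half-open: day ``d`` covers ``[d*24h, (d+1)*24h)``; floor
    division gives the correct negative day for pre-admission offsets.
    """
    if np.isscalar(measured_at):
        return int(measured_at // MS_PER_DAY)
    return np.asarray(measured_at) // MS_PER_DAY


def normalize_route(route) -> str:
    if route is None or (isinstance(route, float) and np.isnan(route)):
        return "na"
    r = str(route).strip().casefold()
    if r in ("", "nan", "na", "n/a"):
        return "na"
    if r in _IV_ALIASES:
        return "iv"
    if r in _ORAL_ALIASES:
        return "oral"
    return "other"


@dataclass
class EventStore:
    """Validated admissions table plus a single concept-level event table.

    ``events`` columns: admissionid, concept, item (normalized), value (float,
    NaN when non-numeric), text (string payload for list/choice items), route
    (iv/oral/other/na), measuredat (int ms relative to admission), day (int).
    """

    admissions: pd.DataFrame
    events: pd.DataFrame
    dropped_unmapped: Mapping[str, int] = field(default_factory=dict)

    def events_for(self, concept: str | None = None) -> pd.DataFrame:
        if concept is None:
            return self.events
        return self.events[self.events["concept"] == concept]

    def admission_ids(self) -> list:
        return list(self.admissions["admissionid"])


def _require_columns(table: str, df: pd.DataFrame, columns: list[str]) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"table {table!r} is missing required column(s): {', '.join(missing)}")


def _parse_timestamps(table: str, raw: pd.Series) -> pd.Series:
    ts = pd.to_numeric(raw, errors="coerce")
    bad = ts.isna() & raw.notna()
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"table {table!r}: unparseable timestamp {raw.iloc[idx]!r} at row {raw.index[idx]}"
        )
    if ts.isna().any():
        idx = int(np.flatnonzero(ts.isna().to_numpy())[0])
        raise SchemaError(f"table {table!r}: missing timestamp at row {ts.index[idx]}")
    return ts.astype(np.int64)


def _to_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False, "t": True, "f": False,
    }
    out = series.astype(str).str.strip().str.casefold().map(mapping)
    if out.isna().any():
        raise SchemaError(f"cannot interpret value {series[out.isna()].iloc[0]!r} as boolean")
    return out.astype(bool)


def _map_items(table: str, df: pd.DataFrame, concept_map: ConceptMap) -> tuple[pd.DataFrame, int]:
    """Attach the concept column; drop (and count) rows with unmapped items."""
    norm = df["item"].map(normalize_name)
    concept = norm.map(getattr(concept_map, table))
    keep = concept.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        unknown = sorted(norm[~keep].unique())
        logger.warning(
            "table %r: dropped %d row(s) whose item is absent from the concept map: %s",
            table, n_dropped, ", ".join(unknown[:10]),
        )
    out = df.loc[keep].copy()
    out["item"] = norm[keep]
    out["concept"] = concept[keep]
    return out, n_dropped


def read_tables(paths: Mapping[str, str | Path], concept_map: ConceptMap) -> EventStore:
    """Read and validate the four input CSV tables into an :class:`EventStore`.

    ``paths`` maps table names (``admissions`` required; ``drugitems``,
    ``numericitems``, ``listitems`` optional) to file paths.  Event rows whose
    item is not in the concept map are dropped with a logged count; an event
    referencing an unknown admission is a referential-integrity error.
    """
    if "admissions" not in paths:
        raise SchemaError("an 'admissions' table is required")
    adm = pd.read_csv(paths["admissions"])
    _require_columns("admissions", adm, _ADMISSION_COLUMNS)
    if adm["admissionid"].duplicated().any():
        dup = adm.loc[adm["admissionid"].duplicated(), "admissionid"].iloc[0]
        raise SchemaError(f"duplicate admissionid {dup!r} in admissions table")
    adm = adm.copy()
    for col in ("urgency", "surgical", "is_first_admission"):
        adm[col] = _to_bool(adm[col])
    first_per_patient = adm.groupby("patientid")["is_first_admission"].sum()
    if len(adm) and not (first_per_patient == 1).all():
        bad = first_per_patient[first_per_patient != 1].index[0]
        raise SchemaError(
            f"patient {bad!r} must have exactly one admission flagged is_first_admission"
        )
    known_ids = set(adm["admissionid"])

    frames: list[pd.DataFrame] = []
    dropped: dict[str, int] = {}

    if "drugitems" in paths:
        drugs = pd.read_csv(paths["drugitems"])
        _require_columns("drugitems", drugs, _REQUIRED["drugitems"])
        drugs, dropped["drugitems"] = _map_items("drugitems", drugs, concept_map)
        if len(drugs):
            frames.append(
                pd.DataFrame(
                    {
                        "admissionid": drugs["admissionid"],
                        "concept": drugs["concept"],
                        "item": drugs["item"],
                        "value": pd.to_numeric(drugs["dose"], errors="coerce"),
                        "text": drugs["item"],
                        "route": drugs["route"].map(normalize_route),
                        "measuredat": _parse_timestamps("drugitems", drugs["start"]),
                    }
                )
            )

    if "numericitems" in paths:
        nums = pd.read_csv(paths["numericitems"])
        _require_columns("numericitems", nums, _REQUIRED["numericitems"])
        unit_series = nums["unit"].astype(str)
        nums, dropped["numericitems"] = _map_items("numericitems", nums, concept_map)
        if len(nums):
            missing_unit = unit_series.loc[nums.index].str.strip().isin(("", "nan"))
            if missing_unit.any():
                raise SchemaError(
                    f"table 'numericitems': empty unit at row {nums.index[missing_unit][0]}"
                )
            frames.append(
                pd.DataFrame(
                    {
                        "admissionid": nums["admissionid"],
                        "concept": nums["concept"],
                        "item": nums["item"],
                        "value": pd.to_numeric(nums["value"], errors="coerce"),
                        "text": nums["value"].astype(str),
                        "route": "na",
                        "measuredat": _parse_timestamps("numericitems", nums["measuredat"]),
                    }
                )
            )

    if "listitems" in paths:
        lists = pd.read_csv(paths["listitems"])
        _require_columns("listitems", lists, _REQUIRED["listitems"])
        lists, dropped["listitems"] = _map_items("listitems", lists, concept_map)
        if len(lists):
            frames.append(
                pd.DataFrame(
                    {
                        "admissionid": lists["admissionid"],
                        "concept": lists["concept"],
                        "item": lists["item"],
                        "value": pd.to_numeric(lists["value"], errors="coerce"),
                        "text": lists["value"].astype(str),
                        "route": "na",
                        "measuredat": _parse_timestamps("listitems", lists["measuredat"]),
                    }
                )
            )

    if frames:
        events = pd.concat(frames, ignore_index=True)
    else:
        events = pd.DataFrame(columns=_EVENT_COLUMNS[:-1])
        events["measuredat"] = events.get("measuredat", pd.Series(dtype=np.int64))

    if len(events):
        unknown = ~events["admissionid"].isin(known_ids)
        if unknown.any():
            bad = events.loc[unknown, "admissionid"].iloc[0]
            raise SchemaError(f"event references unknown admissionid {bad!r}")
        events["measuredat"] = events["measuredat"].astype(np.int64)
        events["day"] = assign_window(events["measuredat"].to_numpy()).astype(np.int64)
    else:
        events["day"] = pd.Series(dtype=np.int64)

    events = events.reset_index(drop=True)
    return EventStore(admissions=adm, events=events[_EVENT_COLUMNS], dropped_unmapped=dropped)


def _write_csv(df: pd.DataFrame, columns: list[str], path: str | Path) -> None:
    out = df[columns].sort_values(["admissionid", "time"], kind="mergesort")
    out.to_csv(path, index=False, na_rep="NaN")


def write_sofa_table(scores: pd.DataFrame, path: str | Path) -> None:
    """Write the per-window SOFA table (component + total scores) as CSV.

    Missing component scores serialize as literal ``NaN``; rows are sorted by
    (admissionid, time).
    """
    df = scores.copy()
    if len(df) == 0:
        df = pd.DataFrame(columns=SOFA_COLUMNS)
    for col in SOFA_COLUMNS[2:8]:
        df[col] = df[col].astype("Int64")
    df["sofa_total_score"] = df["sofa_total_score"].astype(int) if len(df) else df.get(
        "sofa_total_score", pd.Series(dtype=int)
    )
    _write_csv(df, SOFA_COLUMNS, path)


def write_sepsis_table(flags: pd.DataFrame, path: str | Path) -> None:
    """Write the per-window sepsis table as CSV.

    ``antibiotic_escalation`` is ternary: ``True``/``False`` when a
    determination was made, ``NaN`` for windows without any antibiotic
    administration.  The remaining indicator columns are strict booleans.
    """
    df = flags.copy()
    if len(df) == 0:
        df = pd.DataFrame(columns=SEPSIS_COLUMNS)
    else:
        df["sofa_total_score"] = df["sofa_total_score"].astype(int)
        for col in ("prophylaxis", "infection", "sepsis_episode", "septic_shock"):
            df[col] = df[col].astype(bool)
        df["antibiotic_escalation"] = df["antibiotic_escalation"].astype(object)
    _write_csv(df, SEPSIS_COLUMNS, path)


def _read_bool_column(series: pd.Series, ternary: bool) -> pd.Series:
    mapping = {"True": True, "False": False}
    out = series.map(lambda v: mapping.get(v, v) if isinstance(v, str) else v)
    if not ternary and out.isna().any():
        raise SchemaError("unexpected NaN in strict boolean column")
    return out.astype(object) if ternary else out.astype(bool)


def read_sofa_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns("sofa", df, SOFA_COLUMNS)
    for col in SOFA_COLUMNS[2:8]:
        df[col] = df[col].astype("Int64")
    if len(df):
        df["sofa_total_score"] = df["sofa_total_score"].astype(int)
    return df[SOFA_COLUMNS]


def read_sepsis_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns("sepsis", df, SEPSIS_COLUMNS)
    if len(df):
        df["antibiotic_escalation"] = _read_bool_column(
            df["antibiotic_escalation"].astype(object).where(df["antibiotic_escalation"].notna()),
            ternary=True,
        )
        for col in ("prophylaxis", "infection", "sepsis_episode", "septic_shock"):
            df[col] = _read_bool_column(df[col], ternary=False)
        df["sofa_total_score"] = df["sofa_total_score"].astype(int)
    return df[SEPSIS_COLUMNS]
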