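"""Configuration objects: SOFA thresholds, shock criteria, antibiotic ranks, concept map.

Everything that is site- or database-specific (laboratory units, cut-off
values, the antibiotic formulary and its escalation ranks, the mapping from
raw item identifiers to clinical concepts) is data loaded from YAML, with
documented defaults shipped in :mod:`icusepsis.data`.  The algorithms in the
other modules only ever see these dataclasses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "SofaThresholds",
    "ShockCriteria",
    "AntibioticRankMap",
    "ConceptMap",
    "normalize_name",
    "default_thresholds",
    "default_shock_criteria",
    "default_rank_map",
    "default_concept_map",
]

_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Canonical form of a drug/item name: case-folded, whitespace-collapsed."""
    return _WS.sub(" ", str(name).strip().casefold())


def _read_yaml(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def _packaged_yaml(name: str) -> dict:
    with resources.files("icusepsis.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def _check_monotone(name: str, seq, decreasing: bool) -> None:
    pairs = zip(seq, seq[1:])
    ok = all(a > b for a, b in pairs) if decreasing else all(a < b for a, b in zip(seq, seq[1:]))
    if len(seq) != 4 or not ok:
        raise ValueError(f"{name}: expected 4 strictly monotone cut-offs, got {seq!r}")


@dataclass(frozen=True)
class SofaThresholds:
    """Cut-offs for the six SOFA components.

    Score-band conventions (shared with the synthetic generator, which inverts
    them to plant raw values):

    * "low is bad" inputs (PaO2/FiO2, platelets, GCS) use four *descending*
      cut-offs; the score is the number of cut-offs the value falls strictly
      below.
    * "high is bad" inputs (bilirubin, creatinine) use four *ascending* band
      lower bounds; the score is the number of bounds the value reaches.
    * cardiovascular and renal additionally apply the vasopressor-dose and
      urine-output rules.
    """

    pf_cutoffs: tuple[float, ...] = (53.3, 40.0, 26.7, 13.3)
    pf_unit: str = "kPa"
    ventilation_required_from: int = 3
    platelet_cutoffs: tuple[float, ...] = (150.0, 100.0, 50.0, 20.0)
    bilirubin_bounds: tuple[float, ...] = (20.0, 33.0, 102.0, 205.0)
    hypotension_map: float = 70.0
    dopamine_low: float = 5.0
    dopamine_high: float = 15.0
    norepinephrine_cutoff: float = 0.1
    vasopressor_classes: Mapping[str, str] = field(
        default_factory=lambda: {
            "dopamine": "dopamine",
            "dobutamine": "dobutamine",
            "norepinephrine": "norepinephrine",
            "noradrenaline": "norepinephrine",
            "epinephrine": "epinephrine",
            "adrenaline": "epinephrine",
        }
    )
    gcs_cutoffs: tuple[float, ...] = (15, 13, 10, 6)
    creatinine_bounds: tuple[float, ...] = (110.0, 171.0, 300.0, 441.0)
    urine_low: float = 500.0
    urine_very_low: float = 200.0

    def __post_init__(self) -> None:
        _check_monotone("pf_cutoffs", self.pf_cutoffs, decreasing=True)
        _check_monotone("platelet_cutoffs", self.platelet_cutoffs, decreasing=True)
        _check_monotone("gcs_cutoffs", self.gcs_cutoffs, decreasing=True)
        _check_monotone("bilirubin_bounds", self.bilirubin_bounds, decreasing=False)
        _check_monotone("creatinine_bounds", self.creatinine_bounds, decreasing=False)
        if not 0 < self.urine_very_low < self.urine_low:
            raise ValueError("urine cut-offs must satisfy 0 < very_low < low")

    @classmethod
    def from_dict(cls, raw: dict) -> "SofaThresholds":
        resp = raw.get("respiration", {})
        coag = raw.get("coagulation", {})
        liver = raw.get("liver", {})
        cardio = raw.get("cardiovascular", {})
        cns = raw.get("cns", {})
        renal = raw.get("renal", {})
        kw = {}
        if "pf_cutoffs" in resp:
            kw["pf_cutoffs"] = tuple(resp["pf_cutoffs"])
        if "unit" in resp:
            kw["pf_unit"] = resp["unit"]
        if "ventilation_required_from" in resp:
            kw["ventilation_required_from"] = int(resp["ventilation_required_from"])
        if "platelet_cutoffs" in coag:
            kw["platelet_cutoffs"] = tuple(coag["platelet_cutoffs"])
        if "bilirubin_bounds" in liver:
            kw["bilirubin_bounds"] = tuple(liver["bilirubin_bounds"])
        for src, dst in [
            ("hypotension_map", "hypotension_map"),
            ("dopamine_low", "dopamine_low"),
            ("dopamine_high", "dopamine_high"),
            ("norepinephrine_cutoff", "norepinephrine_cutoff"),
        ]:
            if src in cardio:
                kw[dst] = float(cardio[src])
        if "vasopressor_classes" in cardio:
            kw["vasopressor_classes"] = {
                normalize_name(k): v for k, v in cardio["vasopressor_classes"].items()
            }
        if "gcs_cutoffs" in cns:
            kw["gcs_cutoffs"] = tuple(cns["gcs_cutoffs"])
        if "creatinine_bounds" in renal:
            kw["creatinine_bounds"] = tuple(renal["creatinine_bounds"])
        if "urine_low" in renal:
            kw["urine_low"] = float(renal["urine_low"])
        if "urine_very_low" in renal:
            kw["urine_very_low"] = float(renal["urine_very_low"])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SofaThresholds":
        return cls.from_dict(_read_yaml(path))


@dataclass(frozen=True)
class ShockCriteria:
    """Septic-shock criteria: vasopressor support plus hyperlactataemia.

    ``map_target`` (mmHg) records the pressure vasopressors are assumed to be
    titrated to; it documents the vasopressor-use assumption rather than
    entering the score arithmetic.
    """

    cardiovascular_min_score: int = 3
    lactate_threshold: float = 2.0
    lactate_comparator: str = "ge"  # "ge" or "gt"
    map_target: float = 65.0

    def __post_init__(self) -> None:
        if self.lactate_threshold <= 0 or self.map_target <= 0:
            raise ValueError("shock thresholds must be strictly positive")
        if self.lactate_comparator not in ("ge", "gt"):
            raise ValueError("lactate_comparator must be 'ge' or 'gt'")

    def lactate_meets(self, value: float) -> bool:
        if self.lactate_comparator == "ge":
            return value >= self.lactate_threshold
        return value > self.lactate_threshold

    @classmethod
    def from_dict(cls, raw: dict) -> "ShockCriteria":
        shock = raw.get("shock", raw)
        kw = {}
        if "cardiovascular_min_score" in shock:
            kw["cardiovascular_min_score"] = int(shock["cardiovascular_min_score"])
        if "lactate_threshold" in shock:
            kw["lactate_threshold"] = float(shock["lactate_threshold"])
        if "lactate_comparator" in shock:
            kw["lactate_comparator"] = shock["lactate_comparator"]
        if "map_target" in shock:
            kw["map_target"] = float(shock["map_target"])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ShockCriteria":
        return cls.from_dict(_read_yaml(path))


@dataclass(frozen=True)
class AntibioticRankMap:
    """Antibiotic name -> escalation rank, with synonym table and SDD policy.

    Ranks order agents from narrow (1) to reserve (4); the escalation rule
    compares the maximum rank in consecutive windows.  ``sdd_drugs`` are the
    routine decontamination agents ignored within ``sdd_days`` post-admission
    windows.
    """

    ranks: Mapping[str, int]
    synonyms: Mapping[str, str] = field(default_factory=dict)
    sdd_drugs: frozenset[str] = frozenset()
    sdd_days: frozenset[int] = frozenset({0, 1, 2, 3})

    def __post_init__(self) -> None:
        for name, rank in self.ranks.items():
            if int(rank) < 1:
                raise ValueError(f"rank for {name!r} must be a positive integer")

    def resolve(self, name: str) -> tuple[str, int | None]:
        """Return (canonical name, rank) for a raw drug name; rank None if unknown."""
        canon = normalize_name(name)
        canon = self.synonyms.get(canon, canon)
        rank = self.ranks.get(canon)
        return canon, (int(rank) if rank is not None else None)

    def is_sdd_drug(self, name: str) -> bool:
        canon, _ = self.resolve(name)
        return canon in self.sdd_drugs

    @classmethod
    def from_dict(cls, raw: dict) -> "AntibioticRankMap":
        ranks = {normalize_name(k): int(v) for k, v in raw.get("ranks", {}).items()}
        synonyms = {
            normalize_name(k): normalize_name(v) for k, v in (raw.get("synonyms") or {}).items()
        }
        sdd = raw.get("sdd") or {}
        return cls(
            ranks=ranks,
            synonyms=synonyms,
            sdd_drugs=frozenset(normalize_name(d) for d in sdd.get("drugs", [])),
            sdd_days=frozenset(int(d) for d in sdd.get("days", [0, 1, 2, 3])),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AntibioticRankMap":
        return cls.from_dict(_read_yaml(path))


#: Concepts whose events must carry a numeric value and a non-empty unit.
NUMERIC_CONCEPTS = frozenset(
    {
        "pao2",
        "fio2",
        "platelets",
        "bilirubin",
        "map",
        "gcs",
        "creatinine",
        "urine_output",
        "lactate",
        "vasopressor",
    }
)

KNOWN_CONCEPTS = NUMERIC_CONCEPTS | {
    "ventilated",
    "antibiotic",
    "culture_drawn",
    "admission_form_sepsis_flag",
    "admission_diagnosis",
}


@dataclass(frozen=True)
class ConceptMap:
    """Per-table mapping of raw item names/identifiers to clinical concepts."""

    numericitems: Mapping[str, str]
    drugitems: Mapping[str, str]
    listitems: Mapping[str, str]

    def lookup(self, table: str, item: str) -> str | None:
        return getattr(self, table).get(normalize_name(item))

    @classmethod
    def from_dict(cls, raw: dict) -> "ConceptMap":
        def build(section: str) -> dict[str, str]:
            out = {}
            for item, entry in (raw.get(section) or {}).items():
                concept = entry["concept"] if isinstance(entry, dict) else str(entry)
                if concept not in KNOWN_CONCEPTS:
                    raise ValueError(f"unknown concept {concept!r} for item {item!r}")
                out[normalize_name(item)] = concept
            return out

        return cls(
            numericitems=build("numericitems"),
            drugitems=build("drugitems"),
            listitems=build("listitems"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ConceptMap":
        return cls.from_dict(_read_yaml(path))


def default_thresholds() -> SofaThresholds:
    return SofaThresholds.from_dict(_packaged_yaml("sofa_thresholds.yaml"))


def default_shock_criteria() -> ShockCriteria:
    return ShockCriteria.from_dict(_packaged_yaml("sofa_thresholds.yaml"))


def default_rank_map() -> AntibioticRankMap:
    return AntibioticRankMap.from_dict(_packaged_yaml("antibiotic_ranks.yaml"))


def default_concept_map() -> ConceptMap:
    return ConceptMap.from_dict(_packaged_yaml("concepts.yaml"))
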