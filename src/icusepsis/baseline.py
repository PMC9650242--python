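"""The pre-existing admission-sepsis criteria and their comparison to Sepsis-3.

The legacy AmsterdamUMCdb scripts label an admission as septic *at admission*
if any of four criteria holds: (1) sepsis flagged on the admission form,
(2) an admission diagnosis considered a severe infection, (3) non-prophylactic
antibiotic use after surgery, (4) antibiotics given and cultures drawn within
a few hours of admission.  These are admission-centric and take no account of
organ dysfunction, so they disagree substantially with Sepsis-3; this module
reproduces the comparison as a confusion matrix over unique first admissions,
with Sepsis-3 (a sepsis episode in the 24 h window before or after admission)
as the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .antibiotics import escalation_series, filter_sdd_prophylaxis, build_day_profiles
from .config import AntibioticRankMap, normalize_name
from .schema_io import EventStore
from .sepsis import MISSING_DISCARD, _elective_span, _is_elective_surgical

__all__ = [
    "BaselineCriteriaConfig",
    "ConfusionMatrix",
    "baseline_sepsis_at_admission",
    "sepsis3_at_admission",
    "confusion_matrix",
    "compare_cohort",
]

_TRUTHY = {"1", "1.0", "true", "yes", "y"}


@dataclass(frozen=True)
class BaselineCriteriaConfig:
    """Configuration for the legacy admission-sepsis criteria."""

    severe_infection_diagnoses: frozenset[str] = frozenset(
        {"gastrointestinal perforation", "cholangitis", "meningitis"}
    )
    culture_window_hours: float = 6.0
    post_surgery_antibiotic_rule: bool = True

    def __post_init__(self) -> None:
        if self.culture_window_hours <= 0:
            raise ValueError("culture window must be positive")
        object.__setattr__(
            self,
            "severe_infection_diagnoses",
            frozenset(normalize_name(d) for d in self.severe_infection_diagnoses),
        )


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with Sepsis-3 as reference (rows) vs legacy criteria (columns)."""

    tt: int
    tf: int
    ft: int
    ff: int

    @property
    def n(self) -> int:
        return self.tt + self.tf + self.ft + self.ff

    @property
    def sensitivity(self) -> float | None:
        denom = self.tt + self.tf
        return self.tt / denom if denom else None

    @property
    def specificity(self) -> float | None:
        denom = self.ff + self.ft
        return self.ff / denom if denom else None


def _truthy_text(text) -> bool:
    return str(text).strip().casefold() in _TRUTHY


def baseline_sepsis_at_admission(
    store: EventStore,
    admission_id,
    rank_map: AntibioticRankMap,
    config: BaselineCriteriaConfig = BaselineCriteriaConfig(),
) -> bool:
    """Legacy admission-sepsis label: the disjunction of the four criteria."""
    adm_rows = store.admissions[store.admissions["admissionid"] == admission_id]
    if adm_rows.empty:
        raise KeyError(f"admission {admission_id!r} not in store")
    admission = adm_rows.iloc[0]
    events = store.events[store.events["admissionid"] == admission_id]

    # 1. sepsis flagged on the admission form
    flags = events[events["concept"] == "admission_form_sepsis_flag"]
    if len(flags) and flags["text"].map(_truthy_text).any():
        return True

    # 2. admission diagnosis is a severe infection
    diagnoses = events[events["concept"] == "admission_diagnosis"]
    if len(diagnoses) and (
        diagnoses["text"].map(normalize_name).isin(config.severe_infection_diagnoses).any()
    ):
        return True

    # 3. non-prophylactic antibiotics after surgery (first post-admission window),
    #    reusing the SDD and elective-surgery prophylaxis rules
    if config.post_surgery_antibiotic_rule and bool(admission["surgical"]):
        ab_day0 = events[(events["concept"] == "antibiotic") & (events["day"] == 0)]
        if len(ab_day0):
            retained, sdd_flags = filter_sdd_prophylaxis(events, rank_map)
            sdd_only = {(r.admissionid, r.day) for r in sdd_flags.itertuples()}
            profiles, _ = build_day_profiles(retained, rank_map)
            escalation = escalation_series(profiles, admission_id, (-1, 1))
            span = _elective_span(escalation, _is_elective_surgical(admission))
            # day-0 use is prophylactic if SDD-only or covered by the
            # elective-surgery span, whether or not day 0 itself escalated
            prophylactic = (admission_id, 0) in sdd_only or 0 in span
            if not prophylactic:
                return True

    # 4. antibiotics and cultures drawn within the culture window of admission
    horizon = int(config.culture_window_hours * 3_600_000)
    in_window = (events["measuredat"] >= 0) & (events["measuredat"] <= horizon)
    early = events[in_window]
    if (early["concept"] == "antibiotic").any() and (early["concept"] == "culture_drawn").any():
        return True

    return False


def sepsis3_at_admission(sepsis_flags: pd.DataFrame, admission_id) -> bool:
    """Sepsis-3 label at admission: an episode in the window before or after."""
    sub = sepsis_flags[
        (sepsis_flags["admissionid"] == admission_id) & sepsis_flags["time"].isin([-1, 0])
    ]
    return bool(sub["sepsis_episode"].any())


def confusion_matrix(pairs) -> ConfusionMatrix:
    """Tally (sepsis3, baseline) boolean pairs into a 2x2 confusion matrix."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("cannot build a confusion matrix from zero admissions")
    tt = sum(1 for s3, base in pairs if s3 and base)
    tf = sum(1 for s3, base in pairs if s3 and not base)
    ft = sum(1 for s3, base in pairs if not s3 and base)
    ff = sum(1 for s3, base in pairs if not s3 and not base)
    return ConfusionMatrix(tt=tt, tf=tf, ft=ft, ff=ff)


def compare_cohort(
    store: EventStore,
    sofa_scores: pd.DataFrame,
    sepsis_flags: pd.DataFrame,
    rank_map: AntibioticRankMap,
    config: BaselineCriteriaConfig = BaselineCriteriaConfig(),
    first_admissions_only: bool = True,
) -> tuple[ConfusionMatrix, pd.DataFrame]:
    """Per-admission comparison of Sepsis-3 vs the legacy criteria.

    Restricted to unique first admissions (optionally) with a determinable
    Sepsis-3 label: the admission window (day 0) must have fewer than three
    missing SOFA components.  Returns the matrix and the per-admission label
    frame.
    """
    n_missing_day0 = {
        row.admissionid: int(row.n_missing)
        for row in sofa_scores[sofa_scores["time"] == 0].itertuples()
    }
    admissions = store.admissions
    if first_admissions_only:
        admissions = admissions[admissions["is_first_admission"]]

    records = []
    for admission_id in admissions["admissionid"]:
        if n_missing_day0.get(admission_id, 6) >= MISSING_DISCARD:
            continue  # Sepsis-3 label not determinable at admission
        records.append(
            {
                "admissionid": admission_id,
                "sepsis3": sepsis3_at_admission(sepsis_flags, admission_id),
                "baseline": baseline_sepsis_at_admission(store, admission_id, rank_map, config),
            }
        )
    labels = pd.DataFrame(records, columns=["admissionid", "sepsis3", "baseline"])
    matrix = confusion_matrix(zip(labels["sepsis3"], labels["baseline"]))
    return matrix, labels
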