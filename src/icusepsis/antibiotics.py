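"""Antibiotic escalation detection: the proxy for suspected infection.

Each antibiotic administration is resolved against a configurable formulary
that assigns every agent an escalation rank (1 = narrow spectrum ... 4 =
reserve).  For every (admission, day) window the regimen is summarised as the
set of distinct agents with their ranks and routes; *escalation* in window
``d`` means the maximum rank increased relative to window ``d-1`` (or, at an
unchanged maximum rank, the number of distinct agents at that rank
increased), provided at least one agent that day was given intravenously.
Starting any IV antibiotic from an antibiotic-free day counts as an
escalation.  A window with no (non-excluded) administrations yields no
determination (``None``, serialized as ``NaN``).

Routine selective-digestive-decontamination (SDD) agents — cefotaxime in the
default configuration — are excluded from escalation input during the first
four post-admission windows, because the standard Amsterdam UMC procedure
administers them to essentially every admission; a window whose only
administrations are excluded is flagged as prophylaxis.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import AntibioticRankMap

__all__ = [
    "AntibioticDayProfile",
    "filter_sdd_prophylaxis",
    "build_day_profiles",
    "detect_escalation",
    "escalation_series",
]


@dataclass(frozen=True)
class AntibioticDayProfile:
    """The antibiotic regimen of one (admission, day) window."""

    admission_id: object
    day: int
    agents: frozenset  # of (canonical name, rank, route)

    @property
    def max_rank(self) -> int | None:
        return max((r for _, r, _ in self.agents), default=None)

    @property
    def n_at_max(self) -> int:
        m = self.max_rank
        if m is None:
            return 0
        return len({name for name, r, _ in self.agents if r == m})

    @property
    def any_iv(self) -> bool:
        return any(route == "iv" for _, _, route in self.agents)


def filter_sdd_prophylaxis(
    drug_events: pd.DataFrame, rank_map: AntibioticRankMap
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split antibiotic events into escalation input and SDD prophylaxis.

    Returns ``(retained_events, sdd_flags)`` where ``sdd_flags`` has one row
    per (admissionid, day) window whose *only* administrations were excluded
    SDD doses (``prophylaxis`` True).  Exclusion applies to SDD drugs in the
    configured post-admission windows only; the same agent outside those
    windows, and every non-SDD agent, is retained.
    """
    ab = drug_events[drug_events["concept"] == "antibiotic"]
    if ab.empty:
        return ab, pd.DataFrame(columns=["admissionid", "day", "prophylaxis"])
    is_sdd = ab["item"].map(rank_map.is_sdd_drug) & ab["day"].isin(rank_map.sdd_days)
    retained = ab[~is_sdd]
    all_days = ab.groupby(["admissionid", "day"]).size()
    kept_days = retained.groupby(["admissionid", "day"]).size()
    only_excluded = all_days.index.difference(
        kept_days.index if len(kept_days) else all_days.index[:0]
    )
    sdd_flags = pd.DataFrame(
        [(a, int(d), True) for a, d in only_excluded],
        columns=["admissionid", "day", "prophylaxis"],
    )
    return retained, sdd_flags


def build_day_profiles(
    drug_events: pd.DataFrame, rank_map: AntibioticRankMap
) -> tuple[dict, list]:
    """Summarise (already filtered) antibiotic events into per-window profiles.

    Returns ``(profiles, unknown)``: a dict keyed by (admissionid, day) with
    one :class:`AntibioticDayProfile` per window that has at least one
    administration, and the list of (admissionid, day, name) whose name the
    formulary cannot rank (those events are skipped, not fatal).
    """
    profiles: dict = {}
    unknown: list = []
    ab = drug_events[drug_events["concept"] == "antibiotic"]
    for (admission_id, day), sub in ab.groupby(["admissionid", "day"], sort=False):
        agents = set()
        for name, route in zip(sub["item"], sub["route"]):
            canon, rank = rank_map.resolve(name)
            if rank is None:
                unknown.append((admission_id, int(day), canon))
                continue
            agents.add((canon, rank, route))
        if agents:
            profiles[(admission_id, int(day))] = AntibioticDayProfile(
                admission_id=admission_id, day=int(day), agents=frozenset(agents)
            )
    return profiles, unknown


def detect_escalation(
    profile_d: AntibioticDayProfile | None,
    profile_prev: AntibioticDayProfile | None,
) -> bool | None:
    """Escalation determination for one window given the previous window.

    ``None`` (no determination) when the current window has no
    administrations.  Otherwise True iff at least one current agent is IV and
    either the maximum rank increased, or it is unchanged and the number of
    distinct agents at that rank increased.  An empty or absent previous
    window counts as rank zero, so any IV start is an escalation.
    """
    if profile_d is None or not profile_d.agents:
        return None
    if not profile_d.any_iv:
        return False
    prev_max = profile_prev.max_rank if profile_prev is not None else None
    if prev_max is None:
        return True
    cur_max = profile_d.max_rank
    if cur_max > prev_max:
        return True
    if cur_max == prev_max and profile_d.n_at_max > profile_prev.n_at_max:
        return True
    return False


def escalation_series(
    profiles: dict, admission_id, day_range: tuple[int, int]
) -> dict[int, bool | None]:
    """Per-day escalation determinations for one admission across a day range."""
    d_min, d_max = day_range
    out: dict[int, bool | None] = {}
    for day in range(d_min, d_max + 1):
        out[day] = detect_escalation(
            profiles.get((admission_id, day)), profiles.get((admission_id, day - 1))
        )
    return out
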