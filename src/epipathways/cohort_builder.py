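"""Cohort construction: index event, age cap, follow-up, persistence windows.

The cohort is a new-user design without wash-out: the index date is the first
anti-seizure-medication (ASM) exposure in the person's history, the person
must be 18 or younger on that date, must remain observed for at least 730
days after it, must carry an epilepsy diagnosis at any time, and must have at
least one ASM prescription in each post-index persistence window.  Day
arithmetic treats the index date as day 0 and windows as closed integer
intervals.
"""

from __future__ import annotations

import dataclasses
from datetime import date

import pandas as pd

from .cdm_tables import CdmTables

__all__ = [
    "CohortDefinition",
    "CohortMember",
    "DEFAULT_WINDOWS",
    "find_index_event",
    "check_persistence",
    "build_cohort",
    "cohort_to_frame",
]

#: Five 120-day persistence windows covering post-index days 121..730.
#: Days 0..120 are covered by the index prescription itself.
DEFAULT_WINDOWS: tuple[tuple[int, int], ...] = (
    (121, 240),
    (241, 360),
    (361, 480),
    (481, 600),
    (601, 730),
)

DAYS_PER_YEAR = 365.25


@dataclasses.dataclass(frozen=True)
class CohortDefinition:
    """Parametrized inclusion rules.

    ``max_index_age_years`` uses an inclusive comparison (exactly 18.0 at
    index still qualifies).  ``persistence_windows`` are closed day-offset
    intervals that must each contain at least one exposure; they must be
    sorted, non-overlapping and lie within ``[1, min_post_index_days]``.
    """

    max_index_age_years: float = 18.0
    min_post_index_days: int = 730
    persistence_windows: tuple[tuple[int, int], ...] = DEFAULT_WINDOWS
    require_diagnosis: bool = True

    def __post_init__(self) -> None:
        prev_end = 0
        for lo, hi in self.persistence_windows:
            if lo > hi:
                raise ValueError(f"window [{lo},{hi}] has lo > hi")
            if lo <= prev_end:
                raise ValueError("persistence windows must be sorted and non-overlapping")
            if lo < 1 or hi > self.min_post_index_days:
                raise ValueError(
                    f"window [{lo},{hi}] outside [1,{self.min_post_index_days}]"
                )
            prev_end = hi


@dataclasses.dataclass(frozen=True)
class CohortMember:
    person_id: int
    index_date: pd.Timestamp
    age_at_index: float   # fractional years, days / 365.25
    followup_days: int    # observation days after index


def find_index_event(
    birth_date: pd.Timestamp,
    exposure_dates: pd.Series | list,
    definition: CohortDefinition,
) -> pd.Timestamp | None:
    """Earliest ASM exposure, if it occurred at or before the age cap.

    Events are limited to the earliest per person, so a first-ever exposure
    after the cap disqualifies the person outright rather than deferring to a
    later exposure.
    """
    dates = pd.Series(pd.to_datetime(pd.Series(list(exposure_dates))))
    if dates.empty:
        return None
    first = dates.min()
    age = (first - pd.Timestamp(birth_date)).days / DAYS_PER_YEAR
    if age <= definition.max_index_age_years:
        return first
    return None


def check_persistence(
    index_date: pd.Timestamp | date,
    exposure_dates: pd.Series | list,
    definition: CohortDefinition,
) -> bool:
    """True iff every persistence window contains at least one exposure.

    Offsets are integer days since index (index day = day 0); both window
    endpoints are inclusive.
    """
    idx = pd.Timestamp(index_date)
    offsets = {
        (pd.Timestamp(d) - idx).days for d in list(exposure_dates)
    }
    return all(
        any(lo <= off <= hi for off in offsets)
        for lo, hi in definition.persistence_windows
    )


# exclusion reason labels, in evaluation order
REASON_NO_INDEX = "no_asm_exposure"
REASON_AGE = "first_exposure_after_age_cap"
REASON_FOLLOWUP = "insufficient_followup"
REASON_DIAGNOSIS = "no_epilepsy_diagnosis"


def _persistence_reason(lo: int, hi: int) -> str:
    return f"empty_persistence_window_{lo}_{hi}"


def build_cohort(
    tables: CdmTables,
    definition: CohortDefinition | None = None,
    return_exclusions: bool = False,
):
    """Apply the full inclusion cascade; return members sorted by person_id.

    With ``return_exclusions=True`` also returns a ``{person_id: reason}``
    map giving the first violated criterion for every excluded person, which
    makes the attrition cascade auditable.
    """
    definition = definition or CohortDefinition()
    voc = tables.vocabulary
    asm_ids = set(voc.loc[voc["drug_class"] == "N03A_ingredient", "concept_id"])
    epilepsy_ids = set(voc.loc[voc["domain"] == "condition", "concept_id"])

    exposures = tables.drug_exposures
    exposures = exposures[exposures["drug_concept_id"].isin(asm_ids)]
    exp_by_person = {pid: grp["exposure_date"] for pid, grp in exposures.groupby("person_id")}
    cond_persons = set(
        tables.condition_occurrences.loc[
            tables.condition_occurrences["condition_concept_id"].isin(epilepsy_ids),
            "person_id",
        ]
    )
    obs = tables.observation_periods.drop_duplicates("person_id").set_index("person_id")

    members: list[CohortMember] = []
    exclusions: dict[int, str] = {}
    for _, person in tables.persons.sort_values("person_id").iterrows():
        pid = int(person["person_id"])
        dates = exp_by_person.get(pid)
        if dates is None or dates.empty:
            exclusions[pid] = REASON_NO_INDEX
            continue
        index = find_index_event(person["birth_date"], dates, definition)
        if index is None:
            exclusions[pid] = REASON_AGE
            continue
        if pid not in obs.index:
            exclusions[pid] = REASON_FOLLOWUP
            continue
        end = obs.loc[pid, "end_date"]
        followup = (end - index).days
        if followup < definition.min_post_index_days or obs.loc[pid, "start_date"] > index:
            exclusions[pid] = REASON_FOLLOWUP
            continue
        if definition.require_diagnosis and pid not in cond_persons:
            exclusions[pid] = REASON_DIAGNOSIS
            continue
        offsets = {(pd.Timestamp(d) - index).days for d in dates}
        failed = None
        for lo, hi in definition.persistence_windows:
            if not any(lo <= off <= hi for off in offsets):
                failed = (lo, hi)
                break
        if failed is not None:
            exclusions[pid] = _persistence_reason(*failed)
            continue
        age = (index - person["birth_date"]).days / DAYS_PER_YEAR
        members.append(CohortMember(pid, index, age, followup))

    if return_exclusions:
        return members, exclusions
    return members


def cohort_to_frame(members: list[CohortMember]) -> pd.DataFrame:
    """Members as a DataFrame (person_id, index_date, age_at_index, followup_days)."""
    return pd.DataFrame(
        [
            {
                "person_id": m.person_id,
                "index_date": m.index_date,
                "age_at_index": m.age_at_index,
                "followup_days": m.followup_days,
            }
            for m in members
        ],
        columns=["person_id", "index_date", "age_at_index", "followup_days"],
    )
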