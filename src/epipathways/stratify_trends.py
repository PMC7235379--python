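"""Subgroup stratification and the annual monotherapy prescription trend.

Strata come in three kinds: epilepsy category (focal / generalized /
unclassified, from the diagnosis vocabulary's condition groups), onset-age
bins (<4, 4–13, >13 years at index), and electro-clinical syndrome (LGS,
CAE, BECTS, with a "none" remainder).  Each kind partitions the cohort.
The annual trend counts, per calendar year and ingredient, the cohort
members exposed to that ingredient and to no other ASM within the year
(monotherapy-in-year).
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from .cdm_tables import CdmTables
from .cohort_builder import CohortMember
from .pathway_sequencer import (
    PathwayTable,
    TreatmentSequence,
    asm_count_distribution,
    count_pathways,
)

__all__ = [
    "Stratum",
    "StratumResult",
    "classify_epilepsy_type",
    "onset_age_stratum",
    "syndrome_stratum",
    "assign_strata",
    "stratified_pathways",
    "annual_monotherapy_trend",
]

AGE_BINS = ("<4", "4–13", ">13")
SYNDROMES = ("LGS", "CAE", "BECTS")


@dataclasses.dataclass
class Stratum:
    name: str
    kind: str  # epilepsy_type | onset_age | syndrome | all
    member_ids: set[int]


@dataclasses.dataclass
class StratumResult:
    stratum: Stratum
    pathways: PathwayTable
    distribution: dict
    dre_pct: float


def _classifying_concept(
    person_id: int,
    conditions: pd.DataFrame,
    vocabulary: pd.DataFrame,
) -> int | None:
    """The diagnosis concept that labels this person.

    Among the person's epilepsy-vocabulary diagnoses: most frequent concept
    wins; ties broken by earliest condition_start_date, then lowest
    concept_id.  This multi-diagnosis policy is a package choice, exposed
    here as the single point of truth for both type and syndrome labels.
    """
    known = set(vocabulary.loc[vocabulary["domain"] == "condition", "concept_id"])
    sub = conditions[
        (conditions["person_id"] == person_id)
        & (conditions["condition_concept_id"].isin(known))
    ]
    if sub.empty:
        return None
    stats = (
        sub.groupby("condition_concept_id")["condition_start_date"]
        .agg(["count", "min"])
        .reset_index()
    )
    stats = stats.sort_values(
        by=["count", "min", "condition_concept_id"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    return int(stats.iloc[0]["condition_concept_id"])


def classify_epilepsy_type(
    member: CohortMember,
    conditions: pd.DataFrame,
    vocabulary: pd.DataFrame,
) -> str:
    """focal / generalized / unclassified for the member's classifying diagnosis."""
    cid = _classifying_concept(member.person_id, conditions, vocabulary)
    if cid is None:
        return "unclassified"
    group = vocabulary.loc[vocabulary["concept_id"] == cid, "condition_group"].iloc[0]
    return group if group in ("focal", "generalized") else "unclassified"


def onset_age_stratum(age_at_index: float) -> str:
    """Onset-age bin: [0,4) -> "<4", [4,13] -> "4–13", (13,18] -> ">13"."""
    if age_at_index < 0 or age_at_index > 18.01:
        raise ValueError(f"age_at_index {age_at_index} outside [0, 18]")
    if age_at_index < 4:
        return "<4"
    if age_at_index <= 13:
        return "4–13"
    return ">13"


def syndrome_stratum(
    member: CohortMember,
    conditions: pd.DataFrame,
    vocabulary: pd.DataFrame,
) -> str | None:
    """LGS / CAE / BECTS tag of the classifying diagnosis, or None."""
    cid = _classifying_concept(member.person_id, conditions, vocabulary)
    if cid is None:
        return None
    tag = vocabulary.loc[vocabulary["concept_id"] == cid, "syndrome_tag"].iloc[0]
    return tag if tag in SYNDROMES else None


def assign_strata(
    tables: CdmTables,
    members: list[CohortMember],
    kind: str,
) -> list[Stratum]:
    """Partition the cohort into named strata of the given kind.

    Every kind includes an explicit remainder stratum so the union always
    covers the cohort; empty strata are kept (with zero members).
    """
    conditions = tables.condition_occurrences
    voc = tables.vocabulary
    if kind == "all":
        return [Stratum("all", "all", {m.person_id for m in members})]
    if kind == "epilepsy_type":
        names = ["focal", "generalized", "unclassified"]
        label = lambda m: classify_epilepsy_type(m, conditions, voc)
    elif kind == "onset_age":
        names = list(AGE_BINS)
        label = lambda m: onset_age_stratum(m.age_at_index)
    elif kind == "syndrome":
        names = list(SYNDROMES) + ["none"]
        label = lambda m: syndrome_stratum(m, conditions, voc) or "none"
    else:
        raise ValueError(f"unknown stratification kind {kind!r}")
    buckets: dict[str, set[int]] = {n: set() for n in names}
    for m in members:
        buckets[label(m)].add(m.person_id)
    return [Stratum(n, kind, buckets[n]) for n in names]


def stratified_pathways(
    tables: CdmTables,
    members: list[CohortMember],
    sequences: list[TreatmentSequence],
    kind: str,
) -> dict[str, StratumResult]:
    """Per-stratum pathway table, ASM-count distribution, and DRE percentage."""
    strata = assign_strata(tables, members, kind)
    seq_by_person = {s.person_id: s for s in sequences}
    out: dict[str, StratumResult] = {}
    for st in strata:
        seqs = [seq_by_person[pid] for pid in sorted(st.member_ids)]
        table = count_pathways(seqs, tables.vocabulary)
        dist = asm_count_distribution(seqs)
        n_dre = sum(1 for s in seqs if s.is_dre)
        dre_pct = round(100.0 * n_dre / len(seqs), 1) if seqs else 0.0
        out[st.name] = StratumResult(st, table, dist, dre_pct)
    return out


def annual_monotherapy_trend(
    tables: CdmTables,
    members: list[CohortMember],
) -> pd.DataFrame:
    """Per-year monotherapy counts: (year, ingredient, n_patients).

    A member contributes to (year, drug) iff the member has at least one
    exposure to that drug in the calendar year and no exposure to any other
    ASM ingredient that year; a member on two drugs in a year contributes to
    neither.
    """
    voc = tables.vocabulary
    asm_ids = set(voc.loc[voc["drug_class"] == "N03A_ingredient", "concept_id"])
    member_ids = {m.person_id for m in members}
    exp = tables.drug_exposures
    exp = exp[exp["person_id"].isin(member_ids) & exp["drug_concept_id"].isin(asm_ids)]
    rows: dict[tuple[int, int], int] = {}
    if len(exp):
        years = pd.to_datetime(exp["exposure_date"]).dt.year
        per = exp.assign(_year=years).groupby(["person_id", "_year"])["drug_concept_id"].agg(set)
        for (pid, year), drugs in per.items():
            if len(drugs) == 1:
                key = (int(year), int(next(iter(drugs))))
                rows[key] = rows.get(key, 0) + 1
    names = dict(zip(voc["concept_id"], voc["concept_name"]))
    records = [
        {"year": y, "ingredient": names.get(cid, str(cid)), "n_patients": n}
        for (y, cid), n in sorted(rows.items())
    ]
    return pd.DataFrame(records, columns=["year", "ingredient", "n_patients"])
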