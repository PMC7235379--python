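"""Per-patient treatment sequences, pathway frequency tables, DRE classification.

A treatment sequence is the ordered list of *distinct* ASM ingredients a
patient is exposed to during the sequencing window, in order of first
exposure.  The representation deliberately does not distinguish substituting
a drug from adding one — both appear as the next element — and sequences are
capped at 20 ingredients.  Drug-resistant epilepsy (DRE) is operationalized
as the introduction of a third distinct ingredient.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from .cdm_tables import CdmTables, ingredient_names
from .cohort_builder import CohortMember

__all__ = [
    "TreatmentSequence",
    "PathwayTable",
    "build_sequence",
    "build_all_sequences",
    "count_pathways",
    "asm_count_distribution",
    "classify_dre",
    "asm_frequency",
]

SEQUENCE_CAP = 20
DRE_THRESHOLD = 3
SEQUENCE_WINDOW_DAYS = 730


@dataclasses.dataclass(frozen=True)
class TreatmentSequence:
    person_id: int
    ingredients: tuple[int, ...]  # distinct, in first-exposure order

    @property
    def n_distinct(self) -> int:
        return len(self.ingredients)

    @property
    def is_dre(self) -> bool:
        return classify_dre(self)


@dataclasses.dataclass
class PathwayTable:
    """Frequency table of distinct ingredient sequences.

    Rows are sorted by descending patient count, then lexicographically by
    the tuple of ingredient names, so output ordering is deterministic.
    """

    rows: list[tuple[tuple[int, ...], int]]
    total_patients: int

    def to_frame(self, vocabulary: pd.DataFrame | None = None) -> pd.DataFrame:
        names = ingredient_names(vocabulary) if vocabulary is not None else None
        out = []
        for seq, n in self.rows:
            label = "→".join(names[i] for i in seq) if names else "→".join(map(str, seq))
            out.append({"sequence": label, "n_patients": n})
        return pd.DataFrame(out, columns=["sequence", "n_patients"])


def build_sequence(
    member: CohortMember,
    exposures: pd.DataFrame,
    window_days: int | None = SEQUENCE_WINDOW_DAYS,
    cap: int = SEQUENCE_CAP,
) -> TreatmentSequence:
    """Order-preserving de-duplication of the member's in-window exposures.

    *exposures* holds the member's ASM ingredient exposures
    (``drug_concept_id``, ``exposure_date``).  ``window_days=None`` sequences
    over the full follow-up.  A cohort member cannot have zero in-window
    exposures (the index exposure is day 0), so that case raises.
    """
    offs = (pd.to_datetime(exposures["exposure_date"]) - member.index_date).dt.days
    mask = offs >= 0
    if window_days is not None:
        mask &= offs <= window_days
    sub = exposures.loc[mask].assign(_off=offs[mask])
    sub = sub.sort_values(["_off", "drug_concept_id"], kind="mergesort")
    seen: list[int] = []
    for cid in sub["drug_concept_id"]:
        cid = int(cid)
        if cid not in seen:
            seen.append(cid)
            if len(seen) == cap:
                break
    if not seen:
        raise RuntimeError(
            f"cohort member {member.person_id} has no in-window exposures; "
            "cohort construction should make this impossible"
        )
    return TreatmentSequence(member.person_id, tuple(seen))


def build_all_sequences(
    tables: CdmTables,
    members: list[CohortMember],
    window_days: int | None = SEQUENCE_WINDOW_DAYS,
    cap: int = SEQUENCE_CAP,
) -> list[TreatmentSequence]:
    voc = tables.vocabulary
    asm_ids = set(voc.loc[voc["drug_class"] == "N03A_ingredient", "concept_id"])
    exp = tables.drug_exposures
    exp = exp[exp["drug_concept_id"].isin(asm_ids)]
    grouped = dict(tuple(exp.groupby("person_id")))
    return [
        build_sequence(m, grouped[m.person_id], window_days=window_days, cap=cap)
        for m in members
    ]


def count_pathways(
    sequences: list[TreatmentSequence],
    vocabulary: pd.DataFrame | None = None,
) -> PathwayTable:
    """Exact frequency table of distinct sequences, deterministically ordered."""
    counts: dict[tuple[int, ...], int] = {}
    for s in sequences:
        counts[s.ingredients] = counts.get(s.ingredients, 0) + 1
    if vocabulary is not None:
        names = ingredient_names(vocabulary)
        name_key = lambda seq: tuple(names.get(i, str(i)) for i in seq)
    else:
        name_key = lambda seq: tuple(map(str, seq))
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], name_key(kv[0])))
    return PathwayTable(rows=rows, total_patients=len(sequences))


def classify_dre(sequence: TreatmentSequence, threshold: int = DRE_THRESHOLD) -> bool:
    """Drug resistance: at least *threshold* distinct ingredients (default 3)."""
    return sequence.n_distinct >= threshold


def asm_count_distribution(
    sequences: list[TreatmentSequence],
    threshold: int = DRE_THRESHOLD,
) -> dict:
    """Partition of the cohort by number of distinct ASMs: 1, 2, and 3+.

    Returns ``{"counts": {"1": n1, "2": n2, "3+": n3}, "percentages": ...,
    "total": n}`` with percentages rounded to one decimal; the "3+" bucket is
    exactly the DRE class.
    """
    n1 = sum(1 for s in sequences if s.n_distinct == 1)
    n2 = sum(1 for s in sequences if s.n_distinct == 2)
    n3 = sum(1 for s in sequences if s.n_distinct >= threshold)
    total = len(sequences)
    counts = {"1": n1, "2": n2, "3+": n3}
    pct = {k: round(100.0 * v / total, 1) if total else 0.0 for k, v in counts.items()}
    return {"counts": counts, "percentages": pct, "total": total}


def asm_frequency(
    sequences: list[TreatmentSequence],
    mode: str = "slot",
) -> dict[int, float]:
    """Share of each ingredient among the cohort's pathways.

    ``mode="slot"`` (default): the denominator is the total number of
    sequence slots, so shares sum to 1.  ``mode="patient"``: share of
    patients whose pathway contains the ingredient (shares need not sum
    to 1).
    """
    if mode not in ("slot", "patient"):
        raise ValueError(f"unknown mode {mode!r}")
    counts: dict[int, int] = {}
    for s in sequences:
        for cid in s.ingredients:
            counts[cid] = counts.get(cid, 0) + 1
    if mode == "slot":
        denom = sum(len(s.ingredients) for s in sequences)
    else:
        denom = len(sequences)
    return {cid: c / denom for cid, c in counts.items()} if denom else {}
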