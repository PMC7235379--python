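"""Independent brute-force re-implementations used as test oracles.

Everything here is deliberately naive: nested loops over plain Python
objects, no pandas indexing, no shared code with the package under test.
"""

from __future__ import annotations

import pandas as pd


def brute_dangling_keys(tables) -> list[tuple[str, int]]:
    """Every (table, row-position) whose foreign key resolves nowhere."""
    persons = [int(p) for p in tables.persons["person_id"]]
    concepts = [int(c) for c in tables.vocabulary["concept_id"]]
    bad = []
    for i, row in enumerate(tables.observation_periods.itertuples(index=False)):
        if int(row.person_id) not in persons:
            bad.append(("observation_period", i))
    for i, row in enumerate(tables.drug_exposures.itertuples(index=False)):
        if int(row.person_id) not in persons or int(row.drug_concept_id) not in concepts:
            bad.append(("drug_exposure", i))
    for i, row in enumerate(tables.condition_occurrences.itertuples(index=False)):
        if int(row.person_id) not in persons:
            bad.append(("condition_occurrence", i))
    return bad


def brute_build_cohort(tables, definition) -> list[int]:
    """Person ids meeting every inclusion rule, by exhaustive scan."""
    voc = tables.vocabulary
    asm_ids = set()
    cond_ids = set()
    for row in voc.itertuples(index=False):
        if row.drug_class == "N03A_ingredient":
            asm_ids.add(int(row.concept_id))
        if row.domain == "condition":
            cond_ids.add(int(row.concept_id))

    members = []
    for prow in tables.persons.itertuples(index=False):
        pid = int(prow.person_id)
        exp_dates = []
        for erow in tables.drug_exposures.itertuples(index=False):
            if int(erow.person_id) == pid and int(erow.drug_concept_id) in asm_ids:
                exp_dates.append(pd.Timestamp(erow.exposure_date))
        if not exp_dates:
            continue
        index = min(exp_dates)
        age = (index - pd.Timestamp(prow.birth_date)).days / 365.25
        if age > definition.max_index_age_years:
            continue
        span = None
        for orow in tables.observation_periods.itertuples(index=False):
            if int(orow.person_id) == pid:
                span = (pd.Timestamp(orow.start_date), pd.Timestamp(orow.end_date))
                break
        if span is None or span[0] > index:
            continue
        if (span[1] - index).days < definition.min_post_index_days:
            continue
        if definition.require_diagnosis:
            has_dx = False
            for crow in tables.condition_occurrences.itertuples(index=False):
                if int(crow.person_id) == pid and int(crow.condition_concept_id) in cond_ids:
                    has_dx = True
                    break
            if not has_dx:
                continue
        ok = True
        for lo, hi in definition.persistence_windows:
            found = False
            for d in exp_dates:
                off = (d - index).days
                if lo <= off <= hi:
                    found = True
                    break
            if not found:
                ok = False
                break
        if ok:
            members.append(pid)
    return sorted(members)


def brute_build_sequence(index_date, exposures, window_days=730, cap=20):
    """First-appearance-ordered distinct ingredients, by linear scan."""
    events = []
    for row in exposures.itertuples(index=False):
        off = (pd.Timestamp(row.exposure_date) - pd.Timestamp(index_date)).days
        if off >= 0 and (window_days is None or off <= window_days):
            events.append((off, int(row.drug_concept_id)))
    events.sort()
    seq = []
    for _, cid in events:
        if cid not in seq:
            seq.append(cid)
    return tuple(seq[:cap])


def brute_count_pathways(sequences):
    """sequence tuple -> patient count, by repeated counting."""
    distinct = []
    for s in sequences:
        if s.ingredients not in distinct:
            distinct.append(s.ingredients)
    return {d: sum(1 for s in sequences if s.ingredients == d) for d in distinct}


def brute_classify_dre(sequence, threshold=3) -> bool:
    return len(set(sequence.ingredients)) >= threshold
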