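"""Shared fixtures: a tiny handcrafted CDM bundle and a messy random-table maker."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from epipathways.cdm_tables import CdmTables, default_vocabulary

VPA, OXC, LTG = 40001, 40002, 40003
FOCAL_NOS, CAE, BECTS_ID, LGS_ID = 374915, 4179936, 4185733, 4046213


def _dt(s: str) -> pd.Timestamp:
    return pd.Timestamp(s)


@pytest.fixture
def three_patient_tables() -> CdmTables:
    """Three handcrafted patients.

    1: qualifies (VPA monotherapy, diagnosed focal NOS, exposures every ~60d).
    2: fails persistence (window [241,360] empty).
    3: first exposure after age 18 (disqualified by the age cap).
    """
    persons = pd.DataFrame([
        {"person_id": 1, "sex": "female", "birth_date": _dt("2000-01-01")},
        {"person_id": 2, "sex": "male", "birth_date": _dt("2002-06-15")},
        {"person_id": 3, "sex": "male", "birth_date": _dt("1990-01-01")},
    ])
    obs = pd.DataFrame([
        {"person_id": 1, "start_date": _dt("2005-01-01"), "end_date": _dt("2010-01-01")},
        {"person_id": 2, "start_date": _dt("2008-01-01"), "end_date": _dt("2012-01-01")},
        {"person_id": 3, "start_date": _dt("2009-01-01"), "end_date": _dt("2014-01-01")},
    ])
    p1_days = [0, 60, 130, 200, 250, 310, 370, 430, 490, 550, 610, 670, 730]
    p2_days = [0, 60, 130, 200, 370, 430, 490, 550, 610, 670]  # [241,360] empty
    exposures = []
    for d in p1_days:
        exposures.append({"person_id": 1, "drug_concept_id": VPA,
                          "exposure_date": _dt("2005-02-01") + pd.Timedelta(days=d)})
    for d in p2_days:
        exposures.append({"person_id": 2, "drug_concept_id": OXC,
                          "exposure_date": _dt("2008-03-01") + pd.Timedelta(days=d)})
    exposures.append({"person_id": 3, "drug_concept_id": LTG,
                      "exposure_date": _dt("2009-06-01")})  # age 19.4
    conditions = pd.DataFrame([
        {"person_id": 1, "condition_concept_id": FOCAL_NOS,
         "condition_start_date": _dt("2005-02-01")},
        {"person_id": 2, "condition_concept_id": CAE,
         "condition_start_date": _dt("2008-03-01")},
        {"person_id": 3, "condition_concept_id": FOCAL_NOS,
         "condition_start_date": _dt("2009-06-01")},
    ])
    return CdmTables(
        persons=persons,
        observation_periods=obs,
        drug_exposures=pd.DataFrame(exposures),
        condition_occurrences=conditions,
        vocabulary=default_vocabulary(),
    )


def make_random_tables(rng: np.random.Generator, n_persons: int | None = None) -> CdmTables:
    """Structurally valid but behaviorally messy random tables.

    Random index ages (some over 18), random exposure day sets (persistence
    windows may or may not be covered), short or long observation periods,
    and occasionally missing diagnoses — an adversarial input for comparing
    the cohort builder against the brute-force oracle.
    """
    voc = default_vocabulary()
    drug_ids = voc.loc[voc["domain"] == "drug", "concept_id"].astype(int).tolist()
    cond_ids = voc.loc[voc["domain"] == "condition", "concept_id"].astype(int).tolist()
    if n_persons is None:
        n_persons = int(rng.integers(1, 40))
    persons, obs, exps, conds = [], [], [], []
    for pid in range(1, n_persons + 1):
        age_at_first = float(rng.uniform(0.5, 25.0))
        first_exp = pd.Timestamp("2006-01-01") + pd.Timedelta(days=int(rng.integers(0, 3000)))
        birth = first_exp - pd.Timedelta(days=int(age_at_first * 365.25))
        persons.append({"person_id": pid, "sex": rng.choice(["male", "female"]),
                        "birth_date": birth})
        obs_len = int(rng.integers(100, 2000))
        obs_start = first_exp - pd.Timedelta(days=int(rng.integers(0, 200)))
        obs_end = first_exp + pd.Timedelta(days=obs_len)
        obs.append({"person_id": pid, "start_date": obs_start, "end_date": obs_end})
        n_exp = int(rng.integers(0, 14))
        days = sorted(set([0] + list(rng.integers(0, obs_len + 1, size=n_exp))))
        for d in days:
            exps.append({
                "person_id": pid,
                "drug_concept_id": int(rng.choice(drug_ids)),
                "exposure_date": first_exp + pd.Timedelta(days=int(d)),
            })
        if rng.random() < 0.85:
            conds.append({
                "person_id": pid,
                "condition_concept_id": int(rng.choice(cond_ids)),
                "condition_start_date": first_exp + pd.Timedelta(days=int(rng.integers(0, 200))),
            })
    empty = CdmTables.empty(voc)
    return CdmTables(
        persons=pd.DataFrame(persons),
        observation_periods=pd.DataFrame(obs),
        drug_exposures=pd.DataFrame(exps) if exps else empty.drug_exposures,
        condition_occurrences=pd.DataFrame(conds) if conds else empty.condition_occurrences,
        vocabulary=voc,
    )
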