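"""Stratification partitions, diagnosis tie-breaking, and the monotherapy trend."""

import numpy as np
import pandas as pd
import pytest

from epipathways.cdm_tables import default_vocabulary
from epipathways.cohort_builder import CohortDefinition, CohortMember, build_cohort
from epipathways.pathway_sequencer import build_all_sequences
from epipathways.stratify_trends import (
    annual_monotherapy_trend,
    assign_strata,
    classify_epilepsy_type,
    onset_age_stratum,
    stratified_pathways,
    syndrome_stratum,
)
from epipathways.synthetic_data import (
    expected_stratum_dre,
    generate,
    make_paperlike_config,
)

from .conftest import make_random_tables

VOC = default_vocabulary()
MEMBER = CohortMember(1, pd.Timestamp("2010-01-01"), 8.0, 1000)


def conditions(*concept_date_pairs, pid=1):
    return pd.DataFrame([
        {"person_id": pid, "condition_concept_id": cid,
         "condition_start_date": pd.Timestamp(d)}
        for cid, d in concept_date_pairs
    ])


class TestEpilepsyTypeClassification:
    def test_bects_concept_is_focal(self):
        conds = conditions((4185733, "2010-01-01"))
        assert classify_epilepsy_type(MEMBER, conds, VOC) == "focal"

    def test_cae_concept_is_generalized(self):
        conds = conditions((4179936, "2010-01-01"))
        assert classify_epilepsy_type(MEMBER, conds, VOC) == "generalized"

    def test_unknown_concepts_give_unclassified(self):
        conds = conditions((123, "2010-01-01"))
        assert classify_epilepsy_type(MEMBER, conds, VOC) == "unclassified"

    def test_most_frequent_diagnosis_wins(self):
        conds = conditions(
            (4179936, "2010-01-01"),  # CAE once
            (4046213, "2010-02-01"), (4046213, "2010-03-01"),  # LGS twice
        )
        assert syndrome_stratum(MEMBER, conds, VOC) == "LGS"

    def test_frequency_tie_broken_by_earliest_date(self):
        conds = conditions((4046213, "2010-02-01"), (4179936, "2010-01-01"))
        assert syndrome_stratum(MEMBER, conds, VOC) == "CAE"

    def test_full_tie_broken_by_lowest_concept_id(self):
        conds = conditions((4179936, "2010-01-01"), (4046213, "2010-01-01"))
        assert syndrome_stratum(MEMBER, conds, VOC) == "LGS"  # 4046213 < 4179936

    def test_no_syndrome_tag_gives_none(self):
        conds = conditions((374915, "2010-01-01"))
        assert syndrome_stratum(MEMBER, conds, VOC) is None


class TestOnsetAgeBins:
    @pytest.mark.parametrize("age,bin_", [
        (0.0, "<4"), (3.9, "<4"), (4.0, "4–13"), (9.0, "4–13"),
        (13.0, "4–13"), (13.5, ">13"), (18.0, ">13"),
    ])
    def test_half_closed_partition(self, age, bin_):
        assert onset_age_stratum(age) == bin_

    def test_out_of_range_age_raises(self):
        with pytest.raises(ValueError):
            onset_age_stratum(-0.5)
        with pytest.raises(ValueError):
            onset_age_stratum(25.0)


class TestStrataPartition:
    @pytest.mark.parametrize("kind", ["epilepsy_type", "onset_age", "syndrome"])
    def test_strata_partition_cohort(self, kind):
        rng = np.random.default_rng(61)
        tables = make_random_tables(rng, n_persons=60)
        members = build_cohort(tables, CohortDefinition())
        strata = assign_strata(tables, members, kind)
        ids = [st.member_ids for st in strata]
        union = set().union(*ids)
        assert union == {m.person_id for m in members}
        assert sum(len(s) for s in ids) == len(members)  # pairwise disjoint

    def test_empty_strata_are_present_with_zero_counts(self):
        tables, _ = generate(make_paperlike_config(5, seed=2, p_dropout=0.0))
        members = build_cohort(tables, CohortDefinition())
        seqs = build_all_sequences(tables, members)
        results = stratified_pathways(tables, members, seqs, "syndrome")
        assert set(results) == {"LGS", "CAE", "BECTS", "none"}

    def test_all_monotherapy_stratum_has_zero_dre(self):
        tables, truths = generate(make_paperlike_config(60, seed=3, p_dropout=0.0))
        members = build_cohort(tables, CohortDefinition())
        seqs = build_all_sequences(tables, members)
        mono_ids = {s.person_id for s in seqs if s.n_distinct == 1}
        mono_members = [m for m in members if m.person_id in mono_ids]
        mono_seqs = [s for s in seqs if s.person_id in mono_ids]
        results = stratified_pathways(tables, mono_members, mono_seqs, "all")
        assert results["all"].dre_pct == 0.0

    def test_stratum_dre_recovers_injected_rates(self):
        """Per-type DRE% within 3 binomial SE of the mixture-implied rates (n=2000)."""
        cfg = make_paperlike_config(2000, seed=17, p_dropout=0.0)
        tables, _ = generate(cfg)
        members = build_cohort(tables, CohortDefinition())
        seqs = build_all_sequences(tables, members)
        results = stratified_pathways(tables, members, seqs, "epilepsy_type")
        injected = expected_stratum_dre(cfg, tables.vocabulary, "epilepsy_type")
        for name in ("focal", "generalized"):
            n = results[name].distribution["total"]
            p = injected[name]
            se = np.sqrt(p * (1 - p) / n)
            assert abs(results[name].dre_pct / 100 - p) <= 3 * se


class TestAnnualTrend:
    def _one_member_tables(self, exposures):
        tables, _ = generate(make_paperlike_config(1, seed=1, p_dropout=0.0))
        tables.drug_exposures = exposures
        # trend logic only touches exposures and vocabulary
        return tables

    def test_single_drug_year_counts(self):
        exp = pd.DataFrame([
            {"person_id": 1, "drug_concept_id": 40001,
             "exposure_date": pd.Timestamp("2010-03-01")},
            {"person_id": 1, "drug_concept_id": 40001,
             "exposure_date": pd.Timestamp("2010-09-01")},
        ])
        tables = self._one_member_tables(exp)
        trend = annual_monotherapy_trend(tables, [MEMBER])
        assert trend.to_dict("records") == [
            {"year": 2010, "ingredient": "valproic acid", "n_patients": 1}
        ]

    def test_two_drugs_in_year_contribute_nothing(self):
        exp = pd.DataFrame([
            {"person_id": 1, "drug_concept_id": 40001,
             "exposure_date": pd.Timestamp("2010-03-01")},
            {"person_id": 1, "drug_concept_id": 40002,
             "exposure_date": pd.Timestamp("2010-09-01")},
            {"person_id": 1, "drug_concept_id": 40001,
             "exposure_date": pd.Timestamp("2011-02-01")},
        ])
        tables = self._one_member_tables(exp)
        trend = annual_monotherapy_trend(tables, [MEMBER])
        assert (trend["year"] == 2011).all()  # 2010 excluded, 2011 monotherapy

    def test_trend_totals_bounded_by_active_patients(self):
        tables, _ = generate(make_paperlike_config(300, seed=19, p_dropout=0.0))
        members = build_cohort(tables, CohortDefinition())
        trend = annual_monotherapy_trend(tables, members)
        exp = tables.drug_exposures
        years = pd.to_datetime(exp["exposure_date"]).dt.year
        for year, grp in trend.groupby("year"):
            active = exp.loc[years == year, "person_id"].nunique()
            assert grp["n_patients"].sum() <= active

    def test_injected_drift_direction_recovered(self):
        cfg = make_paperlike_config(1200, seed=20, p_dropout=0.0)
        cfg.year_drug_weights = {
            y: {"valproic acid": w}
            for y, w in zip(range(2004, 2016), np.linspace(3.0, 0.1, 12))
        }
        tables, _ = generate(cfg)
        members = build_cohort(tables, CohortDefinition())
        trend = annual_monotherapy_trend(tables, members)
        vpa = trend[trend["ingredient"] == "valproic acid"].set_index("year")["n_patients"]
        totals = trend.groupby("year")["n_patients"].sum()
        share = (vpa / totals).dropna()
        early = share[share.index <= 2008].mean()
        late = share[(share.index >= 2012) & (share.index <= 2015)].mean()
        assert early > late
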