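"""Generator determinism, constructive validity and mixture recovery."""

import numpy as np
import pandas as pd
import pytest

from epipathways.cdm_tables import CdmTables, default_vocabulary
from epipathways.cohort_builder import CohortDefinition, build_cohort
from epipathways.pathway_sequencer import build_all_sequences, count_pathways
from epipathways.synthetic_data import (
    TABLE1_COUNTS,
    GeneratorConfig,
    config_from_file,
    expected_pathway_probs,
    generate,
    ground_truth_frame,
    make_paperlike_config,
)

from .oracles import brute_build_cohort


class TestConfig:
    def test_invalid_probability_map_rejected(self):
        cfg = GeneratorConfig(n_patients=10)
        cfg.syndrome_mixture = {374915: 0.5, 4055361: 0.4}
        with pytest.raises(ValueError, match="sum to 1"):
            cfg.validate()

    def test_mixture_with_repeated_ingredient_rejected(self):
        cfg = GeneratorConfig(n_patients=10)
        cfg.pathway_mixtures["default"] = {("valproic acid", "valproic acid"): 1.0}
        with pytest.raises(ValueError, match="repeated"):
            cfg.validate()

    def test_default_mixtures_are_normalized(self):
        cfg = make_paperlike_config(1, seed=0)
        assert sum(cfg.syndrome_mixture.values()) == pytest.approx(1.0, abs=1e-9)
        for mix in cfg.pathway_mixtures.values():
            assert sum(mix.values()) == pytest.approx(1.0, abs=1e-9)

    def test_paperlike_requires_at_least_one_patient(self):
        with pytest.raises(ValueError):
            make_paperlike_config(0, seed=0)

    def test_yaml_config_round_trips_key_fields(self, tmp_path):
        path = tmp_path / "gen.yaml"
        path.write_text(
            "n_patients: 25\n"
            "seed: 3\n"
            "p_dropout: 0.1\n"
            "calendar_start: 2006-01-01\n"
            "onset_age_range: [0.5, 17.0]\n"
            "pathway_mixtures:\n"
            "  default:\n"
            "    - {sequence: [valproic acid], p: 0.6}\n"
            "    - {sequence: [valproic acid, lamotrigine], p: 0.4}\n"
        )
        cfg = config_from_file(path)
        assert cfg.n_patients == 25 and cfg.p_dropout == 0.1
        assert cfg.onset_age_range == (0.5, 17.0)
        assert cfg.pathway_mixtures["default"][("valproic acid",)] == 0.6
        tables, _ = generate(cfg)
        assert len(tables.persons) == 25

    def test_unknown_config_key_rejected(self, tmp_path):
        path = tmp_path / "gen.yaml"
        path.write_text("n_patients: 5\nbogus_key: 1\n")
        with pytest.raises(ValueError, match="bogus_key"):
            config_from_file(path)


class TestGenerate:
    def test_zero_patients_gives_empty_valid_tables(self):
        tables, truths = generate(GeneratorConfig(n_patients=0))
        assert truths == []
        assert len(tables.persons) == 0
        tables.validate()

    def test_seed_determinism(self):
        cfg = make_paperlike_config(80, seed=9)
        t1, g1 = generate(cfg)
        t2, g2 = generate(cfg)
        for attr in ("persons", "observation_periods", "drug_exposures",
                     "condition_occurrences"):
            pd.testing.assert_frame_equal(getattr(t1, attr), getattr(t2, attr))
        assert ground_truth_frame(g1).equals(ground_truth_frame(g2))

    def test_different_seeds_differ(self):
        t1, _ = generate(make_paperlike_config(80, seed=1))
        t2, _ = generate(make_paperlike_config(80, seed=2))
        assert not t1.drug_exposures.equals(t2.drug_exposures)

    def test_generated_tables_pass_validation(self):
        tables, _ = generate(make_paperlike_config(150, seed=4))
        tables.validate()  # no exception

    def test_no_dropout_means_everyone_qualifies(self):
        tables, truths = generate(make_paperlike_config(200, seed=6, p_dropout=0.0))
        assert all(t.intended_in_cohort for t in truths)
        members = build_cohort(tables, CohortDefinition())
        assert len(members) == 200

    def test_members_and_dropouts_agree_with_brute_force_oracle(self):
        tables, truths = generate(make_paperlike_config(120, seed=8, p_dropout=0.35))
        admitted = set(brute_build_cohort(tables, CohortDefinition()))
        for t in truths:
            assert (t.person_id in admitted) == t.intended_in_cohort

    def test_sequences_realized_in_intended_order(self):
        tables, truths = generate(make_paperlike_config(150, seed=10, p_dropout=0.0))
        members = build_cohort(tables, CohortDefinition())
        seqs = build_all_sequences(tables, members)
        truth = {t.person_id: t.true_sequence for t in truths}
        for s in seqs:
            assert s.ingredients == truth[s.person_id]


class TestPaperlikeMixture:
    def test_focal_count_within_binomial_ci(self):
        """At n=1191 the focal diagnosis count should land near 835 (Table-1 scale)."""
        tables, truths = generate(make_paperlike_config(1191, seed=12))
        voc = default_vocabulary()
        groups = dict(zip(voc["concept_id"], voc["condition_group"]))
        n_focal = sum(1 for t in truths if groups[t.true_syndrome] == "focal")
        p = 835 / 1191
        se = np.sqrt(p * (1 - p) * 1191)
        assert abs(n_focal - 835) < 2.58 * se  # 99% binomial CI

    def test_syndrome_mixture_proportional_to_concept_counts(self):
        cfg = make_paperlike_config(10, seed=0)
        total = sum(TABLE1_COUNTS.values())
        assert total == 1191
        assert cfg.syndrome_mixture[374915] == pytest.approx(613 / total)

    def test_pathway_mixture_recovery(self):
        """n=2000, no dropout: pipeline-recovered pathway frequencies lie within
        3 binomial SE of the injected marginals for every pathway with p >= 0.02."""
        cfg = make_paperlike_config(2000, seed=14, p_dropout=0.0)
        tables, _ = generate(cfg)
        members = build_cohort(tables, CohortDefinition())
        seqs = build_all_sequences(tables, members)
        table = count_pathways(seqs, tables.vocabulary)
        names = dict(zip(tables.vocabulary["concept_id"], tables.vocabulary["concept_name"]))
        observed = {
            tuple(names[c] for c in seq): n / table.total_patients
            for seq, n in table.rows
        }
        expected = expected_pathway_probs(cfg, tables.vocabulary)
        checked = 0
        for seq, p in expected.items():
            if p < 0.02:
                continue
            se = np.sqrt(p * (1 - p) / table.total_patients)
            assert abs(observed.get(seq, 0.0) - p) <= 3 * se, seq
            checked += 1
        assert checked >= 10


class TestCalendarDrift:
    def test_year_weights_shift_first_drug_choice(self):
        base = dict(n_patients=400, p_dropout=0.0)
        cfg = make_paperlike_config(seed=16, **base)
        cfg.year_drug_weights = {
            y: {"valproic acid": w}
            for y, w in zip(range(2004, 2016), np.linspace(2.0, 0.1, 12))
        }
        tables, truths = generate(cfg)
        early = [t for t in truths if t.index_date.year <= 2008]
        late = [t for t in truths if t.index_date.year >= 2012]
        vpa = 40001
        share_early = np.mean([t.true_sequence[0] == vpa for t in early])
        share_late = np.mean([t.true_sequence[0] == vpa for t in late])
        assert share_early > share_late
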