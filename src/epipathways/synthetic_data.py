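"""Synthetic OMOP-CDM cohort generator with per-patient ground truth.

The generator emulates the structure of a single-center pediatric epilepsy
EHR extract: first-ASM index events at age <= 18, at least two years of
post-index observation, one epilepsy diagnosis per patient drawn from a
20-concept vocabulary, ordered ingredient sequences drawn from per-subgroup
pathway mixtures, persistence maintained by a 60-day prescription cadence,
and a configurable fraction of "dropout" patients who violate exactly one
persistence window.  Every patient carries a :class:`GroundTruth` record, so
downstream cohort construction, sequencing and stratification can be tested
against known labels.

Defaults are calibrated to the published summary of the emulated study
population: diagnosis mixture proportional to the printed per-concept counts
(835 focal, 344 generalized, 12 unclassified of 1,191), male share 653/1,192,
onset age ~ truncated normal(8.3, 5.0) on [0.1, 18] years, follow-up ~
truncated normal(6.5, 3.2) on [2.0, 14.2] years, calendar span 2004-01-01 to
2017-10-31, and pathway mixtures whose implied drug-resistance rates
approximate the published per-subgroup rates.
"""

from __future__ import annotations

import dataclasses
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy import stats

from .cdm_tables import CdmTables, default_vocabulary
from .cohort_builder import DEFAULT_WINDOWS

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate",
    "make_paperlike_config",
    "expected_stratum_dre",
    "expected_pathway_probs",
    "ground_truth_frame",
]

DAYS_PER_YEAR = 365.25

# Diagnosis mixture: concept_id -> patient count in the emulated population.
TABLE1_COUNTS: dict[int, int] = {
    374915: 613, 4185733: 67, 4102345: 49, 4044080: 44, 4047888: 26,
    4046207: 24, 4043551: 4, 4044084: 4, 4046206: 3, 4041672: 1,
    4055361: 137, 4179936: 56, 376105: 44, 4046213: 38, 4267274: 34,
    4046210: 15, 4047897: 10, 4043413: 5, 4044225: 5,
    9990001: 12,
}

VPA, OXC, LTG, LEV, TPM = "valproic acid", "oxcarbazepine", "lamotrigine", "levetiracetam", "topiramate"
PB, ETX, RUF, PER, CLB = "phenobarbital", "ethosuximide", "rufinamide", "perampanel", "clobazam"

# Pathway mixtures keyed by subgroup label.  Lookup order for a patient:
# syndrome tag (LGS/CAE/BECTS) -> condition group -> "default".  Sequence
# probabilities imply the subgroup drug-resistance rate (fraction of mass on
# sequences of length >= 3).
DEFAULT_PATHWAY_MIXTURES: dict[str, dict[tuple[str, ...], float]] = {
    "LGS": {  # implied DRE 0.79
        (VPA, LTG, RUF): 0.25,
        (VPA, TPM, LTG, RUF): 0.20,
        (VPA, LEV, TPM, CLB): 0.14,
        (VPA, CLB, RUF, LTG, TPM): 0.10,
        (VPA, TPM, RUF, PER): 0.10,
        (VPA, LTG): 0.11,
        (VPA, TPM): 0.10,
    },
    "CAE": {  # implied DRE 0.071
        (VPA,): 0.55,
        (ETX,): 0.12,
        (VPA, LTG): 0.12,
        (VPA, ETX): 0.139,
        (VPA, LTG, ETX): 0.071,
    },
    "BECTS": {  # implied DRE 0.09
        (OXC,): 0.45,
        (VPA,): 0.20,
        (OXC, VPA): 0.15,
        (OXC, LEV): 0.11,
        (OXC, VPA, LEV): 0.09,
    },
    "focal": {  # implied DRE 0.236 (non-BECTS focal)
        (OXC,): 0.19,
        (VPA,): 0.15,
        (LTG,): 0.08,
        (OXC, VPA): 0.10,
        (VPA, OXC): 0.08,
        (OXC, LEV): 0.07,
        (VPA, LTG): 0.094,
        (OXC, VPA, LTG): 0.08,
        (VPA, OXC, LEV): 0.06,
        (OXC, LTG, LEV, TPM): 0.05,
        (VPA, LTG, TPM): 0.03,
        (OXC, LEV, TPM): 0.016,
    },
    "generalized": {  # implied DRE 0.229 (non-CAE/LGS generalized)
        (VPA,): 0.28,
        (VPA, LTG): 0.15,
        (LTG,): 0.08,
        (VPA, LEV): 0.10,
        (LEV,): 0.05,
        (VPA, TPM): 0.061,
        (PB, VPA): 0.05,
        (VPA, LTG, LEV): 0.10,
        (VPA, LTG, TPM, LEV): 0.07,
        (VPA, LEV, TPM): 0.059,
    },
    "default": {  # unclassified epilepsy; implied DRE 0.15
        (VPA,): 0.50,
        (LEV,): 0.20,
        (VPA, LEV): 0.15,
        (VPA, LEV, TPM): 0.15,
    },
}


@dataclasses.dataclass
class GeneratorConfig:
    """Study-condition parameters for the synthetic cohort.

    ``syndrome_mixture`` maps diagnosis concept_id to probability;
    ``pathway_mixtures`` maps a subgroup label (syndrome tag, condition
    group, or "default") to a distribution over ingredient-name sequences.
    ``p_dropout`` is the probability that a patient has one persistence
    window deliberately emptied.  ``year_drug_weights`` optionally reweights
    sequence choice by the first drug's per-calendar-year preference weight,
    emulating prescribing drift.
    """

    n_patients: int = 1000
    seed: int = 0
    calendar_start: date = date(2004, 1, 1)
    calendar_end: date = date(2017, 10, 31)
    p_male: float = 653 / 1192
    syndrome_mixture: dict[int, float] = dataclasses.field(
        default_factory=lambda: _normalize(TABLE1_COUNTS)
    )
    pathway_mixtures: dict[str, dict[tuple[str, ...], float]] = dataclasses.field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PATHWAY_MIXTURES.items()}
    )
    p_dropout: float = 0.2
    onset_age_mean: float = 8.3
    onset_age_sd: float = 5.0
    onset_age_range: tuple[float, float] = (0.1, 18.0)
    followup_years_mean: float = 6.5
    followup_years_sd: float = 3.2
    followup_years_range: tuple[float, float] = (2.0, 14.2)
    persistence_windows: tuple[tuple[int, int], ...] = DEFAULT_WINDOWS
    exposure_cadence_days: int = 60
    jitter_days: int = 15
    year_drug_weights: dict[int, dict[str, float]] | None = None

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not 0.0 <= self.p_dropout <= 1.0:
            raise ValueError("p_dropout must be in [0, 1]")
        if abs(sum(self.syndrome_mixture.values()) - 1.0) > 1e-9:
            raise ValueError("syndrome_mixture probabilities must sum to 1")
        for key, mix in self.pathway_mixtures.items():
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"pathway mixture {key!r} probabilities must sum to 1")
            for seq in mix:
                if len(seq) != len(set(seq)):
                    raise ValueError(f"pathway {seq} has repeated ingredients")


@dataclasses.dataclass
class GroundTruth:
    """Generator-side labels for one patient (the test oracle)."""

    person_id: int
    intended_in_cohort: bool
    true_sequence: tuple[int, ...]  # ingredient concept_ids, intended order
    true_syndrome: int              # diagnosis concept_id
    true_onset_age: float
    index_date: pd.Timestamp
    dropout_window: tuple[int, int] | None = None  # the emptied window, if any


def _normalize(counts: dict[int, int | float]) -> dict[int, float]:
    total = float(sum(counts.values()))
    return {k: v / total for k, v in counts.items()}


def config_from_file(path) -> GeneratorConfig:
    """Load a GeneratorConfig from a YAML or JSON file.

    Keys mirror the dataclass fields; pathway-mixture sequences are written
    as lists of ingredient names, syndrome-mixture keys as concept ids, and
    dates as ISO strings.  Omitted fields keep their defaults.
    """
    import json
    from pathlib import Path

    import yaml

    text = Path(path).read_text()
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    kwargs: dict = {}
    simple = {
        "n_patients", "seed", "p_male", "p_dropout", "onset_age_mean",
        "onset_age_sd", "followup_years_mean", "followup_years_sd",
        "exposure_cadence_days", "jitter_days",
    }
    for key, value in raw.items():
        if key in simple:
            kwargs[key] = value
        elif key in ("calendar_start", "calendar_end"):
            kwargs[key] = date.fromisoformat(value) if isinstance(value, str) else value
        elif key in ("onset_age_range", "followup_years_range"):
            kwargs[key] = tuple(value)
        elif key == "persistence_windows":
            kwargs[key] = tuple(tuple(w) for w in value)
        elif key == "syndrome_mixture":
            kwargs[key] = {int(k): float(v) for k, v in value.items()}
        elif key == "pathway_mixtures":
            kwargs[key] = {
                label: {tuple(seq): float(p) for seq, p in
                        ((entry["sequence"], entry["p"]) for entry in mix)}
                for label, mix in value.items()
            }
        elif key == "year_drug_weights":
            kwargs[key] = {int(y): dict(w) for y, w in value.items()}
        else:
            raise ValueError(f"unknown generator config key {key!r}")
    cfg = GeneratorConfig(**kwargs)
    cfg.validate()
    return cfg


def make_paperlike_config(n_patients: int, seed: int, **overrides) -> GeneratorConfig:
    """Config whose mixtures reproduce the emulated study's printed summary.

    The defaults of :class:`GeneratorConfig` already are those conditions;
    this constructor exists as the named entry point and accepts overrides
    (e.g. ``p_dropout=0``).
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    cfg = GeneratorConfig(n_patients=n_patients, seed=seed, **overrides)
    cfg.validate()
    return cfg


def _subgroup_label(concept_id: int, vocabulary: pd.DataFrame) -> str:
    row = vocabulary[vocabulary["concept_id"] == concept_id].iloc[0]
    tag = row["syndrome_tag"]
    group = row["condition_group"]
    if tag in ("LGS", "CAE", "BECTS"):
        return tag
    if group in ("focal", "generalized"):
        return group
    return "default"


def _mixture_for(config: GeneratorConfig, label: str) -> dict[tuple[str, ...], float]:
    if label in config.pathway_mixtures:
        return config.pathway_mixtures[label]
    return config.pathway_mixtures["default"]


def expected_stratum_dre(config: GeneratorConfig, vocabulary: pd.DataFrame,
                         kind: str = "epilepsy_type") -> dict[str, float]:
    """Injected drug-resistance rate per stratum, implied by the mixtures.

    Valid for ``kind`` in {"epilepsy_type", "syndrome", "all"}; onset age is
    drawn independently of the pathway, so age strata all share the overall
    rate.
    """
    def mixture_dre(mix: dict[tuple[str, ...], float]) -> float:
        return sum(p for seq, p in mix.items() if len(seq) >= 3)

    weights: dict[str, float] = {}
    dre_mass: dict[str, float] = {}
    for cid, p in config.syndrome_mixture.items():
        row = vocabulary[vocabulary["concept_id"] == cid].iloc[0]
        label = _subgroup_label(cid, vocabulary)
        if kind == "epilepsy_type":
            group = row["condition_group"]
            stratum = group if group in ("focal", "generalized") else "unclassified"
        elif kind == "syndrome":
            tag = row["syndrome_tag"]
            stratum = tag if tag in ("LGS", "CAE", "BECTS") else "none"
        elif kind == "all":
            stratum = "all"
        else:
            raise ValueError(f"unsupported kind {kind!r}")
        d = mixture_dre(_mixture_for(config, label))
        weights[stratum] = weights.get(stratum, 0.0) + p
        dre_mass[stratum] = dre_mass.get(stratum, 0.0) + p * d
    return {s: dre_mass[s] / weights[s] for s in weights}


def expected_pathway_probs(config: GeneratorConfig, vocabulary: pd.DataFrame
                           ) -> dict[tuple[str, ...], float]:
    """Marginal probability of each ingredient-name sequence over all patients."""
    out: dict[tuple[str, ...], float] = {}
    for cid, p in config.syndrome_mixture.items():
        mix = _mixture_for(config, _subgroup_label(cid, vocabulary))
        for seq, q in mix.items():
            out[seq] = out.get(seq, 0.0) + p * q
    return out


def _block_bounds(day: int, horizon: int = 730) -> tuple[int, int]:
    """Closed bounds of the 120-day block containing post-index *day* >= 1."""
    block = (day - 1) // 120
    return block * 120 + 1, min(block * 120 + 120, horizon)


def generate(config: GeneratorConfig) -> tuple[CdmTables, list[GroundTruth]]:
    """Draw a synthetic cohort; deterministic given the config's seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    vocabulary = default_vocabulary()
    name_to_id = {
        row["concept_name"]: int(row["concept_id"])
        for _, row in vocabulary[vocabulary["domain"] == "drug"].iterrows()
    }

    syn_ids = list(config.syndrome_mixture.keys())
    syn_probs = np.array([config.syndrome_mixture[c] for c in syn_ids])

    cal_start = pd.Timestamp(config.calendar_start)
    cal_end = pd.Timestamp(config.calendar_end)
    index_span_days = (cal_end - cal_start).days - 730
    if index_span_days < 0:
        raise ValueError("calendar span must cover at least 730 days")

    persons, obs_rows, exp_rows, cond_rows = [], [], [], []
    truths: list[GroundTruth] = []

    for pid in range(1, config.n_patients + 1):
        sex = "male" if rng.random() < config.p_male else "female"
        syndrome = int(rng.choice(len(syn_ids), p=syn_probs))
        syndrome_id = syn_ids[syndrome]

        lo, hi = config.onset_age_range
        a = (lo - config.onset_age_mean) / config.onset_age_sd
        b = (hi - config.onset_age_mean) / config.onset_age_sd
        onset_age = float(stats.truncnorm.rvs(
            a, b, loc=config.onset_age_mean, scale=config.onset_age_sd, random_state=rng))

        lo, hi = config.followup_years_range
        a = (lo - config.followup_years_mean) / config.followup_years_sd
        b = (hi - config.followup_years_mean) / config.followup_years_sd
        followup_years = float(stats.truncnorm.rvs(
            a, b, loc=config.followup_years_mean, scale=config.followup_years_sd,
            random_state=rng))

        index_date = cal_start + timedelta(days=int(rng.integers(0, index_span_days + 1)))
        birth_date = index_date - timedelta(days=int(round(onset_age * DAYS_PER_YEAR)))

        mixture = _mixture_for(config, _subgroup_label(syndrome_id, vocabulary))
        seqs = list(mixture.keys())
        probs = np.array([mixture[s] for s in seqs], dtype=float)
        if config.year_drug_weights:
            yw = config.year_drug_weights.get(index_date.year, {})
            probs = probs * np.array([yw.get(s[0], 1.0) for s in seqs])
            probs = probs / probs.sum()
        sequence_names = seqs[int(rng.choice(len(seqs), p=probs))]
        sequence_ids = tuple(name_to_id[n] for n in sequence_names)

        # Administrative censoring at the extract's calendar end, never below
        # the 730-day minimum the cohort requires.
        followup_days = max(
            730, min(int(round(followup_years * DAYS_PER_YEAR)), (cal_end - index_date).days)
        )
        prior_days = int(rng.integers(0, 366))
        prior_days = min(prior_days, (index_date - birth_date).days)
        obs_start = index_date - timedelta(days=prior_days)
        obs_end = index_date + timedelta(days=followup_days)

        # Exposure schedule: drug k starts at round(k*730/L) and repeats every
        # `cadence` days to day 730 (add-on semantics, all drugs co-continue).
        # The first exposure of each drug is unjittered so the realized
        # first-appearance order equals the intended sequence; later exposures
        # get +/- jitter clamped inside their 120-day block, so per-window
        # persistence is preserved by construction.
        L = len(sequence_ids)
        exposure_days: list[tuple[int, int]] = []  # (day, ingredient id)
        for k, cid in enumerate(sequence_ids):
            start = round(k * 730 / L)
            day = start
            first = True
            while day <= 730:
                d = day
                if not first and d >= 1:
                    j = int(rng.integers(-config.jitter_days, config.jitter_days + 1))
                    blo, bhi = _block_bounds(d)
                    d = min(max(d + j, blo), bhi)
                exposure_days.append((d, cid))
                first = False
                day += config.exposure_cadence_days

        intended = True
        dropout_window = None
        if rng.random() < config.p_dropout and config.persistence_windows:
            widx = int(rng.integers(0, len(config.persistence_windows)))
            wlo, whi = config.persistence_windows[widx]
            exposure_days = [(d, c) for d, c in exposure_days if not (wlo <= d <= whi)]
            intended = False
            dropout_window = (wlo, whi)

        persons.append({"person_id": pid, "sex": sex,
                        "birth_date": pd.Timestamp(birth_date)})
        obs_rows.append({"person_id": pid, "start_date": pd.Timestamp(obs_start),
                         "end_date": pd.Timestamp(obs_end)})
        for d, cid in sorted(exposure_days):
            exp_rows.append({
                "person_id": pid, "drug_concept_id": cid,
                "exposure_date": pd.Timestamp(index_date + timedelta(days=d)),
            })
        cond_rows.append({
            "person_id": pid, "condition_concept_id": syndrome_id,
            "condition_start_date": pd.Timestamp(index_date),
        })
        truths.append(GroundTruth(
            person_id=pid, intended_in_cohort=intended, true_sequence=sequence_ids,
            true_syndrome=syndrome_id, true_onset_age=onset_age,
            index_date=pd.Timestamp(index_date), dropout_window=dropout_window,
        ))

    if not persons:
        return CdmTables.empty(vocabulary), []
    tables = CdmTables(
        persons=pd.DataFrame(persons),
        observation_periods=pd.DataFrame(obs_rows),
        drug_exposures=pd.DataFrame(exp_rows),
        condition_occurrences=pd.DataFrame(cond_rows),
        vocabulary=vocabulary,
    )
    tables.validate()
    return tables, truths


def ground_truth_frame(truths: list[GroundTruth]) -> pd.DataFrame:
    """Ground truth as a DataFrame; sequences joined by '|', CSV-friendly."""
    return pd.DataFrame(
        [
            {
                "person_id": t.person_id,
                "intended_in_cohort": t.intended_in_cohort,
                "true_sequence": "|".join(map(str, t.true_sequence)),
                "true_syndrome": t.true_syndrome,
                "true_onset_age": round(t.true_onset_age, 4),
                "index_date": t.index_date.strftime("%Y-%m-%d"),
                "dropout_window": (
                    f"{t.dropout_window[0]}_{t.dropout_window[1]}" if t.dropout_window else ""
                ),
            }
            for t in truths
        ],
        columns=[
            "person_id", "intended_in_cohort", "true_sequence", "true_syndrome",
            "true_onset_age", "index_date", "dropout_window",
        ],
    )
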