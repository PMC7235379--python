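"""Minimal OMOP-CDM relational schema: tables, vocabulary, CSV I/O, validation.

The schema is the five-table core an OHDSI-style pathway analysis touches:
``person``, ``observation_period``, ``drug_exposure``, ``condition_occurrence``
and a flat ``concept`` vocabulary.  Deliberate simplifications (documented in
the methods note): one observation period per person, point drug exposures
(a prescription event, not an era), and an ingredient-level-only drug
vocabulary covering the ATC N03A anti-seizure medication class.

Files are comma-separated UTF-8 with a mandatory header row and ISO-8601
dates, so fixtures round-trip bit-exactly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

__all__ = [
    "CdmTables",
    "CdmValidationError",
    "default_vocabulary",
    "read_cdm",
    "write_cdm",
    "resolve_ingredient",
    "TABLE_FILES",
]


class CdmValidationError(ValueError):
    """Raised when a table bundle violates schema or referential integrity."""


#: file name stem -> required columns, in on-disk order
TABLE_FILES = {
    "person": ["person_id", "sex", "birth_date"],
    "observation_period": ["person_id", "start_date", "end_date"],
    "drug_exposure": ["person_id", "drug_concept_id", "exposure_date"],
    "condition_occurrence": ["person_id", "condition_concept_id", "condition_start_date"],
    "concept": ["concept_id", "concept_name", "domain", "drug_class", "condition_group", "syndrome_tag"],
}

_DATE_COLUMNS = {
    "person": ["birth_date"],
    "observation_period": ["start_date", "end_date"],
    "drug_exposure": ["exposure_date"],
    "condition_occurrence": ["condition_start_date"],
    "concept": [],
}

# Epilepsy diagnosis concepts: 10 focal, 9 generalized, 1 unclassified.
# The unclassified concept id is synthetic (the source vocabulary prints
# none for the unclassified group).
_EPILEPSY_CONCEPTS = [
    (374915, "Localization-related epilepsy, not otherwise specified", "focal", None),
    (4185733, "Benign epilepsy with centrotemporal spikes", "focal", "BECTS"),
    (4102345, "Temporal lobe epilepsy", "focal", None),
    (4044080, "Childhood occipital epilepsy (Panayiotopoulos type)", "focal", None),
    (4047888, "Frontal lobe epilepsy", "focal", None),
    (4046207, "Occipital lobe epilepsy (Gastaut type)", "focal", None),
    (4043551, "Epilepsy with continuous spike wave during slow-wave sleep", "focal", None),
    (4044084, "Supplementary motor area epilepsy", "focal", None),
    (4046206, "Parietal lobe epilepsy", "focal", None),
    (4041672, "Rasmussen syndrome", "focal", None),
    (4055361, "Generalized epilepsy, not otherwise specified", "generalized", None),
    (4179936, "Childhood absence epilepsy", "generalized", "CAE"),
    (376105, "West syndrome", "generalized", None),
    (4046213, "Lennox-Gastaut syndrome", "generalized", "LGS"),
    (4267274, "Juvenile myoclonic epilepsy", "generalized", None),
    (4046210, "Juvenile absence epilepsy", "generalized", None),
    (4047897, "Epilepsy with grand mal seizures on awakening", "generalized", None),
    (4043413, "Myoclonic astatic epilepsy", "generalized", None),
    (4044225, "Myoclonic absence epilepsy", "generalized", None),
    (9990001, "Epilepsy, unclassified", "unclassified", None),
]

# Ingredient-level ASM concepts (ATC N03A).  Ids are synthetic.
_ASM_INGREDIENTS = [
    (40001, "valproic acid"),
    (40002, "oxcarbazepine"),
    (40003, "lamotrigine"),
    (40004, "levetiracetam"),
    (40005, "topiramate"),
    (40006, "phenobarbital"),
    (40007, "rufinamide"),
    (40008, "perampanel"),
    (40009, "carbamazepine"),
    (40010, "clobazam"),
    (40011, "zonisamide"),
    (40012, "vigabatrin"),
    (40013, "ethosuximide"),
    (40014, "lacosamide"),
]


def default_vocabulary() -> pd.DataFrame:
    """Bundled concept table: 20 epilepsy diagnoses plus N03A ingredients."""
    rows = [
        {
            "concept_id": cid,
            "concept_name": name,
            "domain": "condition",
            "drug_class": None,
            "condition_group": group,
            "syndrome_tag": tag,
        }
        for cid, name, group, tag in _EPILEPSY_CONCEPTS
    ]
    rows += [
        {
            "concept_id": cid,
            "concept_name": name,
            "domain": "drug",
            "drug_class": "N03A_ingredient",
            "condition_group": None,
            "syndrome_tag": None,
        }
        for cid, name in _ASM_INGREDIENTS
    ]
    return pd.DataFrame(rows, columns=TABLE_FILES["concept"])


@dataclasses.dataclass
class CdmTables:
    """In-memory bundle of the five CDM tables.

    Each attribute is a :class:`pandas.DataFrame` with the columns listed in
    :data:`TABLE_FILES`; date columns hold ``datetime64`` values.
    """

    persons: pd.DataFrame
    observation_periods: pd.DataFrame
    drug_exposures: pd.DataFrame
    condition_occurrences: pd.DataFrame
    vocabulary: pd.DataFrame

    @classmethod
    def empty(cls, vocabulary: pd.DataFrame | None = None) -> "CdmTables":
        """Bundle with zero patients and the default vocabulary."""
        frames = {}
        for name, cols in TABLE_FILES.items():
            df = pd.DataFrame(columns=cols)
            for c in _DATE_COLUMNS[name]:
                df[c] = pd.to_datetime(df[c])
            frames[name] = df
        if vocabulary is None:
            vocabulary = default_vocabulary()
        return cls(
            persons=frames["person"],
            observation_periods=frames["observation_period"],
            drug_exposures=frames["drug_exposure"],
            condition_occurrences=frames["condition_occurrence"],
            vocabulary=vocabulary,
        )

    def _frames(self) -> dict[str, pd.DataFrame]:
        return {
            "person": self.persons,
            "observation_period": self.observation_periods,
            "drug_exposure": self.drug_exposures,
            "condition_occurrence": self.condition_occurrences,
            "concept": self.vocabulary,
        }

    def validate(self) -> None:
        """Raise :class:`CdmValidationError` listing every violation found.

        Checks: required columns, unique person/concept ids, at most one
        observation period per person, every foreign key resolvable, event
        dates after birth, drug exposures inside the observation period, and
        drug concepts resolvable to an N03A ingredient.
        """
        problems: list[str] = []
        for name, df in self._frames().items():
            missing = [c for c in TABLE_FILES[name] if c not in df.columns]
            if missing:
                problems.append(f"{name}: missing columns {missing}")
        if problems:
            raise CdmValidationError("; ".join(problems))

        dup = self.persons["person_id"][self.persons["person_id"].duplicated()]
        if len(dup):
            problems.append(f"person: duplicate person_id {sorted(dup.unique().tolist())}")
        dup = self.vocabulary["concept_id"][self.vocabulary["concept_id"].duplicated()]
        if len(dup):
            problems.append(f"concept: duplicate concept_id {sorted(dup.unique().tolist())}")

        multi = self.observation_periods["person_id"][
            self.observation_periods["person_id"].duplicated()
        ]
        if len(multi):
            problems.append(
                "observation_period: more than one period for person_id "
                f"{sorted(multi.unique().tolist())} (a single period per person is required)"
            )

        known_persons = set(self.persons["person_id"])
        known_concepts = set(self.vocabulary["concept_id"])
        fk_checks = [
            ("observation_period", self.observation_periods, "person_id", known_persons),
            ("drug_exposure", self.drug_exposures, "person_id", known_persons),
            ("drug_exposure", self.drug_exposures, "drug_concept_id", known_concepts),
            ("condition_occurrence", self.condition_occurrences, "person_id", known_persons),
        ]
        for table, df, col, universe in fk_checks:
            bad = df[~df[col].isin(universe)]
            for idx, row in bad.iterrows():
                problems.append(f"{table} row {idx}: dangling {col}={row[col]}")

        birth = self.persons.set_index("person_id")["birth_date"]
        for table, df, col in [
            ("observation_period", self.observation_periods, "start_date"),
            ("drug_exposure", self.drug_exposures, "exposure_date"),
            ("condition_occurrence", self.condition_occurrences, "condition_start_date"),
        ]:
            resolvable = df[df["person_id"].isin(known_persons)]
            b = resolvable["person_id"].map(birth)
            bad = resolvable[resolvable[col] < b]
            for idx, row in bad.iterrows():
                problems.append(f"{table} row {idx}: {col} precedes birth_date for person {row['person_id']}")

        op = self.observation_periods
        bad = op[op["start_date"] > op["end_date"]]
        for idx, row in bad.iterrows():
            problems.append(f"observation_period row {idx}: start_date after end_date")

        # Exposures must fall inside the person's observation period.
        if len(self.drug_exposures):
            spans = op.drop_duplicates("person_id").set_index("person_id")
            de = self.drug_exposures[self.drug_exposures["person_id"].isin(spans.index)]
            lo = de["person_id"].map(spans["start_date"])
            hi = de["person_id"].map(spans["end_date"])
            bad = de[(de["exposure_date"] < lo) | (de["exposure_date"] > hi)]
            for idx, row in bad.iterrows():
                problems.append(
                    f"drug_exposure row {idx}: exposure_date outside observation period "
                    f"for person {row['person_id']}"
                )

        drug_ok = set(
            self.vocabulary.loc[self.vocabulary["domain"] == "drug", "concept_id"]
        )
        bad = self.drug_exposures[
            self.drug_exposures["drug_concept_id"].isin(known_concepts)
            & ~self.drug_exposures["drug_concept_id"].isin(drug_ok)
        ]
        for idx, row in bad.iterrows():
            problems.append(
                f"drug_exposure row {idx}: concept {row['drug_concept_id']} is not a drug concept"
            )

        if problems:
            raise CdmValidationError("; ".join(problems))


def read_cdm(directory_path: str | Path, validate: bool = True) -> CdmTables:
    """Read the five CSV files from *directory_path* into a validated bundle.

    Raises ``FileNotFoundError`` naming the missing table file, and
    :class:`CdmValidationError` for unparseable dates or dangling keys.
    """
    directory = Path(directory_path)
    frames: dict[str, pd.DataFrame] = {}
    for name, cols in TABLE_FILES.items():
        path = directory / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing CDM table file: {name} (expected {path})")
        df = pd.read_csv(path, dtype={c: "object" for c in TABLE_FILES["concept"][3:]} if name == "concept" else None)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise CdmValidationError(f"{name}.csv: missing columns {missing}")
        for c in _DATE_COLUMNS[name]:
            try:
                df[c] = pd.to_datetime(df[c], format="%Y-%m-%d")
            except (ValueError, TypeError) as exc:
                raise CdmValidationError(f"{name}.csv column {c}: unparseable ISO-8601 date ({exc})") from exc
        if name == "concept":
            for c in ("drug_class", "condition_group", "syndrome_tag"):
                df[c] = df[c].where(df[c].notna(), None)
        frames[name] = df[cols]
    tables = CdmTables(
        persons=frames["person"],
        observation_periods=frames["observation_period"],
        drug_exposures=frames["drug_exposure"],
        condition_occurrences=frames["condition_occurrence"],
        vocabulary=frames["concept"],
    )
    if validate:
        tables.validate()
    return tables


def write_cdm(tables: CdmTables, directory_path: str | Path) -> None:
    """Write the bundle as five CSV files; ``read_cdm`` round-trips exactly."""
    tables.validate()
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)
    for name, df in tables._frames().items():
        out = df[TABLE_FILES[name]].copy()
        for c in _DATE_COLUMNS[name]:
            out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d")
        out.to_csv(directory / f"{name}.csv", index=False)


def resolve_ingredient(drug_concept_id: int, vocabulary: pd.DataFrame,
                       mapping: dict[int, int] | None = None) -> int:
    """Map a drug concept to its ingredient-level concept.

    The bundled vocabulary is ingredient-level only, so resolution is the
    identity; an optional *mapping* (e.g. branded product -> ingredient)
    is consulted first, mirroring how an RxNorm relationship table would.
    """
    if mapping and drug_concept_id in mapping:
        drug_concept_id = mapping[drug_concept_id]
    row = vocabulary[vocabulary["concept_id"] == drug_concept_id]
    if row.empty:
        raise KeyError(f"unknown drug concept_id {drug_concept_id}")
    if row.iloc[0]["domain"] != "drug":
        raise KeyError(f"concept_id {drug_concept_id} is not a drug concept")
    return int(drug_concept_id)


def ingredient_names(vocabulary: pd.DataFrame) -> dict[int, str]:
    """concept_id -> concept_name for every drug concept in the vocabulary."""
    drugs = vocabulary[vocabulary["domain"] == "drug"]
    return dict(zip(drugs["concept_id"].astype(int), drugs["concept_name"]))
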