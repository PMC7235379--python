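# Methods

## Data model

The package works over a minimal five-table OMOP-CDM slice. Two
simplifications are deliberate and enforced by validation:

* **One observation period per person.** Multi-period input is rejected with
  an explicit error rather than silently merged; the persistence design
  never needs more than the period containing the index event.
* **Point drug exposures.** A `drug_exposure` row is a prescription event on
  a single date. The persistence criterion ("at least one prescription in
  each window") only needs point events; drug-era construction (joining
  exposures into continuous treatment spans) is out of scope.

The bundled vocabulary is ingredient-level only: 14 ATC-N03A ASM
ingredients (valproic acid, oxcarbazepine, lamotrigine, levetiracetam,
topiramate, phenobarbital, rufinamide, perampanel, and six further common
ASMs) and 20 epilepsy diagnosis concepts in three groups (10 focal,
9 generalized, 1 unclassified), three of them tagged with syndromes (LGS,
CAE, BECTS). The unclassified diagnosis concept id (9990001) is synthetic.
`resolve_ingredient` accepts an optional product→ingredient mapping for
vocabularies that carry branded concepts; the bundled one does not.

Files are comma-separated UTF-8 with a header row and ISO-8601 dates, so
fixtures round-trip bit-exactly and `write_cdm ∘ read_cdm` is the identity.

## Cohort definition

* **Index date** = earliest ASM exposure in the person's history, day 0 of
  all window arithmetic. A person whose first-ever exposure falls after the
  age cap has *no* valid index (events are limited to the earliest per
  person); the builder does not search for a later qualifying exposure.
* **Age at index** is exact fractional years (days/365.25); the cap
  (default 18) is inclusive.
* **Follow-up**: the observation period must start at or before the index
  and end ≥ 730 days after it.
* **Diagnosis**: at least one epilepsy condition occurrence at *any* time
  relative to the index. The permissive reading avoids losing patients whose
  diagnosis was recorded only at a later visit.
* **Persistence**: every window in the (configurable) list must contain ≥ 1
  ASM exposure. Windows are closed integer day intervals; the default five
  windows start at day 121 because the index prescription itself covers the
  first 120 days. A stricter reading requiring a [1, 120] window is a single
  config edit.
* No wash-out period is applied: an EHR cannot see prescriptions issued
  elsewhere before the record begins, so a wash-out would be illusory.

`build_cohort(..., return_exclusions=True)` reports the first violated
criterion per excluded person (no exposure → age cap → follow-up →
diagnosis → first empty window), making the attrition cascade auditable.

## Sequences and drug resistance

A treatment sequence is the order-preserving de-duplication of a member's
in-window exposures: distinct ingredients in order of first exposure,
default window 730 days post-index (full follow-up via
`window_days=None`), capped at 20 ingredients. Substitution and add-on are
not distinguished — a known, accepted limitation of the pathway
representation.

Drug resistance is operationalized as **≥ 3 distinct ingredients** within
the sequencing window ("introduction of a third medication"), a surrogate
for the ILAE failure-of-two-adequate-trials definition. The threshold is a
parameter. Because the DRE class is exactly the "3+" bucket of the
ASM-count distribution, the identity
`pct(3+) = 100 − pct(1) − pct(2)` holds by construction up to the printed
one-decimal rounding.

`asm_frequency` uses **slot shares** by default: the denominator is the
total number of sequence positions over the cohort, so shares sum to 1. A
patient-share mode (fraction of patients whose pathway contains the drug)
is available; the choice matters only for interpretation, not ordering, in
all data we generate.

## Stratification and trend

When a patient carries several distinct epilepsy diagnoses, the classifying
concept is chosen by *most frequent → earliest start date → lowest concept
id*. The tie-breaking policy is a package decision (observational records
rarely state one); it is centralized in one helper so both the category and
the syndrome label use it identically.

Onset-age bins implement the ordinary-language reading of "under 4 /
between 4 and 13 / over 13" as [0, 4), [4, 13], (13, 18]. Each
stratification kind includes an explicit remainder stratum
("unclassified" / "none"), so strata always partition the cohort.

**Monotherapy-in-year**: a member contributes to (year, drug) iff they have
≥ 1 exposure to that drug and none to any other ASM ingredient within the
calendar year; a patient on two drugs that year contributes to neither.
Counts, not shares, are emitted: per-year denominators (active patients)
are ambiguous in a cohort whose members enter and leave calendar years at
different treatment phases.

The sunburst export is a prefix-tree aggregation of the pathway table with
`name`/`concept_id`/`n_patients`/`children` keys. A node's terminal count
(own minus children's sum) is the number of patients whose sequence ends
there, so flattening the tree reproduces the table exactly; the round trip
is property-tested.

## Synthetic-data generator

The generator emulates the structure of a 2004–2017 single-center pediatric
extract with ~1,200 qualifying patients:

| parameter | default | rationale |
|---|---|---|
| diagnosis mixture | proportional to the 20-concept counts (835 focal, 344 generalized, 12 unclassified of 1,191) | the emulated population's printed composition; the printed total participant count (1,192) exceeds the per-concept sum by one — the per-concept proportions are used |
| sex | male with p = 653/1192 | printed male:female ratio |
| onset age | truncated normal(8.3, 5.0) on [0.1, 18] years | printed mean ± SD at diagnosis; the floor keeps birth strictly before the index |
| follow-up | truncated normal(6.5, 3.2) on [2.0, 14.2] years, administratively censored at the calendar end but never below 730 days | printed follow-up summary |
| calendar span | 2004-01-01 .. 2017-10-31; index dates uniform with ≥ 730 days of span remaining | the emulated extract window |
| prescription cadence | one exposure per drug every 60 days to day 730, jitter ± 15 days clamped inside the exposure's 120-day block | guarantees each persistence window non-empty by construction |
| sequence timing | drug *k* of an *L*-drug pathway first appears at day round(k·730/L), unjittered, and co-continues | add-on semantics; first appearances are strictly ordered, so the realized sequence equals the intended one |
| dropout | probability 0.2; one persistence window chosen uniformly and emptied of all exposures | a *targeted* violation: the excluded patient's failure reason is known per patient and testable |
| pathway mixtures | per-subgroup distributions over ingredient sequences (lookup: syndrome tag → epilepsy category → default) | hand-constructed once so implied DRE rates approximate the emulated subgroup profile (focal ≈ 0.224, generalized ≈ 0.265, LGS 0.79, CAE 0.071, BECTS 0.09, overall ≈ 0.235) and slot shares rank valproic acid > oxcarbazepine > lamotrigine > levetiracetam > topiramate |
| calendar drift | off by default; optional per-year weight on the pathway's first drug | lets trend tests inject a known prescribing shift and check its recovery |

`expected_stratum_dre` and `expected_pathway_probs` compute the injected
values analytically from a config, so recovery tests compare pipeline
output to ground truth within 3 binomial standard errors rather than to any
external number.

**What the generator does not emulate** — and therefore what passing tests
do not show about real data: visit structure, dosing and formulation,
comorbidities, irregular prescription cadence (real refill gaps can fail
persistence without true discontinuation), correlation between onset age
and drug choice (e.g. phenobarbital in infants), diagnosis revisions over
time, and richer pathway diversity (a real cohort of this size shows
hundreds of distinct pathways; the mixtures here have a few dozen support
points, so the distinct-pathway count is structurally smaller). Recovery
results demonstrate the *pipeline's* correctness on data satisfying the
stated inclusion structure, not the clinical findings themselves.

## Numerical and determinism choices

* All randomness flows through one `numpy` Generator seeded from the
  config; identical config + seed ⇒ byte-identical tables, and the full
  `run_all` pipeline is byte-deterministic for fixed inputs.
* Pathway tables sort by descending count, then lexicographic ingredient
  names; trend and strata outputs sort by their natural keys. Percentages
  are printed to one decimal.
* Degenerate inputs: zero patients yield valid empty tables; empty strata
  are reported with zero counts; an empty cohort is a valid result, not an
  error. A cohort member with no in-window exposure is impossible by
  construction and raises an internal-consistency error.

## Problem sizes

Default verification runs use 200 randomized instances of ≤ 60 persons for
brute-force oracle comparison, n = 300 for constructive ground-truth
recovery, n = 2,000 for mixture recovery (3-SE bands), and ≥ 1,000
property-test cases for the structural invariants. The acceptance script
generates 1,489 patients so the expected post-dropout cohort matches the
emulated study's ≈ 1,191.
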