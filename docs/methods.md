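# Methods

## The rule and its unit of evaluation

The engine evaluates the five-trigger rule once per opioid/benzodiazepine
prescription initiation, at the prescription's `written_at` instant — the
point where the drug has been chosen but the order is not yet complete.
Encounter-level statistics (a *prescribing encounter* is any encounter with
≥ 1 such prescription) are derived afterwards by unioning the criteria met
across an encounter's prescriptions. Both tallies — per prescription and per
encounter — are reported with explicit denominators, because the two
denominators differ whenever an encounter carries more than one prescription
and alert-burden discussions are meaningless without saying which one is in
use.

An alert fires iff at least one criterion is met. SILENT and LIVE modes run
identical evaluations; LIVE additionally renders a text payload that lists
only the met criteria (canonical order: early refill, ED/UC onsite
treatment, prescription history, overdose, toxicology) with their evidence,
and the two dispositions (continue / cancel). Prescriber responses are
modeled as an optional field and never filled by this package; analyzing
prescriber behavior is out of scope.

## Temporal conventions

* Timestamps are ISO-8601 in files, normalized to UTC in memory; naive
  inputs are read as UTC. A "day" is exactly 86,400 s.
* Every windowed lookback of width *W* is the half-open interval
  [*t* − *W*, *t*): closed below, open above, so events at the evaluation
  instant itself are excluded — "previous 30 days" means strictly previous.
  Overdose and toxicology lookbacks are lifetime (strictly before *t*).
* Consequence at *t* itself: a co-prescription written at the same instant
  (e.g. an opioid and a benzodiazepine ordered together) has elapsed time 0,
  so it *does* qualify as an early refill for its sibling (remaining
  fraction 1.0), but does *not* count toward the 30-day prescription-history
  window, which is open at *t*. Both follow directly from the definitions
  above; the early-refill definition is `0 ≤ elapsed < duration`, and the
  window is [*t* − 30 d, *t*).

## Trigger semantics

* **Early refill.** Prior prescriptions of *either* class are considered:
  both classes are the rule's subject and a cross-class early refill is
  equally concerning. The remaining fraction uses continuous elapsed time;
  the threshold comparison is strict (">50 %"), implemented as
  `remaining > threshold + 1e-12` so that a remaining fraction that equals
  the threshold in exact arithmetic (e.g. 3 days remaining of a 10-day
  supply against 0.30, where binary floats give 0.30000000000000004) does
  not fire. Prescriptions with missing or non-positive days-of-supply are
  skipped and surfaced as evidence warnings rather than guessed at.
* **ED/UC onsite treatment.** Distinct qualifying encounters are counted:
  facility ED or urgent care, disposition not ADMITTED ("not including
  visits leading to admission"), window as above, at least one opioid
  administration linked to the encounter. The index prescription's own
  encounter never counts — the criterion reads as history.
* **Prescription history.** Every prescription of either class counts once,
  including several written within one prior encounter (they are distinct
  initiations); the index prescription is excluded.
* **Overdose.** Modeled as a boolean on the encounter; the source EMR's
  encoding of overdose presentations is not specified anywhere usable, so a
  flag at the encounter level is the minimal faithful representation.
* **Toxicology.** Evidence lists every positive analyte, so one patient can
  contribute to several analyte sub-rows of the surveillance table.

Monotonicity is a design invariant: relaxing any threshold
(remaining-fraction down, minimum counts down) can only add met triggers on
a fixed store, hence flagged sets nest and "additional patients captured" is
non-negative in the relaxing direction. The tuning module reports both
encounter and distinct-patient counts, with patients as the headline unit.

## Trigger thresholds

| parameter | default (final) | initial profile | units |
|---|---|---|---|
| remaining_fraction_threshold | 0.50 | 0.30 | fraction of supply |
| min_ed_uc_visits | 2 | 3 | visits |
| ed_uc_window_days | 30 | 30 | days |
| min_prescriptions | 3 | 3 | prescriptions |
| rx_window_days | 30 | 30 | days |

Both profiles ship as YAML under `rxalert/profiles/`. No alert-rate
objective is optimized anywhere: the sweep tabulates burden-vs-capture
trade-offs and leaves the threshold decision to its users.

## Surveillance report

Age bands (<18, 18–64, ≥65) use completed calendar years at the encounter
date. Facility buckets: ED/Urgent Care; Inpatient Discharge; Outpatient
including phone calls; Other. Phone encounters are *excluded* from the
"all encounters" alert-rate denominator (phone contacts are not reliably
documented as encounters, so that denominator would be fiction) but phone
prescribing encounters *are* counted in the outpatient bucket. Analyte
sub-rows may overlap and need not sum to the toxicology parent row. All
percentages are round-half-up at 2 decimal places, computed in decimal
arithmetic — this convention reproduces every published percentage of the
source surveillance table exactly from its printed counts, which the
acceptance suite asserts cell by cell. A report built without a backing
store (e.g. from externally supplied counts) omits the all-encounter and
per-facility rates rather than inventing denominators.

## Synthetic cohort generator

The generator emulates the *structure* real silent surveillance needs:
patients with mixed risk profiles, encounters across facility types,
prescriptions tied to encounters, onsite administrations, toxicology
results, and pre-period history deep enough for 30-day lookbacks.

* Four archetypes — BASELINE (82 %), FREQUENT_UTILIZER (9 %),
  SUBSTANCE_USE (7 %), OVERDOSE_HISTORY (2 %) by default. Frequent
  utilizers get a higher encounter rate (3.5 vs 0.6 per 30 d) and an
  ED/UC-heavy facility mix; substance-use patients get positive screens per
  analyte (BAC 0.35, cocaine 0.30, marijuana 0.60, once per history);
  overdose-history patients get one overdose presentation before the
  surveillance period.
* Encounters arrive as a homogeneous Poisson process per patient over the
  surveillance period (default 30 d, anchored at 2015-04-01 UTC for
  reproducibility) plus a 90-day pre-period; prescriptions are written at
  the encounter instant; days-of-supply is uniform on [5, 30]; drug-class
  mix at a prescribing encounter is opioid-only 0.73 / benzo-only 0.23 /
  both 0.04; ED/UC admission probability 0.15; onsite opioid administration
  probability 0.30.
* Determinism: one `numpy` child seed per patient, spawned from the master
  seed via `SeedSequence` in a fixed documented order (demographics and
  archetypes first, then per-patient event streams), so identical configs
  give byte-identical serialized logs regardless of unrelated refactoring.

Defaults were chosen so that the five criterion prevalences land at the
same order of magnitude as a large mixed acute/ambulatory system (early
refill the most common trigger at roughly 15–20 % of prescribing
encounters, overdose history the rarest at a few percent); matching any
particular system's published rates exactly is *not* a generator contract,
and the archetype joint distribution of criteria is a free modeling choice —
no patient-level joint distribution exists to emulate. What the generator
does **not** model: diagnoses, comorbidities, demographic risk factors,
drug names and doses, morphine-equivalents, multi-pharmacy/multi-prescriber
behavior, seasonal or weekday structure, and any correlation between
toxicology timing and encounters. Tests passing on this cohort therefore
demonstrate the *logic* (window arithmetic, exclusions, unions, nesting,
conservation, determinism), not epidemiological realism of the rates.

## Problem sizes and runtime choices

The test suite and acceptance script use cohorts of 400–5,000 patients
(oracle equivalence over ≥ 1,000 patients, monotonicity and conservation on
5,000), sizes at which every brute-force oracle comparison and the full
pipeline complete in seconds while still exercising thousands of
prescription evaluations; the published-table arithmetic check runs on the
full 61,747 printed encounter counts since it is pure counting.

## Degenerate inputs and errors

Empty stores, empty periods, and unknown patients in window queries return
empty results, not errors. Zero-denominator percentages render as "0.00"
in an all-empty report, while `format_percent` itself rejects a zero
denominator. Unknown enum values in event logs are rejected with the line or
row and field named — silent coercion would corrupt surveillance
denominators. Dangling cross-references fail store validation listing the
offending ids; a missing days-of-supply is a warning (the early-refill
evaluator skips such prescriptions) rather than an error.

## Known limitations

* The event schema is deliberately minimal: no HL7/FHIR structures, no EMR
  integration, no pop-up UI; the alert payload is plain text.
* A single health system's record is the implicit scope — there is no
  cross-system or prescription-monitoring-program linkage, so triggers see
  only what the store contains.
* Encounter-level union reporting treats criteria as exchangeable; no
  weighting or severity ordering is attempted.
* The early-refill trigger assumes linear consumption of days-of-supply;
  dose changes and as-needed regimens are invisible to it.
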