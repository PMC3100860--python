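# Methods

## Scope and model

`periorisk` implements functional-diagram periodontal risk assessment: each
of a patient's clinical parameters is coded to an ordinal axis score 0–5,
the scores are placed on the radial axes of a radar chart with concentric
low/moderate/high zones, and the patient's overall category follows from
counting how many axes fall in each zone. Two models are implemented over
one shared coding system:

* **modified8** — eight axes: bleeding on probing (BOP), pocket areas
  >5 mm, tooth loss, smoking, attachment-loss/age ratio, glycemic status,
  dental-status/systemic-factors interplay, background characteristics
  (socioeconomic status + stress);
* **lt2003** — the six-axis Lang–Tonetti-style predecessor: the same
  clinical axes without the glycemic and background additions, applied to
  identical raw measurements.

The model is retrospective: it summarises current and historical status,
and makes no claim about future disease progression.

## Coding bands and gap closure

The published coding bands leave small gaps between adjacent rows (e.g.
BOP "<4" followed by "5–9"; counts "7–8" followed by ">9"). Bands are made
total and non-overlapping by treating each printed upper edge as inclusive
and extending it to the next band's floor: BOP percent bands become
0, (0,4], (4,9], (9,16], (16,25], >25; the count bands become 0, 1–2, 3–4,
5–6, 7–8, ≥9; AL/age becomes 0, (0,0.25], …, (0.75,1], >1. This preserves
every printed anchor, and makes each scorer a total, monotone,
single-valued step function — properties the test suite verifies by
exhaustive integer sweeps (counts 0–40) and 0.01-step grids over the
continuous ranges.

Interpretive conventions, each isolated in one scorer so it can be swapped:

* **BOP** is percent of probed sites bleeding (the bare table numbers are
  read as percentages, consistent with the Lang–Tonetti lineage);
  "generalized BOP" is encoded as >25% (score 5).
* **Glycemic status** accepts any consistently banded glycemic measurement
  in mg/dL; the underlying assay (fasting vs. random glucose) is the
  caller's responsibility.
* **AL/age** is taken as a precomputed ratio; when attachment loss and age
  are supplied separately the ratio is their direct quotient, with the
  numerator's unit left to the caller.
* **Background axis**: no published coding exists for socioeconomic status
  and stress, so the package fixes Kuppuswamy class I…V → 0…4, +1 under
  high stress, capped at 5 — an even spread of the five-class scale over
  the axis with stress as a one-step modifier. This is a package
  convention, documented here and confined to `score_background`.
* **Dental–systemic code** (0 healthy … 5 severe with tooth morbidity) is
  recorded directly on the patient record rather than derived from
  free-text history.

Record invariants mirror the study's inclusion criteria: age 30–60 years;
at most 12 missing teeth (≥20 functional teeth on a 32-tooth baseline).

## Classification rules

Scores map to zones low (0–1), moderate (2–3), high (4–5) — an even split
of the 0–5 scale across the three printed diagram zones, isolated in
`risk_area_of`. With m = moderate-zone and h = high-zone axis counts:

* modified8: **high** iff h ≥ 2; else **low** iff m + h ≤ 2; else
  **moderate**.
* lt2003: **high** iff h ≥ 2; else **low** iff m + h ≤ 1; else
  **moderate**.

The published counting clauses for the eight-axis model are neither
exhaustive nor mutually exclusive as printed (a vector with two high axes
satisfies both the low clause "at most 2 parameters in moderate and high"
and the high clause). The completion above applies precedence
high ≻ low ≻ moderate; it honours every printed clause, is total and
deterministic, and is monotone in each axis. "At most 2 in moderate and
high" is read as the combined count m + h. The six-axis rule is not
reprinted with the modified model; the classic counting form of its source
model is adopted. Both rules are functions of (m, h) only and hence
permutation-invariant; the suite checks them by exhaustive enumeration
(all 6^6 six-axis vectors through the object API; all 6^8 eight-axis
vectors vectorised through the same rule table, plus a 10^5 random sample
through the object API).

Polygon area is computed by the shoelace formula over vertices at radius =
score, axis 0 pointing up, axes clockwise in canonical order; uniform
vectors match the regular-polygon closed form (n/2)·r²·sin(2π/n) to 1e-6
relative. The area is reported as a severity diagnostic only: the source
material mentions area-based categorisation but gives no thresholds or
normalisation, so categorisation here is driven solely by the zone-count
rules.

## Functional diagram

Zone annuli are drawn with boundaries at radii 1.5 and 3.5, so each
integer score sits strictly inside its zone. SVG is the default output
(PNG supported); a fixed hash salt and suppressed date metadata make SVG
output byte-reproducible, which the tests exploit by hashing two renders.
Rendering is a pure output stage and never feeds back into classification.

## Synthetic cohort

The generator emulates the study conditions of a 30-patient hospital
cohort of confirmed diabetics with generalized BOP: 12 current and 4
former smokers; 15 patients (50%) with pockets >5 mm at 7–8 areas and 10
(35% rounded to the nearest feasible count of 30) at 5–6 areas; 14 (47%)
with moderate attachment loss mapped to AL/age ∈ (0.25, 0.75] and 3 (10%)
severe (>1); 10 (35%) with 7–8 missing teeth; socioeconomic status massed
on the lower Kuppuswamy classes (default weights 0/.05/.15/.45/.35 for
I–V). Where printed counts and percentages disagree (46% of 30 ≠ 12), the
counts win; percentage-only marginals are rounded to feasible counts once
and fixed in the default config.

Mechanics: each categorical marginal is met **exactly** by building a
deterministic label list and applying an independent seeded shuffle;
continuous values are then drawn uniformly within the assigned band
(BOP ∈ (25, 100]; glycemic ∈ [110, 180] mg/dL so every patient scores ≥2
on the glycemic axis, encoding "confirmed diabetic"; ages uniform 30–60;
cigarettes/day uniform 2–25 for current smokers). Patients without an
elevated pocket/tooth-loss assignment draw from the residual low bands.
Because all patients are diabetic, the dental–systemic code is sampled
from {3, 4, 5} (weights 0.6/0.3/0.1) — diabetes is an endocrine modifier
of periodontal status, the code-3 description. Stress is Bernoulli(0.5).
Default seed: 42. Cohorts are a pure function of (config, seed) down to
CSV bytes.

What the generator does **not** emulate: any joint structure between
marginals (the attribute shuffles are independent — whether the severe
attachment-loss patients are also the high-pocket patients is unknowable
from published information), within-band distributions beyond uniform, and
the original per-patient data. Consequently the pipeline's category
distributions on synthetic cohorts need not — and do not — match the
original study's headline 13/10/7 and 20/5/5 splits; the tested contract
is the report shape (distributions sum to cohort size, contingency margins
consistent) plus the per-table and per-rule properties above. With the
default all-diabetic, all-generalized-BOP marginals most synthetic
patients carry several non-low axes, so the synthetic cohort skews toward
high risk under both models.

## Numerical and interface choices

* All scorers validate their domain and raise `ValidationError` carrying
  the field, offending value and (in record context) patient id; CSV
  errors add the line number. No record is silently dropped.
* Band edges are compared with plain floating-point `<=` against the
  printed decimal edges; scores are exact integers throughout, so no
  tolerance enters classification.
* CSV I/O uses the record field names as header, lowercase categorical
  tokens, and `true`/`false` stress flags; cigarettes/day may be empty
  only for non-current smokers. Python float repr round-trips, so
  read(write(cohort)) == cohort exactly.
* Reports serialise with sorted keys and fixed indentation; re-running on
  the same inputs yields identical bytes. The provenance block carries the
  cohort SHA-256, model list, seed and config.

## Problem sizes

The default test suite enumerates all 46 656 six-axis vectors through the
object API and all 1 679 616 eight-axis vectors through the vectorised
rule path, samples 10^5 vectors through the object-level classifier, and
uses 10^4 random pairs for area monotonicity — a few seconds end to end.
The acceptance script evaluates single table lookups, 9-vector
enumerations for the trigger thresholds, and one 30-patient cohort.

## Known limitations

* The background-axis coding and the zone split of the 0–5 scale are
  package conventions (no published tables exist); both are isolated in
  single functions for replacement.
* Glycemic banding assumes a mg/dL glucose-like measurement; no HbA1c
  conversion is provided.
* The polygon area is order-dependent for non-uniform vectors; the
  canonical axis order fixed in each `ModelSpec` defines it.
* No hypothesis testing between models is performed, matching the
  descriptive design of the underlying study.
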