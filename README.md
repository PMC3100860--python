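# periorisk

Multi-axis **periodontal risk assessment** (PRA) for adult clinical cohorts:
a banded coding engine that maps chairside measurements onto ordinal axis
scores, a rule-based classifier that assigns each patient a low / moderate /
high risk category, a functional-diagram (radar-chart) renderer, a seeded
synthetic-cohort generator with exact marginal counts, and an end-to-end
study pipeline that compares an eight-parameter model against its
six-parameter Lang–Tonetti-style predecessor.

## Who this is for

Dental public-health researchers and biostatisticians who want a tested,
scriptable implementation of functional-diagram risk assessment — for
auditing the coding and counting rules, for method comparison on the same
patients, and for teaching. It is a retrospective risk-stratification tool,
not a prognostic model.

## The model

Each clinical parameter *p* is coded onto an ordinal axis score
*s_p ∈ {0,…,5}* by fixed bands (score 0 is the healthy anchor):

| score | BOP % | PD>5 mm areas | teeth lost | smoking/day | AL/age | glycemic mg/dL |
|---|---|---|---|---|---|---|
| 0 | 0 | 0 | 0 | non-smoker | 0 | <102 |
| 1 | ≤4 | 1–2 | 1–2 | former | ≤0.25 | 102–109 |
| 2 | ≤9 | 3–4 | 3–4 | <10 | ≤0.5 | 110–117 |
| 3 | ≤16 | 5–6 | 5–6 | 10–19 | ≤0.75 | 118–125 |
| 4 | ≤25 | 7–8 | 7–8 | 20 | ≤1 | 126–133 |
| 5 | >25 | ≥9 | ≥9 | >20 | >1 | >133 |

Two further axes complete the eight-parameter model: a 0–5
dental-status/systemic-factors interplay code (used as-is) and a background
axis combining Kuppuswamy socioeconomic class I–V with a stress flag
(class → 0–4, +1 under high stress, capped at 5). The six-axis comparator
drops the glycemic and background axes.

Scores fall into diagram zones — low (0–1), moderate (2–3), high (4–5) —
and with *m* = #moderate-zone axes, *h* = #high-zone axes:

- **modified 8-axis rule:** high if *h* ≥ 2; else low if *m + h* ≤ 2; else
  moderate.
- **6-axis comparator rule:** high if *h* ≥ 2; else low if *m + h* ≤ 1;
  else moderate.

The functional diagram places vertex *k* at radius *s_k* on equally spaced
axes; the shoelace polygon area (equal to (n/2)·r²·sin(2π/n) for uniform
score *r*) is reported as a severity diagnostic.

## Worked example

```python
from periorisk import PatientRecord, build_model_spec, classify, score_patient

patient = PatientRecord(
    patient_id="demo-02", age=52, bop_extent=40.0, pockets_over_5mm=9,
    teeth_lost=5, smoking_status="current", cigarettes_per_day=15,
    al_age_ratio=0.6, glycemic_value=140.0, dental_systemic_status=4,
    ses_class="V", high_stress=True)

for model_id in ("modified8", "lt2003"):
    vector = score_patient(patient, build_model_spec(model_id))
    r = classify(vector)
    print(f"{model_id}: category={r.category} moderate_axes={r.n_moderate_axes} "
          f"high_axes={r.n_high_axes} polygon_area={r.polygon_area:.2f}")
```

prints

```
modified8: category=high moderate_axes=3 high_axes=5 polygon_area=48.79
lt2003: category=high moderate_axes=3 high_axes=3 polygon_area=38.11
```

Five high-zone axes (40% BOP, nine deep-pocket areas, 140 mg/dL glycemia,
severe dental-systemic code, lowest-SES stressed background) put this
patient firmly in the high-risk category under both models; the larger
eight-axis polygon reflects the extra systemic burden the comparator does
not see. More narrative scripts live in `examples/` (scoring, cohort
generation, the full study pipeline, diagram rendering), and a thin CLI
wraps the same functions:

```bash
periorisk generate --seed 42 --out cohort.csv
periorisk report cohort.csv --model both --out report/ --render-diagrams
```

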