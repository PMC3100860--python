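"""Score one patient's clinical measurements onto the eight diagram axes."""

from periorisk import PatientRecord, build_model_spec, score_patient

# a moderate-severity diabetic patient, current light smoker
patient = PatientRecord(
    patient_id="demo-01",
    age=48,
    bop_extent=30.0,            # percent of probed sites bleeding
    pockets_over_5mm=6,         # areas with probing depth > 5 mm
    teeth_lost=3,
    smoking_status="current",
    cigarettes_per_day=8,
    al_age_ratio=0.4,           # attachment loss / age
    glycemic_value=120.0,       # mg/dL
    dental_systemic_status=3,   # endocrine modifier of periodontal status
    ses_class="IV",
    high_stress=True,
)

vector = score_patient(patient, build_model_spec("modified8"))
for axis, score in zip(vector.axis_names, vector.scores):
    print(f"{axis:>16}: {score}")

# Each axis score is an ordinal 0 (healthy anchor) to 5 (most severe band);
# e.g. 30% BOP falls in the >25 band (score 5) and a glycemic value of
# 120 mg/dL falls in the 118-125 band (score 3).
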