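"""Classify one patient under the 8-axis model and the 6-axis comparator."""

from periorisk import (PatientRecord, build_model_spec, classify,
                       score_patient)

patient = PatientRecord(
    patient_id="demo-02", age=52, bop_extent=40.0, pockets_over_5mm=9,
    teeth_lost=5, smoking_status="current", cigarettes_per_day=15,
    al_age_ratio=0.6, glycemic_value=140.0, dental_systemic_status=4,
    ses_class="V", high_stress=True)

for model_id in ("modified8", "lt2003"):
    vector = score_patient(patient, build_model_spec(model_id))
    result = classify(vector)
    print(f"{model_id}: category={result.category} "
          f"moderate_axes={result.n_moderate_axes} "
          f"high_axes={result.n_high_axes} "
          f"polygon_area={result.polygon_area:.2f}")

# The category is decided by counting axes per diagram zone (low 0-1,
# moderate 2-3, high 4-5): two or more high-zone axes force "high" under
# both rules. The polygon area is a diagnostic summary of overall severity,
# not a classification input.
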