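import pytest

from periorisk import (CohortConfig, PatientRecord, build_model_spec,
                       generate_cohort)


@pytest.fixture(scope="session")
def modified8():
    return build_model_spec("modified8")


@pytest.fixture(scope="session")
def lt2003():
    return build_model_spec("lt2003")


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortConfig())


@pytest.fixture
def healthy_patient():
    """All axes at the score-0 anchor."""
    return PatientRecord(
        patient_id="healthy", age=35, bop_extent=0.0, pockets_over_5mm=0,
        teeth_lost=0, smoking_status="nonsmoker", cigarettes_per_day=0,
        al_age_ratio=0.0, glycemic_value=95.0, dental_systemic_status=0,
        ses_class="I", high_stress=False)
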