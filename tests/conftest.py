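import numpy as np
import pytest

from clical.cohort_io import (LesionTreatment, PatientRecord, SbrtCourse,
                              SurvivalOutcome)


def outcomes(pairs):
    """[(time, event), ...] -> [SurvivalOutcome, ...]"""
    return [SurvivalOutcome(float(t), bool(e)) for t, e in pairs]


def make_record(pid="P1", age=50, sex="male", ps=0, primaries=1, cea=2.0,
                mets=2, lesions=((17.0, 3, "lung"),), all_treated=True,
                other_ablative=False, ttr=(7.0, True), os=(30.0, False)):
    return PatientRecord(
        patient_id=pid, age=age, sex=sex, performance_status=ps,
        n_crc_primaries=primaries, cea=cea, n_active_mets=mets,
        course=SbrtCourse(
            lesions=tuple(LesionTreatment(organ_site=site, dose_per_fraction=d,
                                          n_fractions=n)
                          for d, n, site in lesions),
            all_active_mets_treated=all_treated,
            other_ablative_therapy_covers_rest=other_ablative),
        ttr=None if ttr is None else SurvivalOutcome(*ttr),
        os=None if os is None else SurvivalOutcome(*os),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
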