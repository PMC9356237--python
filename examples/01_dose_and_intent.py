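"""Dose conversion and treatment-intent classification.

Converts two common SBRT fractionation schedules to biologically effective
dose (BED, α/β = 10 Gy) and classifies the intent of two example courses.
"""

from clical import bed, central_dose_bed, classify_intent, round_half_up
from clical.cohort_io import LesionTreatment, PatientRecord, SbrtCourse

for n, d in [(8, 7.0), (3, 17.0), (5, 8.0)]:
    value = bed(n, d)
    print(f"{d:g} Gy x {n}: physical {n * d:g} Gy -> "
          f"BED {value:.1f} Gy (displayed {round_half_up(value)} Gy)")
print(f"central BED of the modal schedule (1.5x convention): "
      f"{central_dose_bed(138.0):.0f} Gy")

def course(schedules, all_treated):
    return PatientRecord(
        patient_id="demo", age=62, sex="male", performance_status=0,
        n_crc_primaries=1, cea=3.0, n_active_mets=len(schedules),
        course=SbrtCourse(
            lesions=tuple(LesionTreatment("lung", d, n) for d, n in schedules),
            all_active_mets_treated=all_treated))

# every lesion >= 95 Gy BED and the whole tumour burden covered -> curative
print("2 lesions at 17 Gy x 3, all mets treated:",
      classify_intent(course([(17.0, 3), (17.0, 3)], True)))
# a sub-threshold lesion (8 Gy x 5 = 72 Gy BED) makes the course palliative
print("1 lesion at 8 Gy x 5, all mets treated:  ",
      classify_intent(course([(8.0, 5)], True)))
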