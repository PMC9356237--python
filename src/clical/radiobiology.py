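"""Linear-quadratic dose conversion and treatment-intent classification.

SBRT prescriptions with different fractionation schedules are compared on the
biologically effective dose scale of the linear-quadratic model,

    BED = n·d·(1 + d / (α/β)),

with n the number of fractions, d the dose per fraction (Gy) and α/β the
tissue-specific fractionation sensitivity, taken as 10 Gy for tumour.
Prescribing to the 65–70 % covering isodose produces an inhomogeneous dose
distribution whose central maximum is about 1.5× the prescription dose; the
same 1.5 factor is applied on the BED scale to quote central doses (a
convention, not the LQ transform of the central physical dose — see the
methods note).

A course is *curative in intent* when every treated lesion receives a
prescription BED of at least 95 Gy (the benchmark being the 7 Gy × 8 schedule,
BED 95.2 Gy) **and** all active metastases in the body are ablated, by SBRT or
by another ablative modality.  Anything less — a sub-threshold dose on any
lesion, or untreated residual disease — is palliative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .cohort_io import PatientRecord
from .errors import DomainError, IntentClassificationError

__all__ = [
    "RadiobiologyParams",
    "DEFAULT_PARAMS",
    "bed",
    "round_half_up",
    "central_dose_bed",
    "classify_intent",
    "classify_local_failure",
]

CURATIVE = "curative"
PALLIATIVE = "palliative"

#: relative growth in longest diameter defining local failure
LOCAL_FAILURE_GROWTH = 0.20


@dataclass(frozen=True)
class RadiobiologyParams:
    """Dose-conversion constants.

    alpha_beta : Gy, tumour fractionation sensitivity (default 10).
    curative_bed_threshold : Gy BED₁₀ separating ablative from palliative
        prescriptions (default 95, compared on the *unrounded* BED).
    central_dose_factor : ratio of central maximum to prescription dose when
        prescribing to the covering isodose (default 1.5).
    """

    alpha_beta: float = 10.0
    curative_bed_threshold: float = 95.0
    central_dose_factor: float = 1.5

    def __post_init__(self) -> None:
        if not self.alpha_beta > 0:
            raise DomainError("alpha_beta must be > 0")
        if not self.curative_bed_threshold > 0:
            raise DomainError("curative_bed_threshold must be > 0")
        if not self.central_dose_factor >= 1:
            raise DomainError("central_dose_factor must be >= 1")


DEFAULT_PARAMS = RadiobiologyParams()


def bed(n_fractions: int, dose_per_fraction: float,
        params: RadiobiologyParams = DEFAULT_PARAMS) -> float:
    """Biologically effective dose n·d·(1 + d/(α/β)), unrounded, in Gy."""
    if n_fractions < 1:
        raise DomainError(f"n_fractions must be >= 1, got {n_fractions}")
    if not dose_per_fraction > 0:
        raise DomainError(f"dose_per_fraction must be > 0, got {dose_per_fraction}")
    d = float(dose_per_fraction)
    return n_fractions * d * (1.0 + d / params.alpha_beta)


def round_half_up(x: float) -> int:
    """Round to integer Gy with halves up (95.2 → 95, 76.5 → 77) for display."""
    return int(math.floor(x + 0.5))


def central_dose_bed(prescription_bed: float,
                     params: RadiobiologyParams = DEFAULT_PARAMS) -> float:
    """Central-target BED quoted as ``central_dose_factor ×`` the prescription BED."""
    if prescription_bed < 0:
        raise DomainError("prescription_bed must be >= 0")
    return params.central_dose_factor * prescription_bed


def classify_intent(record: PatientRecord,
                    params: RadiobiologyParams = DEFAULT_PARAMS) -> str:
    """Classify the course as ``"curative"`` or ``"palliative"``.

    Curative iff every treated lesion's unrounded prescription BED reaches the
    threshold *and* the whole active tumour burden is covered (all active
    metastases treated with SBRT, or the remainder ablated otherwise).
    Missing dose data raises — a patient is never silently palliative.
    """
    lesions = record.course.lesions
    if not lesions:
        raise IntentClassificationError(
            f"patient {record.patient_id}: course has no lesions with dose data")
    for j, les in enumerate(lesions):
        if les.dose_per_fraction is None or les.n_fractions is None:
            raise IntentClassificationError(
                f"patient {record.patient_id}: lesion {j} lacks dose data")
    all_ablative = all(
        bed(les.n_fractions, les.dose_per_fraction, params)
        >= params.curative_bed_threshold
        for les in lesions
    )
    covered = (record.course.all_active_mets_treated
               or record.course.other_ablative_therapy_covers_rest)
    return CURATIVE if (all_ablative and covered) else PALLIATIVE


def classify_local_failure(baseline_diameter: float, followup_diameter: float) -> bool:
    """True iff the treated lesion grew by at least 20 % in longest diameter.

    The boundary is inclusive: exactly +20 % is a failure.
    """
    if not baseline_diameter > 0 or not followup_diameter > 0:
        raise DomainError("diameters must be > 0")
    growth = followup_diameter / baseline_diameter - 1.0
    return growth >= LOCAL_FAILURE_GROWTH - 1e-12
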