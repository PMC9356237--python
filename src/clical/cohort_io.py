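"""Cohort data model and delimited-file round trip.

The cohort is stored as two comma-separated UTF-8 files joined on
``patient_id``:

``patients.csv`` — one row per patient::

    patient_id, age, sex, performance_status, n_crc_primaries, cea,
    n_active_mets, all_active_mets_treated, other_ablative_therapy_covers_rest,
    ttr_months, ttr_event, os_months, os_event

``lesions.csv`` — one row per treated lesion (long format)::

    patient_id, lesion_index, organ_site, dose_per_fraction, n_fractions,
    baseline_diameter, lc_months, lc_event

Units are fixed: months for all times, Gy for doses, µg/L for CEA, mm for
diameters.  Missing values are written as empty cells; ``NA``/``NaN`` are
accepted on read but never written.  Event indicators are written ``1``/``0``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import CohortFormatError, SchemaError

__all__ = [
    "SurvivalOutcome",
    "LesionTreatment",
    "SbrtCourse",
    "PatientRecord",
    "ValidationReport",
    "Violation",
    "CLICAL_VARIABLES",
    "ORGAN_SITES",
    "clical_value",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
]

ORGAN_SITES = ("lung", "liver", "lymph_node", "bone_spine", "other")

#: the five clinical variables entering the risk score
CLICAL_VARIABLES = ("age", "performance_status", "n_crc_primaries", "cea", "n_active_mets")

PATIENT_COLUMNS = (
    "patient_id", "age", "sex", "performance_status", "n_crc_primaries",
    "cea", "n_active_mets", "all_active_mets_treated",
    "other_ablative_therapy_covers_rest",
    "ttr_months", "ttr_event", "os_months", "os_event",
)
LESION_COLUMNS = (
    "patient_id", "lesion_index", "organ_site", "dose_per_fraction",
    "n_fractions", "baseline_diameter", "lc_months", "lc_event",
)

_MISSING_TOKENS = {"", "NA", "NaN", "nan", "na"}


@dataclass(frozen=True)
class SurvivalOutcome:
    """A right-censored duration: ``event=True`` means the event was observed
    at ``time`` (months); ``False`` means follow-up ended event-free then."""

    time: float
    event: bool


@dataclass(frozen=True)
class LesionTreatment:
    organ_site: str
    dose_per_fraction: float  # Gy, symbol d
    n_fractions: int          # symbol n
    baseline_diameter: float | None = None  # mm
    lc: SurvivalOutcome | None = None


@dataclass(frozen=True)
class SbrtCourse:
    """The first SBRT course: the treated lesions plus coverage flags used
    for intent classification."""

    lesions: tuple[LesionTreatment, ...]
    all_active_mets_treated: bool
    other_ablative_therapy_covers_rest: bool = False


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    age: int | None
    sex: str | None
    performance_status: int | None
    n_crc_primaries: int | None
    cea: float | None
    n_active_mets: int | None
    course: SbrtCourse
    ttr: SurvivalOutcome | None = None
    os: SurvivalOutcome | None = None

    def missing_clical_variables(self) -> tuple[str, ...]:
        """Names of risk-score variables absent for this patient."""
        return tuple(v for v in CLICAL_VARIABLES if getattr(self, v) is None)


def clical_value(record: PatientRecord, variable: str) -> float | None:
    if variable not in CLICAL_VARIABLES:
        raise KeyError(f"unknown clinical variable {variable!r}")
    v = getattr(record, variable)
    return None if v is None else float(v)


# ---------------------------------------------------------------------------
# reading / writing


def _cell(raw: object) -> str | None:
    s = "" if raw is None else str(raw).strip()
    return None if s in _MISSING_TOKENS else s


def _parse(raw: object, kind: type, row: int, column: str):
    s = _cell(raw)
    if s is None:
        return None
    try:
        if kind is bool:
            if s in ("1", "true", "True"):
                return True
            if s in ("0", "false", "False"):
                return False
            raise ValueError(s)
        if kind is int:
            return int(float(s)) if float(s) == int(float(s)) else int(s)
        return kind(s)
    except ValueError:
        raise CohortFormatError(
            f"row {row}: column {column!r} has non-{kind.__name__} value {s!r}",
            row=row, column=column,
        ) from None


def _outcome(time, event, row: int, tcol: str, ecol: str) -> SurvivalOutcome | None:
    t = _parse(time, float, row, tcol)
    e = _parse(event, bool, row, ecol)
    if t is None and e is None:
        return None
    if t is None or e is None:
        raise CohortFormatError(
            f"row {row}: {tcol}/{ecol} must both be present or both empty", row=row)
    return SurvivalOutcome(time=t, event=e)


def _load_table(path, required: Sequence[str], schema: Mapping[str, str] | None) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return df


def read_cohort(
    patients_path,
    lesions_path,
    schema: Mapping[str, str] | None = None,
) -> tuple[PatientRecord, ...]:
    """Read ``patients.csv`` + ``lesions.csv`` into records.

    ``schema`` optionally maps canonical column names to the names actually
    present in the files.  Empty cells become missing values; malformed
    numerics raise :class:`CohortFormatError` with the offending row index.
    """
    pdf = _load_table(patients_path, PATIENT_COLUMNS, schema)
    ldf = _load_table(lesions_path, LESION_COLUMNS, schema)

    lesions_by_id: dict[str, list[LesionTreatment]] = {}
    for i, row in enumerate(ldf.itertuples(index=False)):
        pid = _cell(row.patient_id)
        if pid is None:
            raise CohortFormatError(f"lesions row {i}: empty patient_id", row=i)
        lesions_by_id.setdefault(pid, []).append(LesionTreatment(
            organ_site=_cell(row.organ_site) or "other",
            dose_per_fraction=_parse(row.dose_per_fraction, float, i, "dose_per_fraction"),
            n_fractions=_parse(row.n_fractions, int, i, "n_fractions"),
            baseline_diameter=_parse(row.baseline_diameter, float, i, "baseline_diameter"),
            lc=_outcome(row.lc_months, row.lc_event, i, "lc_months", "lc_event"),
        ))

    records: list[PatientRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(pdf.itertuples(index=False)):
        pid = _cell(row.patient_id)
        if pid is None:
            raise CohortFormatError(f"patients row {i}: empty patient_id", row=i)
        if pid in seen:
            raise CohortFormatError(f"patients row {i}: duplicate patient_id {pid!r}", row=i)
        seen.add(pid)
        course = SbrtCourse(
            lesions=tuple(lesions_by_id.get(pid, ())),
            all_active_mets_treated=_parse(
                row.all_active_mets_treated, bool, i, "all_active_mets_treated") or False,
            other_ablative_therapy_covers_rest=_parse(
                row.other_ablative_therapy_covers_rest, bool, i,
                "other_ablative_therapy_covers_rest") or False,
        )
        records.append(PatientRecord(
            patient_id=pid,
            age=_parse(row.age, int, i, "age"),
            sex=_cell(row.sex),
            performance_status=_parse(row.performance_status, int, i, "performance_status"),
            n_crc_primaries=_parse(row.n_crc_primaries, int, i, "n_crc_primaries"),
            cea=_parse(row.cea, float, i, "cea"),
            n_active_mets=_parse(row.n_active_mets, int, i, "n_active_mets"),
            course=course,
            ttr=_outcome(row.ttr_months, row.ttr_event, i, "ttr_months", "ttr_event"),
            os=_outcome(row.os_months, row.os_event, i, "os_months", "os_event"),
        ))
    return tuple(records)


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "1" if v else "0"
    if isinstance(v, float):
        return repr(v)  # shortest round-trip representation
    return str(v)


def write_cohort(cohort: Iterable[PatientRecord], patients_path, lesions_path) -> None:
    """Write the two-file delimited representation (inverse of :func:`read_cohort`)."""
    prow, lrow = [], []
    for r in cohort:
        prow.append([
            r.patient_id, r.age, r.sex, r.performance_status, r.n_crc_primaries,
            r.cea, r.n_active_mets, r.course.all_active_mets_treated,
            r.course.other_ablative_therapy_covers_rest,
            None if r.ttr is None else r.ttr.time,
            None if r.ttr is None else r.ttr.event,
            None if r.os is None else r.os.time,
            None if r.os is None else r.os.event,
        ])
        for j, les in enumerate(r.course.lesions):
            lrow.append([
                r.patient_id, j, les.organ_site, les.dose_per_fraction,
                les.n_fractions, les.baseline_diameter,
                None if les.lc is None else les.lc.time,
                None if les.lc is None else les.lc.event,
            ])
    pd.DataFrame(
        [[_fmt(v) for v in row] for row in prow], columns=PATIENT_COLUMNS
    ).to_csv(patients_path, index=False)
    pd.DataFrame(
        [[_fmt(v) for v in row] for row in lrow], columns=LESION_COLUMNS
    ).to_csv(lesions_path, index=False)


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Violation:
    patient_id: str
    field: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, pid: str, field_name: str, message: str) -> None:
        self.violations.append(Violation(pid, field_name, message))

    def to_json(self) -> str:
        return json.dumps(
            [v.__dict__ for v in self.violations], indent=2, ensure_ascii=False)

    def __str__(self) -> str:
        if self.ok:
            return "cohort valid: no violations"
        return "\n".join(f"{v.patient_id}: {v.field}: {v.message}" for v in self.violations)


def validate_cohort(
    cohort: Iterable[PatientRecord],
    age_range: tuple[int, int] = (18, 110),
) -> ValidationReport:
    """Check every record invariant; returns a report and never raises."""
    rep = ValidationReport()
    for r in cohort:
        pid = r.patient_id
        if r.age is not None and not (age_range[0] <= r.age <= age_range[1]):
            rep.add(pid, "age", f"age {r.age} outside plausible range {age_range}")
        if r.performance_status is not None and r.performance_status not in (0, 1, 2, 3):
            rep.add(pid, "performance_status",
                    f"performance_status {r.performance_status} not in 0–3")
        if r.n_crc_primaries is not None and r.n_crc_primaries < 1:
            rep.add(pid, "n_crc_primaries", "must be >= 1")
        if r.cea is not None and r.cea < 0:
            rep.add(pid, "cea", "CEA must be non-negative")
        if r.n_active_mets is not None and r.n_active_mets < 1:
            rep.add(pid, "n_active_mets", "must be >= 1")
        if r.sex is not None and r.sex not in ("male", "female"):
            rep.add(pid, "sex", f"unknown sex {r.sex!r}")
        if not r.course.lesions:
            rep.add(pid, "course.lesions", "course has no treated lesions")
        if r.n_active_mets is not None and len(r.course.lesions) > r.n_active_mets:
            rep.add(pid, "course.lesions",
                    f"{len(r.course.lesions)} treated lesions exceed "
                    f"n_active_mets={r.n_active_mets}")
        for j, les in enumerate(r.course.lesions):
            if les.dose_per_fraction is None or not les.dose_per_fraction > 0:
                rep.add(pid, f"lesion[{j}].dose_per_fraction", "must be > 0")
            if les.n_fractions is None or les.n_fractions < 1:
                rep.add(pid, f"lesion[{j}].n_fractions", "must be >= 1")
            if les.organ_site not in ORGAN_SITES:
                rep.add(pid, f"lesion[{j}].organ_site",
                        f"unknown organ site {les.organ_site!r}")
        for name, out in (("ttr", r.ttr), ("os", r.os)):
            if out is not None and out.time < 0:
                rep.add(pid, name, "time must be >= 0")
    return rep


def mask_variables(record: PatientRecord, variables: Sequence[str]) -> PatientRecord:
    """Return a copy of ``record`` with the given risk-score variables missing."""
    bad = [v for v in variables if v not in CLICAL_VARIABLES]
    if bad:
        raise KeyError(f"not clinical score variables: {bad}")
    return replace(record, **{v: None for v in variables})
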