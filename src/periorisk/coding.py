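"""Axis-score coding for the periodontal risk assessment (PRA) model.

Each clinical parameter is mapped onto an ordinal axis score 0-5. Score 0 is
the healthy anchor, score 5 the most severe band. The printed bands in the
source coding system leave small gaps (e.g. bleeding "<4" followed by "5-9");
these are closed by treating each band's upper edge as inclusive and extending
it to the next band's floor, so every valid input falls in exactly one band
and the mapping is monotone.

Units and interpretation:

* bleeding on probing (BOP) — percent of probed sites that bleed, 0-100;
* pockets — count of sites/areas with probing depth > 5 mm;
* tooth loss — count of missing teeth (baseline dentition of 32);
* smoking — status plus cigarettes per day for current smokers;
* attachment-loss/age — ratio of an attachment-loss measure to age in years;
* glycemic value — mg/dL, standing in for banded "diabetic status";
* dental-systemic interplay — ordinal 0-5 code carried directly;
* background — Kuppuswamy socioeconomic class I-V plus a stress flag
  (no coding table exists for this axis in the source model; the mapping
  here is a fixed, documented convention: class I..V -> 0..4, +1 if
  high stress, capped at 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "ValidationError",
    "PatientRecord",
    "AxisScoreVector",
    "SMOKING_STATUSES",
    "SES_CLASSES",
    "score_bop",
    "score_pockets",
    "score_tooth_loss",
    "score_smoking",
    "score_al_age",
    "score_diabetic",
    "score_dental_systemic",
    "score_background",
    "score_patient",
]

SMOKING_STATUSES = ("nonsmoker", "former", "current")
SES_CLASSES = ("I", "II", "III", "IV", "V")

#: Maximum missing teeth consistent with the >= 20 functional teeth
#: inclusion criterion, on a 32-tooth baseline dentition.
MAX_TEETH_LOST = 12


class ValidationError(ValueError):
    """A clinical field failed validation.

    Carries the offending field name and value, and the patient id when the
    error arises while processing a record.
    """

    def __init__(self, field_name: str, value, message: str,
                 patient_id: Optional[str] = None):
        self.field_name = field_name
        self.value = value
        self.patient_id = patient_id
        prefix = f"patient {patient_id!r}: " if patient_id else ""
        super().__init__(f"{prefix}{field_name}={value!r}: {message}")

    def with_patient(self, patient_id: str) -> "ValidationError":
        return ValidationError(self.field_name, self.value,
                               self.args[0].split(": ", 1)[-1], patient_id)


def _require_number(name: str, value) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ValidationError(name, value, "must be a number")
    return float(value)


def score_bop(bop_extent: float) -> int:
    """Score bleeding on probing, given as percent of bleeding sites.

    Bands: 0 -> 0; (0,4] -> 1; (4,9] -> 2; (9,16] -> 3; (16,25] -> 4; >25 -> 5.
    """
    x = _require_number("bop_extent", bop_extent)
    if not 0 <= x <= 100:
        raise ValidationError("bop_extent", bop_extent,
                              "must lie in [0, 100] percent")
    if x == 0:
        return 0
    for score, upper in ((1, 4), (2, 9), (3, 16), (4, 25)):
        if x <= upper:
            return score
    return 5


def _score_count_band(name: str, count) -> int:
    n = _require_number(name, count)
    if n < 0 or n != int(n):
        raise ValidationError(name, count, "must be a non-negative integer")
    n = int(n)
    if n == 0:
        return 0
    for score, upper in ((1, 2), (2, 4), (3, 6), (4, 8)):
        if n <= upper:
            return score
    return 5


def score_pockets(pockets_over_5mm: int) -> int:
    """Score the count of sites with probing depth > 5 mm.

    Bands: 0; 1-2; 3-4; 5-6; 7-8; >=9.
    """
    return _score_count_band("pockets_over_5mm", pockets_over_5mm)


def score_tooth_loss(teeth_lost: int) -> int:
    """Score the count of missing teeth (same band structure as pockets)."""
    return _score_count_band("teeth_lost", teeth_lost)


def score_smoking(status: str, cigarettes_per_day: Optional[int] = None) -> int:
    """Score smoking exposure.

    Non-smoker -> 0; former smoker -> 1; current smoker scored by dose:
    <10/day -> 2; 10-19 -> 3; exactly 20 -> 4; >20 -> 5.
    """
    if status not in SMOKING_STATUSES:
        raise ValidationError("smoking_status", status,
                              f"must be one of {SMOKING_STATUSES}")
    if status == "nonsmoker":
        return 0
    if status == "former":
        return 1
    if cigarettes_per_day is None:
        raise ValidationError("cigarettes_per_day", cigarettes_per_day,
                              "required for current smokers")
    n = _require_number("cigarettes_per_day", cigarettes_per_day)
    if n < 0 or n != int(n):
        raise ValidationError("cigarettes_per_day", cigarettes_per_day,
                              "must be a non-negative integer")
    n = int(n)
    if n < 10:
        return 2
    if n < 20:
        return 3
    if n == 20:
        return 4
    return 5


def score_al_age(al_age_ratio: float) -> int:
    """Score the attachment-loss-to-age ratio.

    Bands: 0 -> 0; (0,0.25] -> 1; (0.25,0.5] -> 2; (0.5,0.75] -> 3;
    (0.75,1] -> 4; >1 -> 5.
    """
    r = _require_number("al_age_ratio", al_age_ratio)
    if r < 0:
        raise ValidationError("al_age_ratio", al_age_ratio,
                              "must be non-negative")
    if r == 0:
        return 0
    for score, upper in ((1, 0.25), (2, 0.5), (3, 0.75), (4, 1.0)):
        if r <= upper:
            return score
    return 5


def score_diabetic(glycemic_value: float) -> int:
    """Score glycemic status in mg/dL.

    Bands: <102 -> 0; 102-109 -> 1; 110-117 -> 2; 118-125 -> 3;
    126-133 -> 4; >133 -> 5.
    """
    g = _require_number("glycemic_value", glycemic_value)
    if g <= 0:
        raise ValidationError("glycemic_value", glycemic_value,
                              "must be positive")
    if g < 102:
        return 0
    for score, upper in ((1, 109), (2, 117), (3, 125), (4, 133)):
        if g <= upper:
            return score
    return 5


def score_dental_systemic(status_code: int) -> int:
    """Score the dental-status / systemic-factors interplay code.

    The 0-5 status code (0 healthy ... 5 severe with tooth morbidity) is
    itself the axis score.
    """
    c = _require_number("dental_systemic_status", status_code)
    if c != int(c) or not 0 <= c <= 5:
        raise ValidationError("dental_systemic_status", status_code,
                              "must be an integer code in 0..5")
    return int(c)


_SES_BASE = {cls: i for i, cls in enumerate(SES_CLASSES)}


def score_background(ses_class: str, high_stress: bool) -> int:
    """Score background characteristics (socioeconomic class + stress).

    Kuppuswamy class I..V maps to base score 0..4; high stress adds one,
    capped at 5.
    """
    if ses_class not in _SES_BASE:
        raise ValidationError("ses_class", ses_class,
                              f"must be one of {SES_CLASSES}")
    if not isinstance(high_stress, bool):
        raise ValidationError("high_stress", high_stress, "must be a boolean")
    return min(5, _SES_BASE[ses_class] + (1 if high_stress else 0))


@dataclass
class PatientRecord:
    """Raw chairside measurements for one subject."""

    patient_id: str
    age: int
    bop_extent: float
    pockets_over_5mm: int
    teeth_lost: int
    smoking_status: str
    cigarettes_per_day: Optional[int]
    al_age_ratio: float
    glycemic_value: float
    dental_systemic_status: int
    ses_class: str
    high_stress: bool

    def validate(self) -> "PatientRecord":
        """Check every field; raise :class:`ValidationError` naming the
        patient and field on the first failure."""
        try:
            age = _require_number("age", self.age)
            if age != int(age) or not 30 <= age <= 60:
                raise ValidationError("age", self.age,
                                      "must be an integer in [30, 60]")
            tl = _require_number("teeth_lost", self.teeth_lost)
            if tl != int(tl) or not 0 <= tl <= MAX_TEETH_LOST:
                raise ValidationError(
                    "teeth_lost", self.teeth_lost,
                    f"must be an integer in [0, {MAX_TEETH_LOST}] "
                    "(at least 20 functional teeth)")
            # the per-axis scorers validate ranges and categorical tokens
            score_bop(self.bop_extent)
            score_pockets(self.pockets_over_5mm)
            score_smoking(self.smoking_status, self.cigarettes_per_day)
            score_al_age(self.al_age_ratio)
            score_diabetic(self.glycemic_value)
            score_dental_systemic(self.dental_systemic_status)
            score_background(self.ses_class, self.high_stress)
        except ValidationError as err:
            raise err.with_patient(self.patient_id) from None
        return self


@dataclass(frozen=True)
class AxisScoreVector:
    """Ordered per-axis scores 0-5 for one patient under one model."""

    model_id: str
    scores: tuple
    axis_names: tuple = field(default=())

    def __post_init__(self):
        object.__setattr__(self, "scores", tuple(int(s) for s in self.scores))
        object.__setattr__(self, "axis_names", tuple(self.axis_names))
        expected = {"modified8": 8, "lt2003": 6}.get(self.model_id)
        if expected is None:
            raise ValidationError("model_id", self.model_id,
                                  "must be 'modified8' or 'lt2003'")
        if len(self.scores) != expected:
            raise ValidationError(
                "scores", self.scores,
                f"model {self.model_id} requires {expected} axis scores")
        if self.axis_names and len(self.axis_names) != expected:
            raise ValidationError("axis_names", self.axis_names,
                                  "must match the number of axes")
        for s in self.scores:
            if not 0 <= s <= 5:
                raise ValidationError("scores", s,
                                      "axis scores must lie in 0..5")

    def __len__(self) -> int:
        return len(self.scores)


# one scorer per named axis; score_patient dispatches through this table
_AXIS_SCORERS = {
    "bop": lambda r: score_bop(r.bop_extent),
    "pockets": lambda r: score_pockets(r.pockets_over_5mm),
    "tooth_loss": lambda r: score_tooth_loss(r.teeth_lost),
    "smoking": lambda r: score_smoking(r.smoking_status,
                                       r.cigarettes_per_day),
    "al_age": lambda r: score_al_age(r.al_age_ratio),
    "diabetic": lambda r: score_diabetic(r.glycemic_value),
    "dental_systemic": lambda r: score_dental_systemic(
        r.dental_systemic_status),
    "background": lambda r: score_background(r.ses_class, r.high_stress),
}


def score_patient(record: PatientRecord, model) -> AxisScoreVector:
    """Score one patient on every axis of a model.

    ``model`` is a :class:`~periorisk.models.ModelSpec`; its ``axis_names``
    determine which scorers run and in what order.
    """
    record.validate()
    scores = []
    for axis in model.axis_names:
        try:
            scores.append(_AXIS_SCORERS[axis](record))
        except ValidationError as err:
            raise err.with_patient(record.patient_id) from None
    return AxisScoreVector(model_id=model.model_id, scores=tuple(scores),
                           axis_names=tuple(model.axis_names))
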