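"""Model specifications, risk-zone classification and polygon geometry.

Two functional-diagram models are defined:

* ``modified8`` — the eight-parameter model (BOP, pockets > 5 mm, tooth loss,
  smoking, attachment-loss/age, glycemic status, dental-systemic interplay,
  background characteristics);
* ``lt2003`` — the six-parameter Lang-Tonetti-style comparison model (the
  shared clinical axes, without the glycemic and background additions).

Each axis score 0-5 falls into one of three diagram zones — low (0-1),
moderate (2-3), high (4-5) — and a patient's category is decided by counting
axes per zone:

* modified8: high if >= 2 axes are in the high zone; otherwise low if at most
  2 axes are outside the low zone; otherwise moderate. This is the
  deterministic completion of the published counting rule ("all parameters in
  low risk areas, or at most 2 in moderate and high" / "3 in moderate, one in
  high" / "2 parameters in high"), with precedence high > low > moderate so
  every vector receives exactly one category.
* lt2003: high if >= 2 axes high; low if at most 1 axis outside low;
  otherwise moderate.

The polygon area of the functional diagram is reported as a diagnostic but
never drives the category.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np

from .coding import AxisScoreVector, ValidationError

__all__ = [
    "ModelSpec",
    "RiskClassification",
    "MODEL_IDS",
    "CATEGORIES",
    "CATEGORY_RANK",
    "build_model_spec",
    "risk_area_of",
    "category_from_counts",
    "classify_modified",
    "classify_lang_tonetti",
    "classify",
    "polygon_area",
    "polygon_vertices",
]

MODEL_IDS = ("modified8", "lt2003")
CATEGORIES = ("low", "moderate", "high")
CATEGORY_RANK = {c: i for i, c in enumerate(CATEGORIES)}

_MODIFIED8_AXES = ("bop", "pockets", "tooth_loss", "smoking", "al_age",
                   "diabetic", "dental_systemic", "background")
_LT2003_AXES = ("bop", "pockets", "tooth_loss", "al_age", "dental_systemic",
                "smoking")


@dataclass(frozen=True)
class ModelSpec:
    """Axis list and classification rule for one diagram model."""

    model_id: str
    axis_names: Tuple[str, ...]
    rule_id: str

    @property
    def n_axes(self) -> int:
        return len(self.axis_names)


@dataclass(frozen=True)
class RiskClassification:
    """Outcome of classifying one score vector under one model."""

    category: str
    n_moderate_axes: int
    n_high_axes: int
    polygon_area: float


def build_model_spec(model_id: str) -> ModelSpec:
    """Return the fixed specification for ``modified8`` or ``lt2003``."""
    if model_id == "modified8":
        return ModelSpec("modified8", _MODIFIED8_AXES, "table_completed")
    if model_id == "lt2003":
        return ModelSpec("lt2003", _LT2003_AXES, "lt_classic")
    raise ValidationError("model_id", model_id,
                          f"must be one of {MODEL_IDS}")


def risk_area_of(score: int) -> str:
    """Map an axis score to its diagram zone: 0-1 low, 2-3 moderate, 4-5 high."""
    if not isinstance(score, (int, np.integer)) or isinstance(score, bool):
        raise ValidationError("score", score, "must be an integer")
    if not 0 <= score <= 5:
        raise ValidationError("score", score, "axis score must lie in 0..5")
    return CATEGORIES[int(score) // 2]


def category_from_counts(n_moderate: int, n_high: int, rule_id: str) -> str:
    """Decide the risk category from zone counts alone.

    Both rules are functions of (m, h) = (#moderate-zone axes, #high-zone
    axes) only, which makes them permutation-invariant by construction.
    """
    m, h = int(n_moderate), int(n_high)
    if rule_id == "table_completed":
        if h >= 2:
            return "high"
        return "low" if m + h <= 2 else "moderate"
    if rule_id == "lt_classic":
        if h >= 2:
            return "high"
        return "low" if m + h <= 1 else "moderate"
    raise ValidationError("rule_id", rule_id, "unknown classification rule")


def _zone_counts(vector: AxisScoreVector) -> Tuple[int, int]:
    areas = [risk_area_of(s) for s in vector.scores]
    return areas.count("moderate"), areas.count("high")


def _classify(vector: AxisScoreVector, expected_model: str,
              rule_id: str) -> RiskClassification:
    if vector.model_id != expected_model:
        raise ValidationError("model_id", vector.model_id,
                              f"classifier expects a {expected_model} vector")
    m, h = _zone_counts(vector)
    return RiskClassification(
        category=category_from_counts(m, h, rule_id),
        n_moderate_axes=m,
        n_high_axes=h,
        polygon_area=polygon_area(vector),
    )


def classify_modified(vector: AxisScoreVector) -> RiskClassification:
    """Classify an 8-axis vector under the modified-model counting rule."""
    return _classify(vector, "modified8", "table_completed")


def classify_lang_tonetti(vector: AxisScoreVector) -> RiskClassification:
    """Classify a 6-axis vector under the Lang-Tonetti-style rule."""
    return _classify(vector, "lt2003", "lt_classic")


def classify(vector: AxisScoreVector) -> RiskClassification:
    """Dispatch to the model-appropriate classifier."""
    if vector.model_id == "modified8":
        return classify_modified(vector)
    return classify_lang_tonetti(vector)


def polygon_vertices(vector: AxisScoreVector) -> np.ndarray:
    """Cartesian vertices of the score polygon.

    Axis 0 points up; axes proceed clockwise in listed order; the radius of
    vertex k equals the raw score on axis k.
    """
    scores = np.asarray(vector.scores, dtype=float)
    n = len(scores)
    theta = np.pi / 2 - 2 * np.pi * np.arange(n) / n
    return np.column_stack([scores * np.cos(theta), scores * np.sin(theta)])


def polygon_area(vector: AxisScoreVector) -> float:
    """Area of the closed score polygon by the shoelace formula.

    For a uniform vector of radius r on n axes this equals the regular-polygon
    closed form (n/2) * r^2 * sin(2*pi/n); the all-zero vector degenerates to
    area 0.
    """
    pts = polygon_vertices(vector)
    x, y = pts[:, 0], pts[:, 1]
    return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)))


def classification_record(patient_id: str, vector: AxisScoreVector,
                          result: RiskClassification) -> Dict:
    """JSON-serialisable record of one classification."""
    return {
        "patient_id": patient_id,
        "model_id": vector.model_id,
        "axis_names": list(vector.axis_names),
        "scores": list(vector.scores),
        "areas": [risk_area_of(s) for s in vector.scores],
        "n_moderate_axes": result.n_moderate_axes,
        "n_high_axes": result.n_high_axes,
        "polygon_area": round(result.polygon_area, 6),
        "category": result.category,
    }
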