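"""Seeded synthetic patient cohorts with exact marginal counts.

The generator emulates a 30-patient diabetic periodontal cohort: every
patient has generalized bleeding on probing, 12 are current smokers and 4
former smokers, half carry pockets > 5 mm at 7-8 areas and a third at 5-6
areas, attachment-loss/age ratios are split across mild/moderate/severe
bands, a third have 7-8 missing teeth, and socioeconomic status is massed
on the lower Kuppuswamy classes.

Categorical marginals are hit EXACTLY by deterministic label assignment
followed by a seeded shuffle; continuous values are drawn uniformly within
each assigned band. No joint structure between marginals is imposed — the
attribute shuffles are independent. Cohorts are a pure function of
(config, seed): same inputs, byte-identical CSV.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import yaml

from .coding import (SES_CLASSES, SMOKING_STATUSES, PatientRecord,
                     ValidationError)

__all__ = [
    "CohortConfig",
    "generate_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
    "load_config",
]

_CSV_FIELDS = [f.name for f in fields(PatientRecord)]


@dataclass(frozen=True)
class CohortConfig:
    """Marginal counts and sampling weights for one synthetic cohort.

    Defaults encode the study conditions: counts where the source prints
    counts (12 current / 4 former smokers), printed percentages rounded to
    the nearest feasible count of 30 (50% -> 15 high-pocket, 35% -> 10
    mid-pocket and 10 tooth-loss patients, 47% -> 14 moderate-attachment-loss,
    10% -> 3 severe).
    """

    n_patients: int = 30
    n_current_smokers: int = 12
    n_former_smokers: int = 4
    n_pockets_high: int = 15   # 7-8 areas with pockets > 5 mm
    n_pockets_mid: int = 10    # 5-6 areas
    n_loa_moderate: int = 14   # AL/age in (0.25, 0.75]
    n_loa_severe: int = 3      # AL/age > 1
    n_toothloss_78: int = 10   # 7-8 missing teeth
    ses_weights: Dict[str, float] = field(default_factory=lambda: {
        "I": 0.0, "II": 0.05, "III": 0.15, "IV": 0.45, "V": 0.35})
    all_generalized_bop: bool = True
    all_diabetic: bool = True
    seed: int = 42

    def validate(self) -> "CohortConfig":
        n = self.n_patients
        if n <= 0:
            raise ValidationError("n_patients", n, "must be positive")
        for name in ("n_current_smokers", "n_former_smokers",
                     "n_pockets_high", "n_pockets_mid", "n_loa_moderate",
                     "n_loa_severe", "n_toothloss_78"):
            v = getattr(self, name)
            if not 0 <= v <= n:
                raise ValidationError(name, v,
                                      f"must lie in [0, n_patients={n}]")
        if self.n_current_smokers + self.n_former_smokers > n:
            raise ValidationError(
                "n_current_smokers", self.n_current_smokers,
                "smoker counts exceed cohort size")
        if self.n_pockets_high + self.n_pockets_mid > n:
            raise ValidationError("n_pockets_high", self.n_pockets_high,
                                  "pocket-band counts exceed cohort size")
        if self.n_loa_moderate + self.n_loa_severe > n:
            raise ValidationError("n_loa_moderate", self.n_loa_moderate,
                                  "attachment-loss counts exceed cohort size")
        missing = set(SES_CLASSES) - set(self.ses_weights)
        if missing or any(w < 0 for w in self.ses_weights.values()) \
                or sum(self.ses_weights.values()) <= 0:
            raise ValidationError("ses_weights", self.ses_weights,
                                  "must give non-negative weights for all "
                                  "classes I..V with positive total")
        return self


def _assign(rng: np.random.Generator, labels: List[str]) -> List[str]:
    """Seeded shuffle of a deterministic label list."""
    return [labels[i] for i in rng.permutation(len(labels))]


def generate_cohort(config: Optional[CohortConfig] = None,
                    ) -> List[PatientRecord]:
    """Generate a validated synthetic cohort with exact marginal counts."""
    cfg = (config or CohortConfig()).validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients

    smoking = _assign(rng, ["current"] * cfg.n_current_smokers
                      + ["former"] * cfg.n_former_smokers
                      + ["nonsmoker"] * (n - cfg.n_current_smokers
                                         - cfg.n_former_smokers))
    pockets_band = _assign(rng, ["high"] * cfg.n_pockets_high
                           + ["mid"] * cfg.n_pockets_mid
                           + ["low"] * (n - cfg.n_pockets_high
                                        - cfg.n_pockets_mid))
    loa_band = _assign(rng, ["moderate"] * cfg.n_loa_moderate
                       + ["severe"] * cfg.n_loa_severe
                       + ["mild"] * (n - cfg.n_loa_moderate
                                     - cfg.n_loa_severe))
    tooth_band = _assign(rng, ["78"] * cfg.n_toothloss_78
                         + ["low"] * (n - cfg.n_toothloss_78))

    ses_w = np.array([cfg.ses_weights[c] for c in SES_CLASSES], dtype=float)
    ses_w /= ses_w.sum()

    records = []
    for i in range(n):
        bop = (rng.uniform(26.0, 100.0) if cfg.all_generalized_bop
               else rng.uniform(0.0, 100.0))
        if pockets_band[i] == "high":
            pockets = int(rng.integers(7, 9))
        elif pockets_band[i] == "mid":
            pockets = int(rng.integers(5, 7))
        else:
            pockets = int(rng.integers(0, 5))
        teeth = int(rng.integers(7, 9)) if tooth_band[i] == "78" \
            else int(rng.integers(0, 7))
        if loa_band[i] == "severe":
            ratio = rng.uniform(1.01, 1.5)
        elif loa_band[i] == "moderate":
            ratio = rng.uniform(0.26, 0.75)
        else:
            ratio = rng.uniform(0.01, 0.25)
        glycemic = (rng.uniform(110.0, 180.0) if cfg.all_diabetic
                    else rng.uniform(85.0, 180.0))
        # confirmed diabetes is an endocrine modifier of periodontal status,
        # hence dental-systemic codes >= 3 when all_diabetic
        dental = int(rng.choice([3, 4, 5], p=[0.6, 0.3, 0.1])) \
            if cfg.all_diabetic else int(rng.integers(0, 6))
        cigarettes = int(rng.integers(2, 26)) if smoking[i] == "current" else 0
        records.append(PatientRecord(
            patient_id=f"P{i + 1:03d}",
            age=int(rng.integers(30, 61)),
            bop_extent=round(float(bop), 1),
            pockets_over_5mm=pockets,
            teeth_lost=teeth,
            smoking_status=smoking[i],
            cigarettes_per_day=cigarettes,
            al_age_ratio=round(float(ratio), 3),
            glycemic_value=round(float(glycemic), 1),
            dental_systemic_status=dental,
            ses_class=str(rng.choice(SES_CLASSES, p=ses_w)),
            high_stress=bool(rng.random() < 0.5),
        ).validate())
    return records


def write_cohort_csv(cohort: Sequence[PatientRecord],
                     path: str | Path) -> Path:
    """Write one row per patient with the record field names as header."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
        writer.writeheader()
        for rec in cohort:
            row = asdict(rec)
            row["high_stress"] = "true" if rec.high_stress else "false"
            if rec.smoking_status != "current" \
                    and rec.cigarettes_per_day in (None, 0):
                row["cigarettes_per_day"] = 0
            writer.writerow(row)
    return path


def _parse_row(row: Dict[str, str], line_no: int) -> PatientRecord:
    def bad(field_name, value, msg):
        raise ValidationError(field_name, value, f"line {line_no}: {msg}")

    pid = row.get("patient_id") or ""
    if not pid:
        bad("patient_id", pid, "missing patient id")
    smoking = (row.get("smoking_status") or "").strip().lower()
    if smoking not in SMOKING_STATUSES:
        bad("smoking_status", row.get("smoking_status"),
            f"must be one of {SMOKING_STATUSES}")
    cig_raw = (row.get("cigarettes_per_day") or "").strip()
    if cig_raw == "":
        if smoking == "current":
            bad("cigarettes_per_day", cig_raw,
                "required for current smokers")
        cigarettes: Optional[int] = 0
    else:
        cigarettes = int(cig_raw)
    stress_raw = (row.get("high_stress") or "").strip().lower()
    if stress_raw not in ("true", "false"):
        bad("high_stress", row.get("high_stress"), "must be true or false")
    try:
        rec = PatientRecord(
            patient_id=pid,
            age=int(row["age"]),
            bop_extent=float(row["bop_extent"]),
            pockets_over_5mm=int(row["pockets_over_5mm"]),
            teeth_lost=int(row["teeth_lost"]),
            smoking_status=smoking,
            cigarettes_per_day=cigarettes,
            al_age_ratio=float(row["al_age_ratio"]),
            glycemic_value=float(row["glycemic_value"]),
            dental_systemic_status=int(row["dental_systemic_status"]),
            ses_class=(row.get("ses_class") or "").strip().upper(),
            high_stress=stress_raw == "true",
        ).validate()
    except (KeyError, TypeError) as err:
        bad("row", row, f"missing or malformed field ({err})")
    except ValueError as err:
        if isinstance(err, ValidationError):
            raise ValidationError(err.field_name, err.value,
                                  f"line {line_no}: {err}") from None
        bad("row", row, str(err))
    return rec


def read_cohort_csv(path: str | Path) -> List[PatientRecord]:
    """Read and validate a cohort CSV; errors carry the offending line."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValidationError("file", str(path), "empty cohort file")
        missing = set(_CSV_FIELDS) - set(reader.fieldnames)
        if missing:
            raise ValidationError("header", sorted(missing),
                                  "cohort CSV is missing required columns")
        cohort = [_parse_row(row, line_no)
                  for line_no, row in enumerate(reader, start=2)]
    if not cohort:
        raise ValidationError("file", str(path),
                              "cohort file contains no patient rows")
    return cohort


def load_config(path: str | Path) -> CohortConfig:
    """Load a CohortConfig from YAML or JSON keyed by the field names."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" \
        else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValidationError("config", str(path),
                              "config file must contain a mapping")
    known = {f.name for f in fields(CohortConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError("config", sorted(unknown),
                              "unknown config fields")
    return CohortConfig(**data).validate()
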