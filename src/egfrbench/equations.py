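"""The three creatinine-based GFR-estimating equations.

* **EKFC** — rescaled-creatinine equation with two power-law regimes
  joined at SCr/Q = 1 and an age decline starting at the 40-year knot:
  eGFR = 107.3 · (SCr/Q)^(−α) · 0.990^max(age−40, 0), with α = 0.322
  below the knot in rescaled creatinine and 1.132 at or above it.
* **CKD-EPI 2021** — the race-free US equation:
  eGFR = 142 · min(SCr/κ, 1)^α · max(SCr/κ, 1)^(−1.200) · 0.9938^age
  (· 1.012 if female), κ = 0.7 (F) / 0.9 (M) mg/dL, α = −0.241 (F) /
  −0.302 (M). Adults only: ages below 18 are rejected, since the
  log-linear age term grossly overestimates GFR in children.
* **r-LMR** — the Lund-Malmö Revised equation re-expressed in rescaled
  creatinine. The original is piecewise in plasma creatinine with
  sex-specific breakpoints (150 µmol/L women, 180 µmol/L men);
  substituting pCr = Q_adult · (SCr/Q) turns it into a function of the
  rescaled creatinine alone with a fixed per-sex breakpoint
  r0 = threshold / Q_adult, exactly continuous there:
  eGFR = exp(X − 0.0158·age + 0.438·ln age), where
  X = c + s·Q_adult·(r0 − r) for r < r0 and X = c − 0.926·ln(r/r0)
  otherwise.

All eGFR values are in mL/min/1.73 m² and are neither capped nor
rounded; display rounding belongs in reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

from .qvalues import QMode, QSpec, Sex, get_q_spec, q_lookup, q_mode_used, rescale_creatinine
from .units import UMOL_PER_MGDL, Concentration

__all__ = [
    "SubjectRecord",
    "EgfrResult",
    "EQUATION_LABELS",
    "egfr_ekfc",
    "egfr_ckdepi2021",
    "egfr_rlmr",
    "compute_egfr",
    "egfr_batch",
    "EKFC",
    "CKDEPI_2021",
    "RLMR",
]

EQUATION_LABELS = ("EKFC", "CKD-EPI", "r-LMR")

# Single versioned coefficient table; keep every numeric constant here so
# transcription stays auditable in one place.
EKFC = {
    "version": 1,
    "scale": 107.3,               # eGFR at SCr/Q = 1, mL/min/1.73 m²
    "alpha_low": 0.322,           # exponent for SCr/Q < 1
    "alpha_high": 1.132,          # exponent for SCr/Q >= 1
    "age_knot": 40.0,             # years; no age decline before the knot
    "age_decay": 0.990,           # per year beyond the knot
}

CKDEPI_2021 = {
    "version": 1,
    "scale": 142.0,
    "kappa_mg_dl": {Sex.FEMALE: 0.7, Sex.MALE: 0.9},
    "alpha": {Sex.FEMALE: -0.241, Sex.MALE: -0.302},
    "beta": -1.200,
    "age_decay": 0.9938,
    "female_factor": 1.012,
    "min_age": 18.0,
}

RLMR = {
    "version": 1,
    # Original Lund-Malmö Revised pieces (creatinine in µmol/L):
    #   F: X = 2.50 + 0.0121·(150 − pCr) | 2.50 − 0.926·ln(pCr/150)
    #   M: X = 2.56 + 0.00968·(180 − pCr) | 2.56 − 0.926·ln(pCr/180)
    #   eGFR = exp(X − 0.0158·age + 0.438·ln(age))
    # Re-expressed via pCr = Q_adult·r with the European adult plateaus.
    "intercept": {Sex.FEMALE: 2.50, Sex.MALE: 2.56},
    "slope_per_umol": {Sex.FEMALE: 0.0121, Sex.MALE: 0.00968},
    "threshold_umol": {Sex.FEMALE: 150.0, Sex.MALE: 180.0},
    "q_adult_umol": {
        Sex.FEMALE: 0.70 * UMOL_PER_MGDL,
        Sex.MALE: 0.90 * UMOL_PER_MGDL,
    },
    "log_slope": 0.926,
    "age_slope": -0.0158,
    "log_age_slope": 0.438,
}


@dataclass(frozen=True)
class SubjectRecord:
    """One person in a validation cohort."""

    id: str
    age: float
    sex: Sex
    scr: Concentration
    mgfr: Optional[float] = None
    race: Optional[str] = None
    bmi: Optional[float] = None
    cohort: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.age >= 2:
            raise ValueError(f"subject {self.id}: age must be >= 2 years, got {self.age}")
        if self.mgfr is not None and not self.mgfr > 0:
            raise ValueError(f"subject {self.id}: mGFR must be positive, got {self.mgfr}")


@dataclass(frozen=True)
class EgfrResult:
    subject_id: str
    equation: str
    egfr: float
    q_used: Optional[Concentration] = None
    q_mode: str = "n/a"


@dataclass(frozen=True)
class BatchRejection:
    subject_id: str
    equation: str
    reason: str


def _resolve_q(age: float, sex: Sex, spec: QSpec, q_mode: "QMode | str") -> Tuple[Concentration, str]:
    return q_lookup(age, sex, spec, q_mode), q_mode_used(age, spec, q_mode)


def egfr_ekfc(
    scr: Concentration,
    age: float,
    sex: "Sex | str",
    spec: Optional[QSpec] = None,
    q_mode: "QMode | str" = QMode.AUTO,
) -> float:
    """EKFC eGFR in mL/min/1.73 m²."""
    sex = Sex.coerce(sex)
    spec = spec if spec is not None else get_q_spec("europe")
    q, _ = _resolve_q(age, sex, spec, q_mode)
    r = rescale_creatinine(scr, q)
    alpha = EKFC["alpha_low"] if r < 1.0 else EKFC["alpha_high"]
    age_factor = EKFC["age_decay"] ** max(age - EKFC["age_knot"], 0.0)
    return EKFC["scale"] * r ** (-alpha) * age_factor


def egfr_ckdepi2021(scr: Concentration, age: float, sex: "Sex | str") -> float:
    """Race-free CKD-EPI 2021 eGFR in mL/min/1.73 m²; adults (>=18 y) only."""
    sex = Sex.coerce(sex)
    if age < CKDEPI_2021["min_age"]:
        raise ValueError(
            f"CKD-EPI is an adult equation: age must be >= {CKDEPI_2021['min_age']:g} years, got {age}"
        )
    ratio = scr.to_mg_dl() / CKDEPI_2021["kappa_mg_dl"][sex]
    value = (
        CKDEPI_2021["scale"]
        * min(ratio, 1.0) ** CKDEPI_2021["alpha"][sex]
        * max(ratio, 1.0) ** CKDEPI_2021["beta"]
        * CKDEPI_2021["age_decay"] ** age
    )
    if sex is Sex.FEMALE:
        value *= CKDEPI_2021["female_factor"]
    return value


def egfr_rlmr(
    scr: Concentration,
    age: float,
    sex: "Sex | str",
    spec: Optional[QSpec] = None,
    q_mode: "QMode | str" = QMode.AUTO,
) -> float:
    """Re-expressed Lund-Malmö Revised eGFR in mL/min/1.73 m²."""
    sex = Sex.coerce(sex)
    spec = spec if spec is not None else get_q_spec("europe")
    q, _ = _resolve_q(age, sex, spec, q_mode)
    r = rescale_creatinine(scr, q)
    q_adult = RLMR["q_adult_umol"][sex]
    r0 = RLMR["threshold_umol"][sex] / q_adult
    c = RLMR["intercept"][sex]
    if r < r0:
        x = c + RLMR["slope_per_umol"][sex] * q_adult * (r0 - r)
    else:
        x = c - RLMR["log_slope"] * math.log(r / r0)
    return math.exp(x + RLMR["age_slope"] * age + RLMR["log_age_slope"] * math.log(age))


def compute_egfr(
    subject: SubjectRecord,
    equation: str,
    spec: Optional[QSpec] = None,
    q_mode: "QMode | str" = QMode.AUTO,
) -> EgfrResult:
    """Evaluate one equation for one subject."""
    spec = spec if spec is not None else get_q_spec("europe")
    if equation == "EKFC":
        q, mode = _resolve_q(subject.age, subject.sex, spec, q_mode)
        return EgfrResult(subject.id, equation, egfr_ekfc(subject.scr, subject.age, subject.sex, spec, q_mode), q, mode)
    if equation == "CKD-EPI":
        return EgfrResult(subject.id, equation, egfr_ckdepi2021(subject.scr, subject.age, subject.sex))
    if equation == "r-LMR":
        q, mode = _resolve_q(subject.age, subject.sex, spec, q_mode)
        return EgfrResult(subject.id, equation, egfr_rlmr(subject.scr, subject.age, subject.sex, spec, q_mode), q, mode)
    raise ValueError(f"unknown equation {equation!r}; expected one of {EQUATION_LABELS}")


def egfr_batch(
    cohort: Sequence[SubjectRecord],
    equation: str,
    spec: Optional[QSpec] = None,
    q_mode: "QMode | str" = QMode.AUTO,
) -> Tuple[List[EgfrResult], List[BatchRejection]]:
    """Evaluate an equation over a cohort, order-preserving.

    Subjects that fail an equation's preconditions (e.g. under-18 for
    CKD-EPI) are returned as rejection records with reasons, never
    silently dropped.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    results: List[EgfrResult] = []
    rejects: List[BatchRejection] = []
    for subject in cohort:
        try:
            results.append(compute_egfr(subject, equation, spec, q_mode))
        except ValueError as exc:
            rejects.append(BatchRejection(subject.id, equation, str(exc)))
    return results, rejects
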