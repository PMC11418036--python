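"""Rescaled-creatinine Q-values.

The Q-value of a population is the median serum creatinine of healthy
persons of a given age and sex; dividing a measured creatinine by Q
yields a dimensionless "rescaled" creatinine whose healthy median is 1.
Rescaling is the common core of the EKFC and re-expressed Lund-Malmö
equations.

Three regimes are implemented:

* **Age polynomials (2–25 y).** For White Europeans, ln(Q) is a
  polynomial in age (with a natural-log age term), creatinine in
  µmol/L. The curves level off at 0.70 mg/dL (women) and 0.90 mg/dL
  (men) at age 25.
* **Adult plateaus (>25 y).** Fixed per-sex constants: 0.70/0.90 mg/dL
  in Europe, 0.97/0.73 mg/dL (men/women) race-free in the US.
* **Gradual-change interpolation (12–25 y) for non-European
  populations.** Healthy children are assumed to share the European
  creatinine growth curve until age 12; between 12 and 25 the curve is
  multiplied by a factor linear in age, from 1 at age 12 to the ratio
  of the population's adult plateau over the European curve at age 25,
  so the interpolated curve meets the adult plateau exactly at 25.

Note on "log": the printed polynomials write "log(age)". Only the
natural logarithm reproduces the stated 0.70/0.90 mg/dL plateaus at
age 25 (base-10 yields ≈2.5 mg/dL); natural log is used throughout and
regression-tested.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from types import MappingProxyType
from typing import Mapping, Optional, Tuple

from .units import UMOL_PER_MGDL, Concentration

__all__ = [
    "Sex",
    "QSpec",
    "QMode",
    "load_q_registry",
    "get_q_spec",
    "q_polynomial",
    "q_poly_europe",
    "q_fixed",
    "q_interpolated",
    "q_lookup",
    "rescale_creatinine",
]

POLY_AGE_MIN = 2.0
POLY_AGE_MAX = 25.0
INTERP_AGE_START = 12.0


class Sex(str, Enum):
    FEMALE = "F"
    MALE = "M"

    @classmethod
    def coerce(cls, value: "Sex | str") -> "Sex":
        if isinstance(value, Sex):
            return value
        v = str(value).strip().upper()
        if v in ("F", "FEMALE", "W", "WOMAN"):
            return cls.FEMALE
        if v in ("M", "MALE", "MAN"):
            return cls.MALE
        raise ValueError(f"cannot interpret sex {value!r}")


class QMode(str, Enum):
    """How Q is obtained for a subject below age 25."""

    AUTO = "auto"  # age curve below 25, plateau above
    POLYNOMIAL = "polynomial"
    INTERPOLATED = "interpolated"
    FIXED = "fixed"  # adult plateau at every age


@dataclass(frozen=True)
class QSpec:
    """A population's creatinine rescaling description.

    poly_coeffs_by_sex holds (intercept, age, ln-age, age², age³)
    coefficients of ln(Q in µmol/L) for the 2–25 y curve, or None for
    populations defined by interpolation against ``reference``.
    Plateaus are stored in mg/dL as printed.
    """

    population_label: str
    poly_coeffs_by_sex: Optional[Mapping[Sex, Tuple[float, float, float, float, float]]]
    adult_plateau_by_sex: Mapping[Sex, float]
    reference: Optional["QSpec"] = None

    def __post_init__(self) -> None:
        for sex in Sex:
            if sex not in self.adult_plateau_by_sex:
                raise ValueError(f"{self.population_label}: missing adult plateau for {sex}")
            if not self.adult_plateau_by_sex[sex] > 0:
                raise ValueError(f"{self.population_label}: plateau must be positive")
        if self.adult_plateau_by_sex[Sex.FEMALE] >= self.adult_plateau_by_sex[Sex.MALE]:
            raise ValueError(f"{self.population_label}: female plateau must be below male plateau")
        if self.poly_coeffs_by_sex is None and self.reference is None:
            raise ValueError(
                f"{self.population_label}: spec needs either age-polynomial coefficients "
                "or a reference population to interpolate against"
            )

    def plateau(self, sex: Sex) -> Concentration:
        return Concentration.mg_dl(self.adult_plateau_by_sex[Sex.coerce(sex)])


def _poly_ln_q(age: float, coeffs: Tuple[float, float, float, float, float]) -> float:
    c0, c1, c2, c3, c4 = coeffs
    return c0 + c1 * age + c2 * math.log(age) + c3 * age**2 + c4 * age**3


def _check_poly_age(age: float) -> None:
    if not (POLY_AGE_MIN <= age <= POLY_AGE_MAX):
        raise ValueError(
            f"age {age} outside the Q-polynomial domain [{POLY_AGE_MIN:g}, {POLY_AGE_MAX:g}] years"
        )


def q_polynomial(age: float, sex: "Sex | str", spec: Optional[QSpec] = None) -> Concentration:
    """Age-polynomial Q for ages 2–25, in µmol/L."""
    spec = spec if spec is not None else get_q_spec("europe")
    sex = Sex.coerce(sex)
    _check_poly_age(age)
    if spec.poly_coeffs_by_sex is None:
        raise ValueError(f"population {spec.population_label!r} has no age-polynomial coefficients")
    return Concentration.umol_l(math.exp(_poly_ln_q(age, spec.poly_coeffs_by_sex[sex])))


def q_poly_europe(age: float, sex: "Sex | str") -> Concentration:
    """European age-polynomial Q-value (µmol/L), ages 2–25."""
    return q_polynomial(age, sex, get_q_spec("europe"))


def q_fixed(sex: "Sex | str", spec: Optional[QSpec] = None) -> Concentration:
    """Adult plateau Q constant for the population (mg/dL)."""
    spec = spec if spec is not None else get_q_spec("europe")
    return spec.plateau(Sex.coerce(sex))


def q_interpolated(age: float, sex: "Sex | str", spec: QSpec) -> Concentration:
    """Gradual-change Q between ages 12 and 25 for a non-European population.

    Returns the reference curve unchanged up to age 12, then the
    reference curve times a factor linear in age with f(12) = 1 and
    f(25) = plateau / reference(25), so Q is exactly continuous with
    the population's adult plateau at 25.
    """
    sex = Sex.coerce(sex)
    if spec.reference is None:
        raise ValueError(
            f"population {spec.population_label!r} has no reference population for interpolation"
        )
    _check_poly_age(age)
    ref = q_polynomial(age, sex, spec.reference)
    if age <= INTERP_AGE_START:
        return ref
    ref25 = q_polynomial(POLY_AGE_MAX, sex, spec.reference).to_umol_l()
    plateau = spec.plateau(sex).to_umol_l()
    ratio = plateau / ref25
    frac = (age - INTERP_AGE_START) / (POLY_AGE_MAX - INTERP_AGE_START)
    factor = 1.0 + frac * (ratio - 1.0)
    return Concentration.umol_l(ref.to_umol_l() * factor)


def q_lookup(
    age: float,
    sex: "Sex | str",
    spec: Optional[QSpec] = None,
    mode: "QMode | str" = QMode.AUTO,
) -> Concentration:
    """Dispatch Q across regimes: age curve on [2, 25], plateau above.

    Ages below 2 are rejected (infancy is out of scope). ``mode=fixed``
    forces the adult plateau at every age, which is how the fixed-Q
    variant of EKFC is evaluated below 25.
    """
    spec = spec if spec is not None else get_q_spec("europe")
    sex = Sex.coerce(sex)
    mode = QMode(mode)
    if age < POLY_AGE_MIN:
        raise ValueError(f"age {age} below the supported minimum of {POLY_AGE_MIN:g} years")
    if mode is QMode.FIXED or age > POLY_AGE_MAX:
        return spec.plateau(sex)
    if spec.poly_coeffs_by_sex is not None:
        return q_polynomial(age, sex, spec)
    return q_interpolated(age, sex, spec)


def q_mode_used(age: float, spec: QSpec, mode: "QMode | str" = QMode.AUTO) -> str:
    """Label of the Q regime :func:`q_lookup` applies for this age/spec."""
    mode = QMode(mode)
    if mode is QMode.FIXED or age > POLY_AGE_MAX:
        return "fixed"
    return "polynomial" if spec.poly_coeffs_by_sex is not None else "interpolated"


def rescale_creatinine(scr: Concentration, q: Concentration) -> float:
    """Dimensionless rescaled creatinine SCr/Q; units reconciled first."""
    if not isinstance(scr, Concentration) or not isinstance(q, Concentration):
        raise TypeError("rescale_creatinine requires Concentration inputs (explicit units)")
    return scr.to_umol_l() / q.to_umol_l()


def _load_raw_registry() -> dict:
    with resources.files("egfrbench.data").joinpath("q_specs.json").open("r") as fh:
        return json.load(fh)


def _build_registry(raw: dict) -> Mapping[str, QSpec]:
    if raw.get("version") != 1:
        raise ValueError(f"unsupported Q registry version {raw.get('version')!r}")
    built: dict[str, QSpec] = {}

    def build(key: str) -> QSpec:
        if key in built:
            return built[key]
        entry = raw["populations"][key]
        coeffs = entry["poly_coeffs_by_sex"]
        if coeffs is not None:
            coeffs = {Sex(s): tuple(float(c) for c in v) for s, v in coeffs.items()}
        ref = entry.get("reference")
        spec = QSpec(
            population_label=entry["label"],
            poly_coeffs_by_sex=coeffs,
            adult_plateau_by_sex={Sex(s): float(v) for s, v in entry["adult_plateau_mg_dl"].items()},
            reference=build(ref) if ref else None,
        )
        built[key] = spec
        return spec

    for key in raw["populations"]:
        build(key)
    return MappingProxyType(built)


_REGISTRY: Optional[Mapping[str, QSpec]] = None


def load_q_registry() -> Mapping[str, QSpec]:
    """Built-in population registry, loaded from the versioned JSON document."""
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = _build_registry(_load_raw_registry())
    return _REGISTRY


def get_q_spec(population: str) -> QSpec:
    registry = load_q_registry()
    try:
        return registry[population]
    except KeyError:
        raise KeyError(
            f"unknown Q population {population!r}; built-ins: {sorted(registry)}"
        ) from None


def register_q_spec(spec: QSpec) -> None:
    """Add a custom population to the in-process registry."""
    global _REGISTRY
    registry = dict(load_q_registry())
    registry[spec.population_label] = spec
    _REGISTRY = MappingProxyType(registry)
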