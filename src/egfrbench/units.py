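"""Serum creatinine concentration values with explicit units.

Creatinine appears in two conventional units: µmol/L (SI, used by the
European Q-value polynomials) and mg/dL (US convention, used for the
adult plateau constants). The conversion factor is 88.4 µmol/L per
mg/dL. All arithmetic inside the package is done in µmol/L; public
interfaces accept either unit through :class:`Concentration`.
"""

from __future__ import annotations

from dataclasses import dataclass

#: µmol/L per mg/dL for creatinine (molar mass convention used clinically).
UMOL_PER_MGDL = 88.4

UNIT_UMOL_L = "umol_l"
UNIT_MG_DL = "mg_dl"
_UNITS = (UNIT_UMOL_L, UNIT_MG_DL)


@dataclass(frozen=True)
class Concentration:
    """A strictly positive creatinine concentration tagged with its unit."""

    value: float
    unit: str = UNIT_UMOL_L

    def __post_init__(self) -> None:
        if self.unit not in _UNITS:
            raise ValueError(f"unknown concentration unit {self.unit!r}; expected one of {_UNITS}")
        if not self.value > 0:
            raise ValueError(f"concentration must be strictly positive, got {self.value}")

    @classmethod
    def umol_l(cls, value: float) -> "Concentration":
        return cls(float(value), UNIT_UMOL_L)

    @classmethod
    def mg_dl(cls, value: float) -> "Concentration":
        return cls(float(value), UNIT_MG_DL)

    def to_umol_l(self) -> float:
        if self.unit == UNIT_UMOL_L:
            return self.value
        return self.value * UMOL_PER_MGDL

    def to_mg_dl(self) -> float:
        if self.unit == UNIT_MG_DL:
            return self.value
        return self.value / UMOL_PER_MGDL

    def as_unit(self, unit: str) -> "Concentration":
        if unit == UNIT_UMOL_L:
            return Concentration.umol_l(self.to_umol_l())
        if unit == UNIT_MG_DL:
            return Concentration.mg_dl(self.to_mg_dl())
        raise ValueError(f"unknown concentration unit {unit!r}")
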