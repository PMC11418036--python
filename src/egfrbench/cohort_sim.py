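"""Synthetic young-adult cohorts for exercising the validation pipeline.

Real validation cohorts of measured GFR are not publicly deposited, so
the pipeline is exercised on synthetic cohorts that reproduce the
published cohort profiles at the marginal level: truncated-normal age
and mGFR, a fixed sex split, a Black/non-Black mix, and serum
creatinine generated from mGFR by inverting the EKFC closed form and
multiplying by log-normal noise exp(ε), ε ~ N(0, σ²).

What this emulates — and what it does not: the marginals of age and
mGFR match the printed means/SDs (as untruncated-normal parameters),
but age and mGFR are sampled independently, creatinine noise is purely
multiplicative, and no assay-recalibration error is modelled. With
σ = 0 the generator is an exact inverse of EKFC, so truth is known
exactly and pipeline identities (bias 0, P30 100) can be asserted.

Sampling uses one global seed spawned into named per-column
substreams, so adding a column never perturbs the others, and a cohort
is byte-identical for a fixed (profile, seed).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from types import MappingProxyType
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__ as _pkg_version
from .equations import EKFC
from .qvalues import QMode, QSpec, Sex, get_q_spec, q_lookup
from .units import Concentration

__all__ = [
    "CohortProfile",
    "SyntheticCohort",
    "scr_from_mgfr",
    "generate_cohort",
    "profile_registry",
    "write_cohort_csv",
]

#: Default multiplicative creatinine noise (SD on the log scale).
DEFAULT_NOISE_SIGMA = 0.15

_STREAMS = ("age", "sex", "race", "mgfr", "noise", "bmi")


@dataclass(frozen=True)
class CohortProfile:
    """Generative parameters for one synthetic cohort."""

    label: str
    n: int
    age_mean: float
    age_sd: float
    mgfr_mean: float
    mgfr_sd: float
    age_lo: float = 18.0
    age_hi: float = 25.0
    mgfr_lo: float = 5.0
    mgfr_hi: float = 250.0
    sex_fraction_female: float = 0.5
    race_black_fraction: float = 0.0
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    generator_equation: str = "EKFC"
    q_population: str = "europe"
    bmi_mean: Optional[float] = None
    bmi_sd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"{self.label}: cohort size must be positive")
        for name in ("age_sd", "mgfr_sd", "noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.label}: {name} must be >= 0")
        for name in ("sex_fraction_female", "race_black_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{self.label}: {name} must lie in [0, 1]")
        if not (self.age_lo < self.age_hi and self.mgfr_lo < self.mgfr_hi):
            raise ValueError(f"{self.label}: truncation bounds must be ordered")
        if self.generator_equation != "EKFC":
            raise ValueError(
                f"{self.label}: only the EKFC inverse model is available as generator equation"
            )


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort plus its provenance."""

    frame: pd.DataFrame
    profile: CohortProfile
    seed: int
    package_version: str = _pkg_version


def _invert_ekfc(mgfr: np.ndarray, age: np.ndarray, q_umol: np.ndarray) -> np.ndarray:
    """Noise-free SCr (µmol/L) such that EKFC returns exactly this mGFR.

    The age factor is divided out first; the power-law branch is chosen
    so that mGFR >= 107.3 (age-adjusted) maps to SCr/Q <= 1.
    """
    age_factor = EKFC["age_decay"] ** np.maximum(age - EKFC["age_knot"], 0.0)
    core = np.asarray(mgfr, dtype=float) / age_factor
    alpha = np.where(core >= EKFC["scale"], EKFC["alpha_low"], EKFC["alpha_high"])
    return q_umol * (EKFC["scale"] / core) ** (1.0 / alpha)


def scr_from_mgfr(
    mgfr: float,
    age: float,
    sex: "Sex | str",
    spec: Optional[QSpec] = None,
    sigma: float = 0.0,
    seed: Optional[int] = None,
) -> Concentration:
    """Serum creatinine consistent with a target mGFR under EKFC.

    With ``sigma`` = 0 this is the exact inverse of the EKFC equation;
    with ``sigma`` > 0 the exact value is multiplied by exp(ε) with
    ε ~ N(0, σ²), which is median-unbiased on the log scale.
    """
    if not mgfr > 0:
        raise ValueError("mGFR must be strictly positive")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    spec = spec if spec is not None else get_q_spec("europe")
    q = q_lookup(age, sex, spec, QMode.AUTO).to_umol_l()
    scr = float(_invert_ekfc(np.asarray([mgfr]), np.asarray([age]), np.asarray([q]))[0])
    if sigma > 0:
        if seed is None:
            raise ValueError("a seed is required when sigma > 0")
        scr *= float(np.exp(np.random.default_rng(seed).normal(0.0, sigma)))
    return Concentration.umol_l(scr)


def _truncnorm_sample(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    if sd == 0:
        if not lo <= mean <= hi:
            raise ValueError("degenerate distribution outside its truncation bounds")
        return np.full(size, float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(profile: CohortProfile, seed: int) -> SyntheticCohort:
    """Draw one cohort from a profile; deterministic per (profile, seed)."""
    streams = dict(zip(_STREAMS, np.random.SeedSequence(seed).spawn(len(_STREAMS))))
    rngs = {name: np.random.default_rng(ss) for name, ss in streams.items()}
    n = profile.n

    age = _truncnorm_sample(rngs["age"], profile.age_mean, profile.age_sd, profile.age_lo, profile.age_hi, n)
    sex = np.where(rngs["sex"].random(n) < profile.sex_fraction_female, "F", "M")
    race = np.where(rngs["race"].random(n) < profile.race_black_fraction, "Black", "non-Black")
    mgfr = _truncnorm_sample(
        rngs["mgfr"], profile.mgfr_mean, profile.mgfr_sd, profile.mgfr_lo, profile.mgfr_hi, n
    )
    spec = get_q_spec(profile.q_population)
    q_umol = np.array(
        [q_lookup(a, s, spec, QMode.AUTO).to_umol_l() for a, s in zip(age, sex)]
    )
    scr = _invert_ekfc(mgfr, age, q_umol)
    if profile.noise_sigma > 0:
        scr = scr * np.exp(rngs["noise"].normal(0.0, profile.noise_sigma, n))

    data = {
        "id": [f"{profile.label}-{i:05d}" for i in range(n)],
        "age_years": age,
        "sex": sex,
        "scr_umol_l": scr,
        "mgfr_ml_min_173": mgfr,
        "race": race,
        "cohort": profile.label,
    }
    if profile.bmi_mean is not None:
        data["bmi"] = _truncnorm_sample(
            rngs["bmi"], profile.bmi_mean, profile.bmi_sd or 0.0, 12.0, 60.0, n
        )
    return SyntheticCohort(frame=pd.DataFrame(data), profile=profile, seed=seed)


def write_cohort_csv(cohort: SyntheticCohort, path) -> None:
    """Write the cohort in the pipeline's CSV schema, byte-deterministic."""
    with open(path, "w", newline="") as fh:
        cohort.frame.to_csv(fh, index=False, float_format="%.6f", lineterminator="\n")


def cohort_csv_bytes(cohort: SyntheticCohort) -> bytes:
    buf = io.StringIO()
    cohort.frame.to_csv(buf, index=False, float_format="%.6f", lineterminator="\n")
    return buf.getvalue().encode()


def _build_registry() -> Mapping[str, CohortProfile]:
    europe = CohortProfile(
        label="Europe-young",
        n=1892,
        age_mean=20.7,
        age_sd=2.1,
        mgfr_mean=89.5,
        mgfr_sd=28.9,
        race_black_fraction=0.0,
        q_population="europe",
    )
    # The combined-US age/mGFR moments are the only ones published; the
    # non-Black and Black sub-profiles reuse them with their own n and mix.
    us = CohortProfile(
        label="US-young",
        n=474,
        age_mean=22.2,
        age_sd=2.2,
        mgfr_mean=61.5,
        mgfr_sd=35.3,
        race_black_fraction=37 / 474,
        q_population="us",
    )
    us_nonblack = replace(us, label="US-young-non-Black", n=437, race_black_fraction=0.0)
    us_black = replace(us, label="US-young-Black", n=37, race_black_fraction=1.0)
    return MappingProxyType({p.label: p for p in (europe, us, us_nonblack, us_black)})


_PROFILES = _build_registry()


def profile_registry() -> Mapping[str, CohortProfile]:
    """Immutable registry of the built-in cohort profiles."""
    return _PROFILES
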