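"""Desk-scale validation pipeline.

Reads (or generates) a cohort, computes eGFR under the requested
equations, stratifies, and emits the performance tables, trend curves,
Bland–Altman summaries, CI-overlap verdicts, and a provenance block.
Everything is a pure function of (input bytes, config): repeated runs
produce byte-identical reports.

Stratification axes follow the usual validation-study subgroups: sex,
race, BMI, and GFR level with the fixed categories <30, 30–45, 45–60,
60–90, 90–120 and ≥120 mL/min/1.73 m². Bins are left-closed
right-open, with the extremes open-ended (so exactly 120 falls in
"≥120"). GFR-level subgroups are formed on mGFR (equation-independent)
and, separately, on each equation's own eGFR, since the defining
estimate is a reporting convention that differs between consortia;
both variants are emitted, labelled. BMI bins default to the WHO
cut-offs <18.5 / 18.5–25 / 25–30 / ≥30 kg/m². Rows missing an optional
field fall into an explicit "unknown" stratum so stratified n always
sums to cohort n.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .cohort_sim import generate_cohort, profile_registry
from .equations import EQUATION_LABELS, SubjectRecord, compute_egfr
from .metrics import performance_table
from .qvalues import QMode, Sex, get_q_spec
from .trends import bland_altman, fit_bias_age_curve, fit_p30_age_curve
from .units import Concentration

__all__ = [
    "GFR_BIN_LABELS",
    "BMI_BIN_LABELS",
    "gfr_category",
    "bmi_category",
    "stratify",
    "RunConfig",
    "read_cohort_csv",
    "add_egfr_columns",
    "run_validation",
    "write_report",
]

log = logging.getLogger("egfrbench")

GFR_BIN_EDGES = (30.0, 45.0, 60.0, 90.0, 120.0)
GFR_BIN_LABELS = ("<30", "30-45", "45-60", "60-90", "90-120", ">=120")
BMI_BIN_EDGES = (18.5, 25.0, 30.0)
BMI_BIN_LABELS = ("<18.5", "18.5-25", "25-30", ">=30")

STRATUM_AXES = ("all", "sex", "race", "mgfr_category", "egfr_category", "bmi_category")


def _categorize(values: pd.Series, edges: Sequence[float], labels: Sequence[str]) -> pd.Series:
    bins = [-np.inf, *edges, np.inf]
    cat = pd.cut(values, bins=bins, labels=labels, right=False, include_lowest=True)
    out = cat.astype(object)
    out[values.isna()] = "unknown"
    return out


def gfr_category(values: pd.Series) -> pd.Series:
    """Fixed GFR categories, left-closed ([90, 120) is '90-120', 120 is '>=120')."""
    return _categorize(pd.Series(values, dtype=float), GFR_BIN_EDGES, GFR_BIN_LABELS)


def bmi_category(values: pd.Series) -> pd.Series:
    return _categorize(pd.Series(values, dtype=float), BMI_BIN_EDGES, BMI_BIN_LABELS)


def stratify(df: pd.DataFrame, by: str, equation: Optional[str] = None) -> Dict[str, np.ndarray]:
    """Boolean row masks per stratum for one axis.

    ``egfr_category`` requires ``equation`` and uses that equation's
    own eGFR column. Missing optional values land in an "unknown"
    stratum, so masks partition the cohort on every axis.
    """
    n = len(df)
    if by == "all":
        return {"all": np.ones(n, dtype=bool)}
    if by == "sex":
        labels = df["sex"].astype(str)
    elif by == "race":
        if "race" not in df.columns:
            raise ValueError("stratification by race requires a 'race' column")
        labels = df["race"].fillna("unknown").astype(str)
    elif by == "mgfr_category":
        labels = gfr_category(df["mgfr_ml_min_173"])
    elif by == "egfr_category":
        if equation is None:
            raise ValueError("egfr_category stratification requires an equation label")
        col = f"egfr_{equation}"
        if col not in df.columns:
            raise ValueError(f"stratification by eGFR requires column {col!r}")
        labels = gfr_category(df[col])
    elif by == "bmi_category":
        if "bmi" not in df.columns:
            raise ValueError("stratification by BMI requires a 'bmi' column")
        labels = bmi_category(df["bmi"])
    else:
        raise ValueError(f"unknown stratification axis {by!r}; expected one of {STRATUM_AXES}")
    labels = pd.Series(np.asarray(labels, dtype=object), index=df.index)
    order: List[str] = []
    if by == "mgfr_category" or by == "egfr_category":
        order = [l for l in GFR_BIN_LABELS if (labels == l).any()]
    elif by == "bmi_category":
        order = [l for l in BMI_BIN_LABELS if (labels == l).any()]
    else:
        order = sorted(set(labels) - {"unknown"})
    if (labels == "unknown").any():
        order.append("unknown")
    return {str(lab): (labels == lab).to_numpy() for lab in order}


@dataclass(frozen=True)
class RunConfig:
    """Fully serialisable description of one validation run."""

    input_csv: Optional[str] = None
    profile: Optional[str] = None
    n_override: Optional[int] = None
    seed: int = 0
    equations: Tuple[str, ...] = EQUATION_LABELS
    q_population: str = "europe"
    q_mode: str = "auto"
    strata: Tuple[str, ...] = ("all", "sex", "mgfr_category")
    compare_fixed_q: bool = False
    n_boot: int = 2000
    ci_method: str = "wald"
    output_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.profile is None):
            raise ValueError("config must name exactly one of input_csv or profile")
        for eq in self.equations:
            if eq not in EQUATION_LABELS:
                raise ValueError(f"unknown equation {eq!r}; expected among {EQUATION_LABELS}")
        for axis in self.strata:
            if axis not in STRATUM_AXES:
                raise ValueError(f"unknown stratum axis {axis!r}; expected among {STRATUM_AXES}")
        QMode(self.q_mode)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("equations", "strata"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["equations"] = list(self.equations)
        d["strata"] = list(self.strata)
        return d


_MANDATORY_COLUMNS = ("id", "age_years", "sex")
_SCR_COLUMNS = ("scr_umol_l", "scr_mg_dl")


def read_cohort_csv(path) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Load a cohort CSV; malformed rows go to a rejects frame with reasons.

    Schema: id, age_years, sex (F/M), exactly one of scr_umol_l /
    scr_mg_dl, optional mgfr_ml_min_173, race, bmi or
    height_cm+weight_kg, cohort.
    """
    df = pd.read_csv(path)
    present_scr = [c for c in _SCR_COLUMNS if c in df.columns]
    if len(present_scr) != 1:
        raise ValueError(
            f"cohort file must have exactly one creatinine column of {_SCR_COLUMNS}, found {present_scr}"
        )
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file lacks mandatory columns: {missing}")
    scr_col = present_scr[0]
    if "bmi" not in df.columns and {"height_cm", "weight_kg"} <= set(df.columns):
        height_m = pd.to_numeric(df["height_cm"], errors="coerce") / 100.0
        df["bmi"] = pd.to_numeric(df["weight_kg"], errors="coerce") / height_m**2

    keep: List[int] = []
    rejects: List[dict] = []
    for i, row in df.iterrows():
        reason = None
        age = pd.to_numeric(pd.Series([row["age_years"]]), errors="coerce").iloc[0]
        scr = pd.to_numeric(pd.Series([row[scr_col]]), errors="coerce").iloc[0]
        try:
            Sex.coerce(row["sex"])
        except ValueError:
            reason = f"unrecognised sex {row['sex']!r}"
        if reason is None and (pd.isna(age) or age < 2):
            reason = "missing or out-of-range age"
        if reason is None and (pd.isna(scr) or scr <= 0):
            reason = "non-positive creatinine"
        if reason is None and "mgfr_ml_min_173" in df.columns and pd.notna(row["mgfr_ml_min_173"]):
            if pd.to_numeric(pd.Series([row["mgfr_ml_min_173"]]), errors="coerce").iloc[0] <= 0:
                reason = "non-positive measured GFR"
        if reason is None:
            keep.append(i)
        else:
            rejects.append({"id": row.get("id", f"row-{i}"), "row": int(i), "reason": reason})
    cohort = df.loc[keep].copy()
    cohort["age_years"] = pd.to_numeric(cohort["age_years"])
    cohort[scr_col] = pd.to_numeric(cohort[scr_col])
    if scr_col == "scr_mg_dl":
        cohort["scr_umol_l"] = cohort["scr_mg_dl"] * 88.4
    cohort["sex"] = [Sex.coerce(s).value for s in cohort["sex"]]
    return cohort.reset_index(drop=True), pd.DataFrame(rejects, columns=["id", "row", "reason"])


def add_egfr_columns(
    df: pd.DataFrame,
    equations: Sequence[str],
    q_population: str = "europe",
    q_mode: str = "auto",
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Append one egfr_<equation> column per equation; NaN where rejected."""
    spec = get_q_spec(q_population)
    df = df.copy()
    reject_rows: List[dict] = []
    for eq in equations:
        values = np.full(len(df), np.nan)
        for pos, (_, row) in enumerate(df.iterrows()):
            subject = SubjectRecord(
                id=str(row["id"]),
                age=float(row["age_years"]),
                sex=Sex.coerce(row["sex"]),
                scr=Concentration.umol_l(float(row["scr_umol_l"])),
            )
            try:
                values[pos] = compute_egfr(subject, eq, spec, q_mode).egfr
            except ValueError as exc:
                reject_rows.append({"id": subject.id, "equation": eq, "reason": str(exc)})
        df[f"egfr_{eq}"] = values
    return df, pd.DataFrame(reject_rows, columns=["id", "equation", "reason"])


def _curve_section(df: pd.DataFrame, equations: Sequence[str]) -> dict:
    """Bias-vs-age and P30-vs-age curves per equation, where fittable."""
    out: dict = {}
    for eq in equations:
        col = f"egfr_{eq}"
        sub = df[df[col].notna() & df["mgfr_ml_min_173"].notna()]
        entry: dict = {}
        age = sub["age_years"].to_numpy()
        if len(sub) >= 50 and age.max() > age.min():
            bias = (sub[col] - sub["mgfr_ml_min_173"]).to_numpy()
            entry["bias_vs_age"] = fit_bias_age_curve(age, bias).to_dict()
        if len(sub) >= 100 and age.max() > age.min():
            within = (
                np.abs(sub[col] - sub["mgfr_ml_min_173"]) <= 0.30 * sub["mgfr_ml_min_173"]
            ).to_numpy()
            entry["p30_vs_age"] = fit_p30_age_curve(age, within.astype(float)).to_dict()
        for mode in ("absolute", "relative"):
            ba = bland_altman(sub[col].to_numpy(), sub["mgfr_ml_min_173"].to_numpy(), mode=mode)
            entry[f"bland_altman_{mode}"] = {
                "mean_difference": ba.mean_difference,
                "loa_low": ba.loa_low,
                "loa_high": ba.loa_high,
                "x_axis": ba.x_axis,
            }
        out[eq] = entry
    return out


def _json_ready(obj):
    if isinstance(obj, dict):
        return {k: _json_ready(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_ready(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return None
    return obj


def run_validation(config: RunConfig) -> dict:
    """Execute the full study at desk scale; returns the report bundle.

    The bundle holds the whole-cohort and per-axis performance tables
    (as records), trend curves, Bland–Altman summaries, CI-overlap
    verdicts, rejected rows, and a provenance block. If the config
    names an output directory the bundle is also written to disk.
    """
    log.info("run_validation: starting (seed=%d)", config.seed)
    if config.profile is not None:
        registry = profile_registry()
        if config.profile not in registry:
            raise ValueError(f"unknown profile {config.profile!r}; built-ins: {sorted(registry)}")
        profile = registry[config.profile]
        if config.n_override:
            from dataclasses import replace

            profile = replace(profile, n=config.n_override)
        cohort = generate_cohort(profile, config.seed).frame
        read_rejects = pd.DataFrame(columns=["id", "row", "reason"])
        source = {"profile": profile.label, "n": int(profile.n), "seed": config.seed}
    else:
        cohort, read_rejects = read_cohort_csv(config.input_csv)
        source = {"input_csv": str(config.input_csv), "n": int(len(cohort))}
    if "mgfr_ml_min_173" not in cohort.columns or cohort["mgfr_ml_min_173"].isna().all():
        raise ValueError("validation requires measured GFR (mgfr_ml_min_173) for the cohort")

    cohort, eq_rejects = add_egfr_columns(cohort, config.equations, config.q_population, config.q_mode)

    tables: Dict[str, pd.DataFrame] = {}
    for axis in config.strata:
        if axis == "egfr_category":
            parts = []
            for eq in config.equations:
                masks = stratify(cohort, axis, equation=eq)
                tab = performance_table(
                    cohort, [eq], masks, seed=config.seed, n_boot=config.n_boot,
                    ci_method=config.ci_method,
                )
                tab.insert(0, "axis", f"egfr_category[{eq}]")
                parts.append(tab)
            tables[axis] = pd.concat(parts, ignore_index=True)
        else:
            masks = stratify(cohort, axis)
            if axis != "all" and any(m.sum() == 0 for m in masks.values()):
                log.warning("axis %s has empty strata", axis)
            tab = performance_table(
                cohort, list(config.equations), masks, seed=config.seed,
                n_boot=config.n_boot, ci_method=config.ci_method,
            )
            tab.insert(0, "axis", axis)
            tables[axis] = tab

    if config.compare_fixed_q:
        fixed_cohort, _ = add_egfr_columns(cohort, config.equations, config.q_population, "fixed")
        tab = performance_table(
            fixed_cohort, list(config.equations), None, seed=config.seed,
            n_boot=config.n_boot, ci_method=config.ci_method,
        )
        tab.insert(0, "axis", "all[fixed-Q]")
        tables["all_fixed_q"] = tab

    curves = _curve_section(cohort, config.equations)

    bundle = {
        "provenance": {
            "package": "egfrbench",
            "version": _pkg_version,
            "config": config.to_dict(),
            "source": source,
        },
        "tables": {axis: _json_ready(tab.to_dict(orient="records")) for axis, tab in tables.items()},
        "curves": _json_ready(curves),
        "rejects": {
            "read": _json_ready(read_rejects.to_dict(orient="records")),
            "equations": _json_ready(eq_rejects.to_dict(orient="records")),
        },
    }
    if config.output_dir:
        write_report(bundle, tables, config.output_dir)
    log.info("run_validation: done (%d table axes)", len(tables))
    return bundle


def write_report(bundle: dict, tables: Mapping[str, pd.DataFrame], outdir) -> List[Path]:
    """Write the JSON report plus one CSV per table axis."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    report = outdir / "report.json"
    report.write_text(json.dumps(bundle, indent=2, sort_keys=True) + "\n")
    written.append(report)
    for axis, tab in tables.items():
        path = outdir / f"performance_{axis}.csv"
        with open(path, "w", newline="") as fh:
            tab.to_csv(fh, index=False, float_format="%.6f", lineterminator="\n")
        written.append(path)
    return written
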