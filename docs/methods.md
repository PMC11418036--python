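# Methods

This note records the models implemented in `egfrbench`, their
assumptions, the parameters that matter, and the design choices made
where conventions genuinely diverge.

## Q-values and rescaled creatinine

A Q-value is the median serum creatinine of healthy persons of a given
age, sex and population. The European curve for ages 2–25 is a
polynomial in ln(Q) (Q in µmol/L) with coefficients per sex
(intercept, age, ln-age, age², age³); above 25, fixed plateaus apply
(0.70 mg/dL women, 0.90 mg/dL men). Three decisions here:

- **The "log(age)" term is the natural logarithm.** The printed
  polynomials do not name the base; only the natural log reproduces
  the stated plateaus at age 25 (the male curve then evaluates to
  0.915 mg/dL vs the printed 0.90; base-10 gives ≈2.46 mg/dL). A
  regression test pins this down. The residual 0.006–0.015 mg/dL gap
  between polynomial and rounded plateau motivates the 0.02 mg/dL
  plateau tolerance used in the consistency checks.
- **Units.** Internal canonical unit is µmol/L (the polynomial's
  unit); mg/dL converts by the factor 88.4. Public APIs take a
  `Concentration` tagged with its unit — a bare number is refused, so
  a mg/dL value can never be silently divided by a µmol/L Q.
- **Gradual-change interpolation for new populations (12–25 y).**
  Healthy children are assumed to share the European creatinine growth
  curve until 12; between 12 and 25 the curve is multiplied by a
  factor linear in age from 1 up to the ratio (population adult
  plateau)/(European curve at 25). The denominator is the *polynomial
  value* at 25, not the rounded plateau: this makes the interpolated
  curve exactly continuous with the population's adult plateau at 25,
  which is the stated purpose of the construction; the plateau-rounding
  discrepancy is thereby confined to the European branch. Ages below 2
  are rejected rather than extrapolated; above 25 the plateau applies
  with no upper age bound.

Built-in populations (Europe, race-free US with plateaus 0.97/0.73
mg/dL) live in a versioned JSON registry; users can register further
populations with the same schema.

## Equations

Coefficients sit in one constants table per equation rather than
scattered literals. EKFC: 107.3·(SCr/Q)^(−α)·0.990^max(age−40,0) with
α = 0.322 below SCr/Q = 1 and 1.132 at or above (continuous at the
breakpoint since both branches give 107.3). CKD-EPI 2021 (race-free):
142·min(SCr/κ,1)^α·max(SCr/κ,1)^(−1.200)·0.9938^age·1.012 for women;
it is restricted to ages ≥ 18 — a hard error, not a warning — because
its log-linear age term misbehaves in children. The `q_mode` flag
makes the fixed-vs-polynomial-Q contrast a one-flag switch: `auto`
uses the age curve below 25 and the plateau above; `fixed` forces the
plateau at every age.

The r-LMR is the Lund-Malmö Revised equation rewritten in rescaled
creatinine. The published LMR is piecewise in plasma creatinine with
sex-specific breakpoints (150 µmol/L women, 180 µmol/L men):
eGFR = exp(X − 0.0158·age + 0.438·ln age) with X linear in creatinine
below the breakpoint and log-linear above. Substituting
pCr = Q_adult·r (r = SCr/Q, Q_adult the European adult plateau) gives
an exactly equivalent function of r alone with a fixed per-sex
rescaled breakpoint r0 = threshold/Q_adult (≈2.26 men, ≈2.42 women),
exactly continuous there. This algebraic re-expression — rather than a
refit — is the package's transcription of the re-expressed equation; a
frozen fixture (eGFR at SCr/Q = 1, age 22: 93.554 men, 96.789 women)
guards it.

eGFR values are never capped or rounded internally.

## Validation metrics

Median bias = median(eGFR − mGFR); imprecision = IQR of the bias
(reported as width with q1;q3); P30/P20 = percentage of estimates
within ±30%/±20% of mGFR, boundary inclusive. Conventions chosen where
the field's reports leave the method unstated:

- **Median-bias CI:** nonparametric bootstrap percentile interval,
  default 2000 resamples, mandatory seed. Published tables show
  asymmetric median CIs consistent with resampling or rank-based
  methods but do not identify one; the bootstrap is an assumption.
- **Proportion CI:** Wald normal approximation on the percent scale,
  clipped to [0, 100] — it reproduces the interval widths printed in
  published validation tables (65.4% at n = 1892 → ±2.1). Wilson is
  available via `method="wilson"`.
- **Quantiles:** linear interpolation (type 7, the numpy default) for
  medians and quartiles.
- **Two equations are "different"** on a metric iff their 95% CIs
  share no point; touching endpoints count as overlap. No hypothesis
  tests and no multiplicity adjustment anywhere, by design.

## Age trends and agreement

Bias-vs-age is a median (τ = 0.5) quantile regression on a 4th-degree
age polynomial. The check-loss minimisation is solved exactly as a
linear program (HiGHS) on standardised ages — deterministic, and exact
on noiseless data where iterative reweighting stalls. A degree-0 fit
equals the sample median, which ties the curve to the bias metric.

P30-vs-age is a least-squares cubic regression spline on the
0/100-scaled within-30% indicator with three free interior knots,
chosen by grid search over triples of age deciles and one local
refinement on a finer quantile grid (no selection rule is standard;
this coarse-then-refine search is the package's choice). Fitted values
are clipped to [0, 100]. Curves store both their fit range and a
possibly narrower evaluation range (studies fit on 18–100 y but
display 18–25); evaluation outside it is refused.

Bland–Altman: mean difference and mean ± 1.96·SD limits, absolute
(mL/min/1.73 m²) or relative (percent). Two conventions are decided,
not inferred: the x-axis is mGFR (differences against the reference,
as GFR-validation figures are drawn), with the classical
mean-of-methods axis behind `x_axis="mean"`; relative differences are
percent of mGFR, with percent-of-mean behind `denominator="mean"`.
Relative mode carries ±30% guide lines.

## Synthetic cohorts

Profiles encode n, truncated-normal age and mGFR (age on [18, 25],
mGFR on [5, 250] mL/min/1.73 m²), a female fraction (default 0.5), a
Black/non-Black mix, and a multiplicative creatinine noise σ (log
scale, default 0.15). Creatinine is generated by inverting the EKFC
closed form — SCr = Q·(107.3/mGFR_adj)^(1/α), branch chosen so
mGFR ≥ 107.3 maps to SCr/Q ≤ 1 — then multiplied by exp(ε),
ε ~ N(0, σ²), which is median-unbiased on the log scale. With σ = 0
the generator is the exact inverse of EKFC (round-trip identity to
1e-9), so pipeline identities (bias 0, P30 100) are checkable exactly.

Built-in profiles: Europe-young (n = 1892, age 20.7 ± 2.1, mGFR
89.5 ± 28.9, all non-Black), US-young (n = 474, age 22.2 ± 2.2, mGFR
61.5 ± 35.3, 37/474 Black), and the US non-Black (437) / Black (37)
sub-profiles, which reuse the combined-US distributions because
separate moments are not published. Means/SDs are the parameters of
the *untruncated* normal; truncation shifts the realised mean (≈+4
mL/min/1.73 m² for the US mGFR profile, negligible for Europe), and
calibration checks account for that shift analytically via the
truncated-normal moments. Age and mGFR are sampled independently, the
sex split is 50/50, and no assay-recalibration error is modelled —
so passing tests demonstrate pipeline correctness and direction of
effect on EKFC-consistent data, not the equations' performance on real
cohorts, whose joint age–GFR structure and creatinine calibration
differ. Sampling uses one global seed spawned into named per-column
substreams (adding a column never perturbs the others); a cohort is
byte-identical for fixed (profile, seed).

## Pipeline

`run_validation` is a pure function of its config: cohort (file or
profile+seed) → eGFR columns per equation → stratified performance
tables → trend curves and Bland–Altman summaries → JSON/CSV report
with a provenance block. GFR category bins are left-closed right-open
with open-ended extremes (a value of exactly 120 is "≥120"); BMI bins
default to the WHO cut-offs <18.5/18.5–25/25–30/≥30 kg/m² (the study
categories are not printed; these are placeholders a user can
override by stratifying externally). eGFR-category subgroups are
computed per equation on that equation's own estimate, mGFR subgroups
once for all — both labelled. Rows missing optional fields fall into
an explicit "unknown" stratum so ns always sum. Subjects failing an
equation's preconditions are reported with reasons, never dropped
silently.

## Problem sizes and numerical notes

The test suite works at desk scale: cohorts of 200–10 000 subjects,
2000 bootstrap resamples for reported CIs (200 in fast pipeline
tests), 500 replicates × 1000 resamples for the bootstrap coverage
property, 5000 points for spline-recovery checks. Degenerate inputs
degrade explicitly: n = 0 strata emit metric-free rows, n < 2 no bias
CI, n < 4 no IQR; all-identical P30 outcomes yield the constant curve;
all-equal ages are a fit error. Cohort CSVs are written with six
decimals, so identities that are exact in memory (1e-9) hold to ~1e-6
through a file round-trip.

## Known limitations

Cystatin C equations, pediatric-only equations, race-coefficient
CKD-EPI variants and body-surface-area de-indexing are out of scope.
The synthetic generator cannot validate equation accuracy on real
populations (see above). Free-knot selection is a heuristic grid
search, not a global optimum. The bootstrap median CI is one defensible
choice among several and does not reproduce any particular published
interval.
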