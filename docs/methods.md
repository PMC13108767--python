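# Methods

This note documents the model implemented by `pifc`, the choices made where
the design was genuinely open, and what the synthetic-data tests do and do
not demonstrate.

## Estimation

**Two-way fixed effects by dummy coding.** The policy–prevalence regressions
are estimated as OLS on a design augmented with country and year indicator
columns (reference-cell coding; first country and year are the reference).
At this panel size (~96 rows per gender: 16 countries × 6 biennial years) the
dummy route is numerically exact and identical in its slope coefficients to
the within-transformation; the test suite verifies equality against an
independently hand-built indicator-matrix least-squares solution to 1e-8 on
randomized small panels. Standard errors are classical OLS errors on that
design (no clustering): they feed only diagnostics, never the reported
confidence intervals, which come from the bootstrap.

Rows with a missing value in any variable of the model at hand are dropped
listwise per model, so the univariable and multivariable fits may use
different estimation samples; no imputation is performed. Fits are
unweighted — each country-year is one observation. Men and women are fitted
strictly separately, and gender differences are described, not tested.

A predictor with zero within-country variance is collinear with the country
effects; the fit refuses with an error naming the predictor rather than
returning an arbitrary solution. VIFs are computed on the raw predictor
columns via the auxiliary-regression definition VIF_k = 1/(1 − R²_k);
perfect collinearity yields `inf`, not an exception. R² components are
squared correlations: country-demeaned (within), country means (between),
and raw series (overall); zero-variance components yield `nan`.

**Interaction model.** The sensitivity specification appends an uncentered
MPOWER × literacy product. Uncentered means the main-effect coefficients are
interpretable at literacy = 0 / MPOWER = 0; downstream code only ever uses
the country-specific marginal effects ∂Prev/∂MPOWER = β_m + β_x·literacy and
∂Prev/∂literacy = β_l + β_x·MPOWER evaluated at each country's current
covariates, which are centering-invariant.

## Scenarios

Policy gaps are computed from each (country, gender)'s 2025 values when
present, else the latest observed year (recorded per output row): MPOWER gap
= 34 − current, literacy gap = 100 − current, affordability gap = 10
regardless of the current level. Single-policy scenarios multiply the gap by
the matching univariable coefficient; the combined scenario sums the three
reductions computed with the multivariable coefficients (the coefficient
source is stamped into each output row). The reduction is a one-time level
shift applied in 2025 and held constant through 2050; no phase-in or lag
structure is modelled. Counterfactual prevalence is floored at 0 and capped
at 100; the floor is the pipeline's only nonlinearity, and the arithmetic is
otherwise fully signed — a positive fitted coefficient yields a negative
"reduction" (higher counterfactual prevalence), never a clamp.

## Incidence and attribution

Annual incidence interpolates the 5-year anchors with a constant increment
(difference/5) inside each interval, reproducing every anchor exactly.
Cumulative totals sum calendar years 2025 through 2050 **inclusive — 26
annual values**; `cumulative_cases(year_from, year_to)` exposes the
25-value alternative, and the convention in force is echoed into `run.log`.
Fractional case counts are carried unrounded through all arithmetic;
rounding (half-up for counts, one decimal for percents) happens only in the
`*_report.csv` outputs.

Levin PAFs are computed at the finest (country, gender, site, scenario)
stratum with prevalence as a proportion — the function raises on any value
outside [0, 1], which catches percent/proportion confusion by contract.
Because Levin's formula is nonlinear, coarser levels (country, site, HDI
tier, region) are obtained only by case-weighting: aggregate PAF =
Σ attributable / Σ total, aggregate PIF = Σ preventable / Σ total. Relative
risks are gender-specific; a gender="both" row is used as fallback when no
gender-specific value exists (logged), and (cervix, men) is inapplicable by
construction and skipped, not errored. Prevalence is treated as current
smoking versus all others, matching the current-smoking meta-analytic RRs,
and the scenario prevalence is held at its (possibly floored) 2025 value for
the whole window with no exposure–outcome lag.

## Uncertainty

Percentile bootstrap throughout (the CI is taken from the empirical
replicate distribution; no BCa correction), with the point estimate always
computed from the unresampled data. One master seed spawns per-replicate
substreams, so replicates are order-independent. Failing replicates (e.g., a
singular refit) are dropped and counted; more than 10 % failures aborts.

Three resampling units:

- **country** (default, 1,000 replicates): countries drawn with replacement;
  a country drawn twice is relabelled and enters the refit as two distinct
  units; regressions, scenarios, and attribution are rerun per replicate.
  Used for regional, HDI-tier, and site-level CIs. Country-keyed CIs are
  refused under this unit — replicate country sets differ.
- **country_panel_rows**: each country's fitting-year rows resampled with
  replacement (coefficient uncertainty without dropping countries).
- **rr_lognormal**: each RR redrawn from a lognormal with median at its
  point estimate and log-SD matched to its 95 % CI. Regressions are left
  untouched, so this unit is coherent for per-country CIs, and it is what
  the run driver uses for the country table.

The choice of unit for per-country intervals is an interpretation: resampling
countries cannot produce a CI for a single country's estimate, so some
within-replicate source of variation (RR uncertainty, within-country row
resampling) is required, and the unit used is recorded in `run.log`.

Sensitivity analyses: multiplying projected incidence by a constant (0.9 /
1.1) scales every case count exactly and leaves PAF/PIF untouched — the
tests verify the scaling commutes exactly with aggregation; and the
interaction model replaces the combined-scenario coefficients with the
marginal effects above (with β_x = 0 this reproduces the main pipeline
bit-for-bit, verified).

## Synthetic data

The generator emulates the study conditions rather than any real dataset:
16 countries (canonical names and HDI tiers included), biennial panels
2010–2020 plus a 2025 baseline, prevalence generated from the same linear
fixed-effects structure the estimator assumes, with defaults chosen once as
realistic for the region — true coefficients (men) of −0.26 pp per MPOWER
point (the regional effect ceiling), −0.18 per affordability unit, −0.20 per
literacy point, women scaled to their compressed prevalence range
(intercepts 65 / 22 pp; country-effect SD 4 / 2 pp; year-effect SD 0.8 pp;
residual SD 1.0 pp); MPOWER integer 20–31 with mild positive correlation to
literacy (ρ ≈ 0.3, so VIF diagnostics and the interaction sensitivity have
realistic structure); affordability 0–15 % of GDP per capita; literacy
30–100 %. Prevalence is clipped to [0, 100]; the clipped fraction is
recorded in the returned ground truth and a warning fires above 5 %
(recovery tests run in zero-clipping regimes). Case anchors grow exactly
linearly from their 2025 base, so interpolation is exact by construction,
and RRs are drawn log-uniformly in [1.1, 10] with ±25 %-log CI bounds for
the lognormal resampler.

Because the generator shares the estimator's functional form, passing
recovery tests show correctness of the estimation machinery, not robustness
to misspecification: real panels have measurement error in policy scores,
non-linear responses, lagged behaviour, and unmeasured time-varying
confounding, none of which the synthetic data exhibit. Scenario magnitudes
computed on synthetic data depend on the chosen true coefficients and should
not be read as regional estimates.

## Problem sizes and numerical choices

The default test suite runs reduced bootstrap replicate counts (tens) and
the acceptance script the full 1,000; the bootstrap-coverage property is
checked with 300 outer replicates × 600 bootstrap draws of a known normal
sampling distribution, for which the percentile interval's true coverage at
n = 40 is ≈ 93 %. Oracle equalities are asserted at 1e-8, interpolation
exactness at 1e-9, conservation at 1e-6 relative. Ties in quantiles use the
linear-interpolation default. Degenerate inputs (single country, constant
predictor, empty CI columns, factor ≤ 0) raise typed errors from
`pifc.errors` rather than propagating numpy warnings.

## Known limitations

- Associations are treated as causal when projecting scenarios; time-varying
  confounders (economic growth, enforcement intensity) are not modelled.
- Uniform gender-specific coefficients are applied across countries.
- No lag between a prevalence change and the cancer-risk change; effects
  start in 2025 and persist unchanged for 25 years.
- Former-smoker risk, smoking intensity, and water-pipe-specific risks are
  out of scope; prevalence is a single current-smoking dichotomy.
- GLOBOCAN-style projections are consumed as given; only the ±10 % scaling
  probes their uncertainty.
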