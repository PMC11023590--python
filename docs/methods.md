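# Methods

## The structural system

The package models the joint evolution of country-level life satisfaction
(LS, a 0–10 ladder average) and healthy life expectancy at birth (HLEB,
years) as a two-equation simultaneous system.  The happiness equation
includes contemporaneous HLEB; the health equation includes the trailing
k-year mean of LS (`LSk`, k = 4 by default).  Both equations share the
exogenous regressors: log GDP per capita, the Gini index, five religion
variables (strict-majority dummies for the social coding, population
shares for the individual coding) and three education variables (gross
enrolment rates for the social coding, per-student expenditures in
thousand PPP dollars for the individual coding).  Crossing the two religion
codings with the two education codings yields the four estimation contexts
whose published coefficient tables ship as fixtures.

Simultaneity has two sources: HLEB carries its own disturbance into the
happiness equation, and the two disturbances are cross-correlated.  `LSk`
is predetermined — built entirely from past LS — so it is treated as part
of the instrument set; the happiness equation is then just-identified
(HLEB instrumented by `LSk` given the common exogenous regressors).  A
configuration flag treats `LSk` as endogenous instead, mirroring
robustness fits that instrument the 4-year mean with the 5-year mean.

## Estimation

`two_sls` and `three_sls` are implemented directly from the textbook
formulas.  2SLS projects each endogenous regressor on the instrument
matrix (via a QR factorisation, never forming the n×n projection);
residuals always use the original regressors.  3SLS is non-iterated:
one feasible-GLS step on the stacked system, weighting by the inverse of
the cross-equation residual covariance estimated from the 2SLS residuals
with 1/n scaling (no degrees-of-freedom correction).  Standard errors come
from the inverse weighted cross-product matrix; inference is classical and
normal-based (z statistics, p = 2(1−Φ(|z|)), 95% CI at ±1.959964·SE),
matching the layout of the published tables.  Per-equation R² uses
structural residuals against the centred total sum of squares.  A singular
residual covariance triggers a logged fallback to per-equation 2SLS.

Degenerate regressors (zero sample variance — e.g. a majority dummy for a
faith with no majority country in a particular draw) make the design
rank-deficient; `prune_degenerate_regressors` drops them with a warning
before fitting, which is the standard remedy and mirrors how a fixed
country sample pins which dummies are estimable.

Two fixed-effects modes exist.  `pooled` (default) estimates the equations
with a common intercept and is the only mode that can produce coefficients
on time-invariant religion dummies, which the published tables contain.
`within` demeans every variable by country first; it annihilates
time-invariant regressors, which are detected, reported and excluded from
the transformed specification.  How the original analysis combined
country fixed effects with time-invariant dummies is not reconstructable;
both modes are therefore shipped and the pooled mode is used for
reproduction.

Lag selection (`select_lag`) refits the system for each candidate k on the
common sample where the deepest lag is defined, and picks the k maximising
the health-equation R², ties broken toward smaller k.

## Coefficient aggregation

Aggregation operates on coefficient tables (printed or freshly estimated).
Significance is p < α with α = 0.10: this is the unique level that
reproduces all eight published religion-link averages (0.52, 0.59, 0.21,
0.51 for happiness; −0.26, −0.22, 2.96, −1.31 for health), including the
two borderline entries with p = 0.056 and p = 0.059.  Sign matrices report
+/−/0 per (variable, context) at the same α.

Cross-context differences (majority-coded minus share-coded religion
tables, and enrolment- minus expenditure-coded education tables) are
offered under three significance policies — `raw` (always subtract the
printed estimates), `zero_ns` (zero out non-significant estimates first),
`null_if_either_ns` (report 0 unless both are significant) — because the
published difference table is internally inconsistent: its Christianity
health cell subtracts a non-significant estimate (−1.456 = raw), its
secondary-education happiness cell zeroes one (−0.060 = zero_ns), and its
Islam happiness cell nulls a difference despite one significant entry
(0.000 = null_if_either_ns).  No single rule reproduces every cell, so the
package exposes all three and does not guess an intent.

Cumulative education gains per level L ∈ {primary, secondary, tertiary}
are contribution(L) = coef(GE_L)·mean(GE_L) + coef(EE_L)·mean(EE_L), using
the enrolment coefficient from the social-context table and the
expenditure coefficient from the individual-context table, coefficients
included regardless of significance, expenditure means in thousand PPP
dollars, cumulated primary → secondary → tertiary.  This rule was
reconstructed by requiring all six published triples to match at two
decimals; one published value (minority-context primary health, printed
7.14) recomputes as 7.13, apparently a rounding slip in the source.

The shipped summary-statistics fixture reproduces the printed table
verbatim, including its anomalies: the per-student expenditure minima are
printed in plain dollars inside thousand-dollar rows, so the min ≤ mean
ordering fails for those rows.  `validate_fixtures` reports (rather than
corrects) these cells, alongside cell-by-cell z = coef/SE and CI checks
on all eight coefficient tables.

## Dynamics

The couplings η3 (happiness per year of healthy life) and θ3 (years per
ladder point of the lagged happiness mean) — by default the averages of
the four published context estimates, 0.086 and 3.161 — are embedded in
the deviation-from-equilibrium recursion

    hap[t] = η3·hea[t−1]
    hea[t] = (θ3/k)·Σ_{j=1..k} hap[t−j]

with companion matrix of dimension k+1.  Although the happiness equation
is contemporaneous in the statistical model, the dynamics use a one-year
lag on both couplings: that discretisation is the only one consistent
with the published eigen-pair (±√(0.086·3.161) = ±0.521 with unit
eigenvectors (∓0.163, 0.987)), and annual steps match annual data.  The
discrepancy is deliberate and documented rather than resolved.  Printed
eigenvector components and the standardized cross-effect
(θ3·mean(LS)/mean(HLEB) = 0.2758 → "0.27") follow the source's
truncate-toward-zero convention, which the package reproduces alongside
full precision.

A shock trajectory iterates x[t] = A·x[t−1] from a one-coordinate initial
deviation.  Because the transition matrix is entrywise nonnegative,
deviations after a positive shock never cross zero; the "oscillation" is
damped ringing — repeated rise and fall of the envelope.  The oscillation
flag therefore triggers on either ≥2 sign changes of a series or ≥2
direction reversals of its first differences (monotone decay stays
unflagged).

Convergence time is the first step from which both series stay within
rel_tol of equilibrium, with each series measured against its own peak
amplitude.  This per-series normalisation makes the answer a property of
the damping envelope rather than of the (incommensurable) units of the
two series, and yields 8 annual steps at 1% tolerance for shocks on either
coordinate — consistent with ρ⁸ = 0.0055 ≤ 0.01 < ρ⁷ = 0.0105 for spectral
radius ρ = 0.521.  Normalising by the raw shock magnitude instead is
available (`normalize="shock"`); it yields 10 steps for a happiness shock
because the health series is amplified by θ3 ≈ 3.2 relative to the shock.

## Synthetic data

The generator draws balanced panels from the structural system with known
parameters, so recovery is checkable exactly.  Defaults are the study
conditions: 162 countries × 21 years (2000–2020, 3402 records), k = 4,
structural coefficients at the published majority/enrolment estimates, and
cross-equation error correlation 0.3.  Disturbance scales (σ_ε = 0.60,
σ_ζ = 2.50) are calibrated so a default fit reproduces the reported
goodness of fit (R² ≈ 0.60 happiness, ≈ 0.73 health).

Exogenous processes are not specified by the source and are chosen once to
match the printed summary ranges: log GDP is a country intercept (mean 9.0,
SD 1.1) plus 2%/year drift plus AR(1) noise; the Gini index is a bounded
AR(1) reflected into [23.2, 64.8]; religion shares are drawn once per
country from a Dirichlet concentrated on a dominant faith and held constant
over time, with dominant faiths allocated by largest-remainder proportional
counts (8:90:2:46:1 majorities plus 15 no-majority per 162 countries) so
rare-majority faiths are represented at every panel size; enrolments and
expenditures are country intercepts with mild trends and clipping to the
observed ranges; life expectancy at birth tracks HLEB with an ~8-year gap.

Generation is exact and loop-free per year: the health equation contains
no contemporaneous LS, so each year draws (ε, ζ) jointly, computes HLEB
from the predetermined `LSk`, then LS from HLEB.  A burn-in of k + 4 years
initialises the lag window from the per-country deterministic fixed point
and is discarded.  All draws derive from a single seeded generator in
documented order, so regeneration is bitwise identical.  Structural
consistency is tested: plugging the true parameters into the equations on
generated data recovers the drawn disturbances to < 1e−10.

What the generator does **not** emulate: cross-country shock correlation
(countries are independent given the common trends), COVID-era breaks,
time-varying religion shares, and measurement error in LS or HLEB.
Passing recovery tests therefore show that the estimator is correct under
the stated data-generating assumptions, not that those assumptions hold
for the real compiled dataset — which is not redistributable, so the
published coefficient values themselves are reproduced only through the
shipped printed tables, not re-estimated.

## Numerical and testing choices

- All validation tolerances for "exact" identities are 1e−10…1e−12; the
  3SLS implementation is required to match an independently coded
  brute-force stacked-GLS oracle (explicit Kronecker-product weighting) to
  1e−8 on small instances.
- Parameter recovery is checked over 100 seeded replicates at the default
  study scale: 95% CI coverage of both couplings ≥ 90/100, mean bias of
  η̂3 below 0.01.  The endogeneity demonstration (correlation 0.5) checks
  |OLS bias| > |3SLS bias| for η3 over 100 replicates; lag selection must
  recover k = 4 modally over 20 replicates.  These simulation sizes keep
  the full suite under a minute of estimator time while leaving the Monte
  Carlo margins comfortable.
- The estimation-to-dynamics round trip uses a wide cross-section (2500
  countries) with light health-side noise: the happiness coupling is
  instrument-identified and its relative precision has a floor of order
  1/(θ3·√n) that no noise scale removes, so the cross-section, not the
  noise level, is the lever that tightens the fitted eigenvalues.
- Missingness injection blanks only interior cells of each country-series
  (endpoints are never removed), so linear interpolation can always
  restore a value; the interpolation report counts unfillable leading and
  trailing gaps, and countries still incomplete are dropped and listed at
  balance enforcement.

## Known limitations

- The real compiled panel is not available; all estimator claims are
  synthetic-data claims plus fixture-level reproduction of the published
  arithmetic.
- Classical (non-cluster-robust) standard errors, matching the published
  tables; serially correlated disturbances within country would call for
  clustering, which the package does not implement.
- The within mode cannot reproduce the published tables (their
  time-invariant dummies would be annihilated); it exists for sensitivity
  analysis.
- No GMM, LIML, dynamic-panel (Arellano–Bond) or vector error-correction
  estimators; the source analysis explicitly declines the latter.
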