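# ethos

Simultaneous-equation panel analysis of happiness and health: a
two-equation system linking country-level **life satisfaction** (LS, a
0–10 ladder) and **healthy life expectancy at birth** (HLEB, years),
estimated by three-stage least squares, post-processed into
religion/education link summaries, and embedded in a linear dynamical
system to study stability and convergence after shocks.

It is written for quantitative epidemiologists and well-being researchers
who work with country-year panels and want every stage — data
construction, system estimation, coefficient aggregation, dynamics — as
tested, reproducible code.

## The model

For country *i* and year *t*:

```
LS[i,t]   = η0 + η1·lnGDP[i,t] + η2·GINI[i,t] + η3·HLEB[i,t] + η'·REL[i,t] + η''·EDU[i,t] + ε[i,t]
HLEB[i,t] = θ0 + θ1·lnGDP[i,t] + θ2·GINI[i,t] + θ3·LSk[i,t]  + θ'·REL[i,t] + θ''·EDU[i,t] + ζ[i,t]
```

where `LSk` is the mean of LS over the previous *k* years (k = 4 in the
headline specification), REL is five religion variables (majority dummies
or population shares) and EDU three education levels (gross enrolment
rates or per-student expenditures).  HLEB is endogenous in the happiness
equation — the disturbances (ε, ζ) are cross-correlated — so the system is
estimated by 2SLS/3SLS with `LSk` (predetermined by construction) in the
instrument set.  The 3SLS step weights the stacked equations by the
inverse cross-equation residual covariance.

The estimated couplings η3 (happiness per year of healthy life) and θ3
(years of healthy life per ladder point of lagged happiness) feed the
deviation dynamics

```
hap[t] = η3·hea[t−1],    hea[t] = (θ3/k)·Σ_{j=1..k} hap[t−j]
```

whose companion-matrix eigenvalues decide stability: for k = 1 they are
±√(η3·θ3).

A synthetic-data module generates balanced panels from this exact
structural model with known parameters (including the cross-equation error
correlation that makes single-equation OLS biased), so estimation and
dynamics are testable end to end without any external download.  The
published coefficient tables and summary statistics ship as CSV fixtures
in `src/ethos/fixtures/`.

## Worked example

```
$ python analysis/04_aggregate_links.py
average couplings: health->happiness 0.086, lagged happiness->health 3.161
mean significant religion links (happiness): [0.52, 0.59, 0.21, 0.51]
mean significant religion links (health):    [-0.26, -0.22, 2.96, -1.31]
cumulative education sums, majority context, LS: [-1.09, -0.82, -1.0]
cumulative education sums, majority context, HLEB: [7.2, 9.29, 10.27]
...
$ python analysis/05_dynamics.py
eigenvalues: [-0.521, 0.521] (stable: True)
unit eigenvectors: [[-0.163, 0.987], [0.163, 0.987]]
oscillating convergence after a unit happiness shock: 8 annual steps at 1% tolerance
standardized cross-effect: 0.27
```

Reading the output: averaged over the four estimation contexts, a year of
healthy life expectancy is associated with +0.086 ladder points of life
satisfaction, and a ladder point of the 4-year happiness mean with +3.16
years of healthy life.  At significance level 0.10, religions on average
link positively with happiness and negatively with health, while education
links cumulate to a gain of about 10.3 years of HLEB and a loss of about
1 ladder point of LS through tertiary education in majority-religion
contexts.  The coupled system is globally stable (spectral radius 0.521 <
1): after a one-point happiness shock both series ring down and are within
1% of their peak amplitudes after 8 annual steps.  Rescaled by the sample
means, θ3 corresponds to a standardized cross-effect of 0.27.

The numbered scripts under `analysis/` run the full synthetic pipeline:
`01_simulate_panel.py` (162 countries × 21 years = 3402 records from the
structural model), `02_prepare_panel.py` (interpolation, majority dummies,
LSk4, balancing), `03_estimate_system.py` (3SLS in all four contexts plus
lag selection over k ∈ {3,4,5}), then `04`/`05` as above.  The same stages
are exposed as a CLI (`ethos simulate|prepare|estimate|aggregate|dynamics|run`).

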