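# Methods

## Scope and data model

The package estimates incident cancer cases for a target year from three
dense surfaces per sex and site: deaths, incident cases and person-years,
each indexed by 5-year age group (18 bands, 0–4 … 85+, the CI5 convention
used by Spanish registries; configurable) and single calendar years. Zeros
must be explicit in input files by default so that extraction gaps surface
as errors rather than silent zero-filling. Ages enter all models at band
midpoints, with 87.5 for the open 85+ band. The bundled ICD-10 site catalog
groups six frequent sites per sex plus an "others" remainder; the all-sites
aggregate (excluding non-melanoma skin, C44) is defined additively as the
sum over sites, and the reader enforces disjointness of the code sets so the
aggregate cannot double-count.

## Stage 1: age-period-cohort mortality projection

Deaths are Poisson with mean `N·(A_a + D·p + P_p + C_c)^5`: the fifth root
of the rate is linear in the components. Identifiability is imposed by
restricting the nonlinear period and cohort components to the null space of
`{1, axis position}` — zero sum and zero linear slope — so the drift `D`
uniquely carries the linear trend. Periods are single years (the method is
applied to annual series); cohorts are year-minus-age-midpoint diagonals
grouped into 5-year bands, with bands observed in fewer than two cells
merged into their nearest neighbour.

The likelihood is maximised by Fisher-scoring IRLS derived for the
non-canonical link `g(μ) = (μ/N)^{1/5}` (working response
`z = η + (y−μ)/(5Nη⁴)`, weights `w = 25Nη³`), with step-halving on deviance
increase. Because the linear predictor of a power link can cross zero, η is
floored at 1e−6 before being raised to the fifth power — the standard
truncation in power-link projection practice. On noiseless inputs the fit is
an exact fixed point, the constraints hold to ~1e−15, and fitted totals
reproduce observed totals to machine precision; at registry scale the drift
estimator is unbiased to within ~0.5% (residual cohort-band discretisation).

Projection beyond the window keeps `A_a` and the drift, sets future period
perturbations to zero, and lets unobserved cohorts inherit the nearest
observed cohort component. The drift may be attenuated by a schedule of
per-5-year-block fractions (default 1.0, 0.75, 0.5, 0.25, continuing at the
last value) — the published "cut trend" recipe; at the 3-year horizons used
here the default is effectively full drift. Strata averaging fewer than 5
deaths/year over the window (configurable) are too sparse for the
decomposition and fall back to the age-specific mean rates of the window's
last five years.

## Stage 2: the IMR model

Incident cases are Poisson with the observed deaths as offset and
`log IMR = β₀ + β₁t + β₂t² + s(age)`, where `t` is the year centred on the
window mean and `s` is a linear spline with four knots at the 10th
percentile, first tertile, second tertile and 90th percentile of the
death-weighted pooled age distribution ("mortality pool"; weighting by
deaths rather than person-years is our reading of that phrase). Knot
computation errors out if deaths are so concentrated that fewer than four
distinct quantiles exist. Cells with zero deaths are excluded from the
likelihood (log 0 offset undefined) but their IMR remains defined by the
linear predictor. The model family is nominally a GLMM; since only fixed
effects are specified, the default is the fixed-effects model with an
optional random intercept per age group behind a flag.

Priors are weakly informative Normal(0, 10²) on all coefficients; at
registry scale the likelihood dominates. Two fitting paths share this
posterior:

* **MAP/Laplace (default in validation loops):** penalized Newton-IRLS to
  the posterior mode, draws from the Gaussian (Laplace) approximation.
  Deterministic and ~milliseconds per fit.
* **MCMC:** emcee ensemble sampling in the Laplace-whitened space
  (`β = β_MAP + Lz`), which removes the coefficient correlations that slow
  the stretch move; walkers are grouped into 4 pseudo-chains for split-R̂
  and ESS, with a convergence gate at R̂ ≤ 1.05. Defaults: 1000 warm-up and
  1500 retained steps (stretch-move autocorrelation is ≈15–20 steps here,
  so each walker contributes ≥50 effective draws), 2000 retained draws.

On well-conditioned fixtures the two paths agree: MCMC medians fall within
a small fraction of one posterior SD of the MAP estimates and posterior SDs
match to ~5%.

## Scenario projection

Scenarios are applied per age group and per posterior draw to the fitted
IMR series: C1 takes the last fitted value, C3/C5 the mean of the last 3/5,
and L/Q fit ordinary least squares to log-IMR over the trend window
(default: the full fitted series) and extrapolate. Fitting on the log scale
guarantees positive extrapolations; results are floored at 1e−6. The L/Q
scenarios refit a trend to the fitted IMR values rather than extrapolating
the model's internal year polynomial; the latter is a possible variant but
would make L/Q insensitive to the choice of trend window. Expected cases
for a target year are the death-weighted sum over ages per draw, summarised
by the posterior median and central 95% interval; the all-sites estimate is
the sum of site-level estimates. Rounding to integers happens only at
report rendering (half away from zero; deviations to 1 decimal, MAPE to 2).

## Back-validation design

For target year T the mortality window is `[T−3−20+1, T−3]` projected over
`[T−2, T]`, and the IMR window `[T−5−15+1, T−5]` projected over `[T−4, T]`
(lags 3 and 5 years, windows 20 and 15 years by default). A target of 2013
therefore uses mortality 1991–2010 and an IMR series 1994–2008, and rolling
targets 2013→2004 never requires mortality before 1982 or incidence before
1985 — matching the availability of the data the design mimics. The
constant-family lookback counts the last available *fitted* IMR years, i.e.
ends 5 years before the target. Inputs are hard-truncated at the lag
boundaries before any fitting, so deleting all later data from the inputs
changes no output byte (the leakage guard asserted in the tests). The
scenario with minimal MAPE is selected per sex and site; exact ties favour
the simpler assumption (C1 < C3 < C5 < L < Q). Validation years with zero
observed cases are dropped from MAPE with a warning; the period-total
deviation is still computed.

Funnel statistics plot each site's period deviation against its mean annual
observed cases with Poisson control limits `±z·100/√(total observed)` at
z = 1.96 and 3.09. These limits are this package's declared choice, not a
reproduction of any published figure's (undocumented) limits.

## Synthetic registry

The generator draws deaths from the stage-1 model (Poisson around
`N·η⁵` with configurable age curve, drift, period/cohort perturbations) and
cases from the stage-2 model (Poisson around deaths × IMR, with the IMR's
constant/linear/quadratic year trend acting on the log scale, coherent with
the log-linear model and the L/Q scenarios). Defaults are sized like a
mid-size southern-Spanish province: ~460,000 person-years per sex growing
0.5%/year, ~1,000–1,400 all-sites deaths and ~1,700–2,400 incident cases
per year in men, base IMR falling from 3.5 in childhood to 1.3 at 85+,
drift 0.0005 on the fifth-root scale (≈1%/year rate growth). The
mortality and incidence streams use decoupled seeds; the validation fixture
also returns the noiseless expected incidence of held-out years so recovery
tests compare against generative truth, not one realisation.

What the generator does *not* emulate: overdispersion (the estimation model
itself assumes Poisson), screening-induced IMR shocks (the known failure
mode of the method for breast and prostate cancer), coding changes, and
migration. Passing recovery tests therefore demonstrate correctness of the
implementation under the model's own assumptions, not robustness of the
method to real-world IMR disruptions.

## Experiment sizes and thresholds used in the tests

Recovery and discrimination experiments use 12–20 seeded replicates with
3 validation target years each — enough that Monte-Carlo error is small
relative to the effects probed while the whole suite stays fast. The
linear-trend fixture uses a 2%/year log-IMR slope: over the 5-year
projection gap this biases the constant scenarios by ~10–15%, an order of
magnitude above the ~3–4% yearly forecast noise of a ~2,000-case registry,
so the L scenario should and does win the MAPE comparison in a clear
majority of replicates (Q, which nests L, takes most of the remainder). On
constant-IMR fixtures the spread among C1/C3/C5 MAPEs is required to stay
under 2 percentage points, the scale implied by that same forecast noise;
observed spreads are ~0.3. Coverage of the linear-trend coefficient by the
95% interval is required in ≥90% of 20 replicates.

## Known limitations

* The method degrades when counts are small, the IMR is large, or the IMR
  shifts abruptly (screening programmes); the sparse-stratum fallback and
  the funnel display mitigate but do not remove this.
* The Laplace approximation slightly understates tail uncertainty for very
  sparse strata; use the MCMC path for production interval estimates there.
* Weighted quantiles for knots use the discrete (lower) convention; with
  18 age bands, knots land on band midpoints.
* Period perturbations are not extrapolated; projections inherit only the
  drift, so sudden period effects in the last fitted years propagate into
  neither stage-1 projections nor scenarios.
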