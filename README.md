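# imrest

Estimation of cancer incidence from mortality data via incidence-to-mortality
ratios (the IMR method), with a built-in back-validation framework for
choosing the IMR-trend assumption.

## Who this is for

Cancer registries and epidemiologists who need incidence figures for regions
or years where a population-based registry count is not (yet) available, but
official mortality statistics are. The package implements the two-stage
estimation used for national incidence estimates in Spain and in the
GLOBOCAN/EUCAN family of projects, plus an objective goodness-of-fit score
to replace the traditionally subjective choice of IMR scenario.

## The method

**Stage 1 — mortality projection.** Deaths are modelled with an
age-period-cohort decomposition under a power-5 link
(the NORDPRED formulation):

```
R_ap = (A_a + D·p + P_p + C_c)^5
```

where `R_ap` is the mortality rate for age group `a` in period `p`, `A_a`
the age component, `D` the common drift (the linear trend shared by the
period and cohort axes), and `P_p`, `C_c` nonlinear period and cohort
components constrained to zero sum and zero slope. The fitted model projects
expected deaths to the target year, optionally damping the drift with the
1.0/0.75/0.5/0.25 five-year-block "cut trend" schedule.

**Stage 2 — the IMR model.** Incident cases are Poisson with the observed
deaths as offset:

```
cases_at ~ Poisson(deaths_at · IMR(a, t))
log IMR(a, t) = β₀ + β₁t + β₂t² + s(age)
```

with a second-degree polynomial in the year of diagnosis and a linear spline
in age with four knots at the 10th percentile, first and second tertiles and
90th percentile of the death-weighted age distribution. The posterior
(Normal(0, 10²) priors) is sampled by ensemble MCMC (emcee, with split-R̂ and
ESS gates) or approximated deterministically by a penalized-IRLS MAP fit
with Laplace draws.

**Scenarios.** Between the last fitted IMR year and the target year the IMR
follows one of five assumptions: C1 (last value), C3/C5 (mean of last 3/5
values), L/Q (linear/quadratic extrapolation of log-IMR). Expected cases are
`E = Σ_age IMR(age, y) · projected_deaths(age, y)`, draw by draw.

**Back-validation.** Each target year is re-estimated using only data
available under realistic reporting lags (mortality lag 3 years over a
20-year window; incidence lag 5 years over a 15-year window), and scored
against the registry's observed cases by the signed relative deviation
`100·(E−O)/O` and the mean absolute percentage error
`MAPE(s) = 100/n · Σ_i |E_i(s)−O_i|/O_i`; the scenario with the smallest
MAPE wins.

A synthetic-registry generator (Poisson surfaces with the exact generative
structure above, sized like a ~920,000-inhabitant province) makes every
stage testable without access to confidential registry microdata.

## Worked example

```python
from imrest import (simulate_mortality, simulate_incidence, simulate_population,
                    run_back_validation)
from imrest.synthetic import SyntheticConfig
from imrest.reporting import render_summary

cfg = SyntheticConfig(seed=42, years=(1988, 2013),
                      imr_trend="linear", imr_trend_coefs=(0.02,))
mort = simulate_mortality(cfg)
inc = simulate_incidence(cfg, mort)
pop = simulate_population(cfg)

report = run_back_validation(mort, inc, pop, targets=[2011, 2012, 2013], seed=0)
print(render_summary(report).to_string(index=False))
```

```
 sex                                 site  observed  expected  relative_deviation  mape best_scenario
male all sites (except non-melanoma skin)      8859      8436                -4.8  4.81             L
```

The registry was simulated with a log-IMR rising 2% per year, and the
validation correctly selects the linear scenario: `report.mape_table()`
shows MAPE 4.81 for L against 14.6/15.8/17.0 for C1/C3/C5 and 10.0 for Q.
The period deviation of −4.8% means the three validation years were
underestimated by 4.8% overall under the best scenario.

The same pipeline is available from the shell:

```bash
imrest simulate --seed 42 --out data/
imrest validate --mortality data/mortality.csv --incidence data/incidence.csv \
                --population data/population.csv --targets 2011:2013 --out results/
imrest estimate --mortality data/mortality.csv --incidence data/incidence.csv \
                --population data/population.csv --target-year 2013 --out est.csv
```

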