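"""Back-validation of the IMR estimation pipeline against observed incidence.

The validation design mimics real-world reporting lags: to estimate the
incidence of a target year T, only mortality up to T-3 and incidence up to
T-5 may be used.  A 20-year mortality window feeds the APC projection and a
15-year window feeds the IMR model; both are rolled backwards one target
year at a time, producing a series of (observed, expected) pairs per sex,
site and scenario.

Fit quality is scored by the signed relative deviation per year,

    100 * (Expected - Observed) / Observed,

and summarised over the validation period by the mean absolute percentage
error (MAPE); the scenario with the smallest MAPE is selected per stratum.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .apc import APCModel, MortalityProjection
from .imr import IMRModel
from .scenarios import SCENARIO_CODES, run_all_scenarios
from .surfaces import CountSurface, PopulationSurface, marginal_by_year

__all__ = [
    "LagDesign",
    "ValidationReport",
    "relative_deviation",
    "mape",
    "select_best_scenario",
    "build_windows",
    "estimate_for_target",
    "run_back_validation",
    "funnel_statistics",
]


def relative_deviation(observed: float, expected: float) -> float:
    """Signed percentage deviation of expected from observed cases.

    Negative values mean the observed cases exceeded the expectation
    (underestimation).
    """
    if observed <= 0:
        raise ValueError("relative deviation undefined for observed <= 0")
    return 100.0 * (expected - observed) / observed


def mape(observed_series: Mapping[int, float], expected_series: Mapping[int, float]) -> float:
    """Mean absolute percentage error over an inclusive year series.

    Years with zero observed cases are dropped with a warning (small-site
    safeguard); the year sets must otherwise match.
    """
    obs = dict(observed_series)
    exp = dict(expected_series)
    if set(obs) != set(exp):
        raise ValueError(
            f"year sets differ: {sorted(set(obs) ^ set(exp))} present in only one series"
        )
    if not obs:
        raise ValueError("empty series")
    years = sorted(obs)
    kept = [y for y in years if obs[y] > 0]
    if len(kept) < len(years):
        warnings.warn(
            f"dropping {len(years) - len(kept)} zero-observed year(s) from MAPE",
            stacklevel=2,
        )
        if not kept:
            raise ValueError("all observed values are zero")
    return float(np.mean([abs(relative_deviation(obs[y], exp[y])) for y in kept]))


def select_best_scenario(mapes: Mapping[str, float]) -> str:
    """Scenario with minimal MAPE; ties favour the simpler assumption
    (C1 < C3 < C5 < L < Q)."""
    if not mapes:
        raise ValueError("empty MAPE map")
    order = {code: i for i, code in enumerate(SCENARIO_CODES)}
    return min(mapes, key=lambda s: (mapes[s], order.get(s, len(order))))


# ---------------------------------------------------------------------------
# window construction


@dataclass(frozen=True)
class LagDesign:
    """Reporting lags and window lengths for the rolling validation.

    Defaults reproduce the realistic registry context: mortality available
    with a 3-year delay and modelled over a 20-year window, incidence with a
    5-year delay and an IMR window of 15 years.
    """

    mortality_lag: int = 3
    incidence_lag: int = 5
    mortality_window: int = 20
    imr_window: int = 15

    def __post_init__(self) -> None:
        if min(self.mortality_lag, self.incidence_lag, self.mortality_window, self.imr_window) <= 0:
            raise ValueError("lags and window lengths must be positive")
        if self.incidence_lag < self.mortality_lag:
            raise ValueError("incidence lag cannot be shorter than the mortality lag")


def build_windows(
    target_year: int,
    design: LagDesign = LagDesign(),
    first_mortality_year: int | None = None,
    first_incidence_year: int | None = None,
) -> dict[str, tuple[int, int]]:
    """Fitting windows and projection spans for one target year.

    mortality window = [T - lag_m - W_m + 1, T - lag_m], projected to T;
    IMR window = [T - lag_i - W_i + 1, T - lag_i], projected to T.
    """
    t = int(target_year)
    m_end = t - design.mortality_lag
    m_start = m_end - design.mortality_window + 1
    i_end = t - design.incidence_lag
    i_start = i_end - design.imr_window + 1
    if first_mortality_year is not None and m_start < first_mortality_year:
        raise ValueError(
            f"target {t} needs mortality back to {m_start}, "
            f"before first available year {first_mortality_year}"
        )
    if first_incidence_year is not None and i_start < first_incidence_year:
        raise ValueError(
            f"target {t} needs incidence back to {i_start}, "
            f"before first available year {first_incidence_year}"
        )
    return {
        "mortality_window": (m_start, m_end),
        "mortality_projection": (m_end + 1, t),
        "imr_window": (i_start, i_end),
        "imr_projection": (i_end + 1, t),
    }


# ---------------------------------------------------------------------------
# rolling estimation


def estimate_for_target(
    mortality: CountSurface,
    incidence: CountSurface,
    population: PopulationSurface,
    target_year: int,
    design: LagDesign = LagDesign(),
    scenarios: Sequence[str] = SCENARIO_CODES,
    method: str = "map",
    draws: int = 500,
    seed: int = 0,
    trend_window: int | None = None,
    apc_kwargs: dict | None = None,
) -> dict[str, "pd.Series"]:
    """Expected cases for one target year under each scenario, using only
    data available under the reporting lags (hard leakage guard: inputs are
    truncated at the lag boundaries before any fitting)."""
    w = build_windows(
        target_year, design,
        first_mortality_year=int(mortality.years[0]),
        first_incidence_year=int(incidence.years[0]),
    )
    mw, iw = w["mortality_window"], w["imr_window"]
    # leakage guard: nothing after the lag boundary can reach a model
    mort_avail = mortality.truncate_after(mw[1])
    inc_avail = incidence.truncate_after(iw[1])
    mort_for_imr = mortality.truncate_after(iw[1])

    apc = APCModel(mort_avail, population, window=mw, **(apc_kwargs or {})).fit()
    proj_years = list(range(w["mortality_projection"][0], w["mortality_projection"][1] + 1))
    deaths_proj = apc.project(population, proj_years)

    imr_fit = IMRModel(inc_avail, mort_for_imr, window=iw).fit(
        method=method, draws=draws, seed=seed
    )
    estimates = run_all_scenarios(imr_fit, deaths_proj, [target_year], trend_window=trend_window)
    out = {}
    for code in scenarios:
        est = estimates[code]
        lo, hi = est.interval
        out[code] = pd.Series(
            {"expected": float(est.median[0]), "lo": float(lo[0]), "hi": float(hi[0])}
        )
    return out


@dataclass
class ValidationReport:
    """Paired observed/expected series and derived scores.

    ``pairs`` columns: sex, site, scenario, year, observed, expected, lo, hi,
    deviation (signed yearly percentage).
    """

    pairs: pd.DataFrame
    design: LagDesign = field(default_factory=LagDesign)

    def mape_table(self) -> pd.DataFrame:
        rows = []
        for (sex, site, scen), grp in self.pairs.groupby(["sex", "site", "scenario"]):
            m = mape(
                dict(zip(grp["year"], grp["observed"])),
                dict(zip(grp["year"], grp["expected"])),
            )
            rows.append((sex, site, scen, m))
        return pd.DataFrame(rows, columns=["sex", "site", "scenario", "mape"])

    def best_scenarios(self) -> pd.DataFrame:
        mt = self.mape_table()
        rows = []
        for (sex, site), grp in mt.groupby(["sex", "site"]):
            mapes = dict(zip(grp["scenario"], grp["mape"]))
            best = select_best_scenario(mapes)
            rows.append((sex, site, best, mapes[best]))
        return pd.DataFrame(rows, columns=["sex", "site", "best_scenario", "mape"])

    def summary(self) -> pd.DataFrame:
        """Per sex and site at the best scenario: period totals, period
        deviation, MAPE and the selected scenario code."""
        best = self.best_scenarios().set_index(["sex", "site"])
        rows = []
        for (sex, site), grp in self.pairs.groupby(["sex", "site"]):
            code = best.loc[(sex, site), "best_scenario"]
            sel = grp[grp["scenario"] == code]
            obs, exp = float(sel["observed"].sum()), float(sel["expected"].sum())
            rows.append(
                (
                    sex, site, obs, exp,
                    relative_deviation(obs, exp),
                    float(best.loc[(sex, site), "mape"]),
                    code,
                )
            )
        return pd.DataFrame(
            rows,
            columns=[
                "sex", "site", "observed", "expected",
                "relative_deviation", "mape", "best_scenario",
            ],
        )

    def funnel(self) -> pd.DataFrame:
        return funnel_statistics(self)


def run_back_validation(
    mortality: Mapping[tuple[str, str], CountSurface] | CountSurface,
    incidence: Mapping[tuple[str, str], CountSurface] | CountSurface,
    population: Mapping[str, PopulationSurface] | PopulationSurface,
    targets: Sequence[int],
    design: LagDesign = LagDesign(),
    scenarios: Sequence[str] = SCENARIO_CODES,
    method: str = "map",
    draws: int = 500,
    seed: int = 0,
    trend_window: int | None = None,
    aggregate: bool = True,
    apc_kwargs: dict | None = None,
) -> ValidationReport:
    """Roll the full two-stage pipeline over ``targets`` and pair each
    estimate with the registry's observed cases.

    Each target year is refitted from scratch on its own lagged windows;
    the all-sites aggregate (sum of site-level expected cases) is appended
    when several sites share a sex.
    """
    if isinstance(mortality, CountSurface):
        mortality = {(mortality.sex, mortality.site): mortality}
    if isinstance(incidence, CountSurface):
        incidence = {(incidence.sex, incidence.site): incidence}
    if isinstance(population, PopulationSurface):
        population = {population.sex: population}
    if set(mortality) != set(incidence):
        raise ValueError("mortality and incidence strata differ")

    rows = []
    for target in sorted(int(t) for t in targets):
        for (sex, site), mort in sorted(mortality.items()):
            inc = incidence[(sex, site)]
            obs = float(marginal_by_year(inc).loc[target])
            est = estimate_for_target(
                mort, inc, population[sex], target, design=design,
                scenarios=scenarios, method=method, draws=draws,
                seed=seed + target, trend_window=trend_window,
                apc_kwargs=apc_kwargs,
            )
            for code, vals in est.items():
                rows.append(
                    (sex, site, code, target, obs,
                     vals["expected"], vals["lo"], vals["hi"])
                )
    pairs = pd.DataFrame(
        rows, columns=["sex", "site", "scenario", "year", "observed", "expected", "lo", "hi"]
    )
    if aggregate:
        agg_label = "all sites (except non-melanoma skin)"
        extra = []
        for (sex, scen, year), grp in pairs.groupby(["sex", "scenario", "year"]):
            if grp["site"].nunique() > 1:
                extra.append(
                    (sex, agg_label, scen, year,
                     grp["observed"].sum(), grp["expected"].sum(),
                     grp["lo"].sum(), grp["hi"].sum())
                )
        if extra:
            pairs = pd.concat([pairs, pd.DataFrame(extra, columns=pairs.columns)],
                              ignore_index=True)
    with np.errstate(divide="ignore"):
        pairs["deviation"] = 100.0 * (pairs["expected"] - pairs["observed"]) / pairs["observed"]
    return ValidationReport(pairs=pairs, design=design)


def funnel_statistics(report: ValidationReport) -> pd.DataFrame:
    """Per-site funnel coordinates at the best scenario.

    x = mean annual observed cases, y = period-total relative deviation;
    Poisson control limits +/- z * 100 / sqrt(total observed) at z = 1.96
    and 3.09.
    """
    summ = report.summary()
    n_years = report.pairs.groupby(["sex", "site"])["year"].nunique()
    rows = []
    for _, r in summ.iterrows():
        total = r["observed"]
        mean_annual = total / n_years.loc[(r["sex"], r["site"])]
        se = 100.0 / np.sqrt(total) if total > 0 else np.inf
        rows.append(
            (r["sex"], r["site"], mean_annual, r["relative_deviation"],
             1.96 * se, 3.09 * se)
        )
    return pd.DataFrame(
        rows,
        columns=["sex", "site", "mean_annual_observed", "period_deviation",
                 "limit_95", "limit_998"],
    )
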