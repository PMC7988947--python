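"""Five IMR-trend scenarios and conversion of projected deaths to expected cases.

Between the last fitted IMR year and the target year the ratio must be
extrapolated under an explicit assumption.  Five scenarios are supported,
applied per age group and per posterior draw:

  C1  IMR stays at the last available fitted value
  C3  the mean of the last three fitted values stays constant
  C5  the mean of the last five fitted values stays constant
  L   linear trend in log-IMR, fitted by OLS over the trend window
  Q   quadratic trend in log-IMR, likewise

Expected incident cases for a target year are then, draw by draw,
E = sum_age IMR(age, year) * projected_deaths(age, year), summarised by the
posterior median and a 95% interval.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .apc import MortalityProjection
from .imr import IMRResults, IMRSeries, IMR_FLOOR

__all__ = [
    "SCENARIO_CODES",
    "ScenarioSpec",
    "project_imr",
    "expected_cases",
    "run_all_scenarios",
    "EstimateResult",
]

#: fixed preference order; also the tie-break order in model selection
SCENARIO_CODES = ("C1", "C3", "C5", "L", "Q")

_CONSTANT_LOOKBACK = {"C1": 1, "C3": 3, "C5": 5}


@dataclass(frozen=True)
class ScenarioSpec:
    """One IMR-behaviour assumption.

    ``trend_window`` (L/Q only) is the number of trailing fitted years used
    to fit the trend; None means the whole fitted series.
    """

    code: str
    trend_window: int | None = None

    def __post_init__(self) -> None:
        if self.code not in SCENARIO_CODES:
            raise ValueError(f"unknown scenario {self.code!r}; choose from {SCENARIO_CODES}")

    @property
    def lookback(self) -> int:
        if self.code in _CONSTANT_LOOKBACK:
            return _CONSTANT_LOOKBACK[self.code]
        return self.trend_window or 2


def project_imr(
    series: IMRSeries, spec: ScenarioSpec | str, target_years
) -> IMRSeries:
    """Extrapolate a fitted IMR series to ``target_years`` under one scenario.

    Applied independently per age group and per posterior draw; L/Q fit OLS
    on log-IMR (positivity-preserving) and floor the result at a small
    positive epsilon.
    """
    if isinstance(spec, str):
        spec = ScenarioSpec(spec)
    target_years = np.asarray(sorted(int(y) for y in np.atleast_1d(target_years)))
    n_avail = series.years.size
    if n_avail < spec.lookback:
        raise ValueError(
            f"scenario {spec.code} needs {spec.lookback} fitted years, "
            f"series has {n_avail}"
        )
    draws = series.draws  # (S, A, Y)
    if spec.code in _CONSTANT_LOOKBACK:
        k = _CONSTANT_LOOKBACK[spec.code]
        level = draws[:, :, -k:].mean(axis=2)  # (S, A)
        out = np.repeat(level[:, :, None], target_years.size, axis=2)
    else:
        window = spec.trend_window or n_avail
        window = min(window, n_avail)
        deg = 1 if spec.code == "L" else 2
        if window < deg + 1:
            raise ValueError(f"scenario {spec.code} needs at least {deg + 1} fitted years")
        t_fit = series.years[-window:].astype(float)
        t0 = t_fit.mean()
        log_imr = np.log(draws[:, :, -window:])  # (S, A, W)
        S, A, W = log_imr.shape
        V = np.vander(t_fit - t0, deg + 1, increasing=True)  # (W, deg+1)
        coef, *_ = np.linalg.lstsq(V, log_imr.reshape(S * A, W).T, rcond=None)
        Vt = np.vander(target_years.astype(float) - t0, deg + 1, increasing=True)
        pred = (Vt @ coef).T.reshape(S, A, target_years.size)
        out = np.exp(pred)
    return IMRSeries(ages=series.ages, years=target_years, draws=np.maximum(out, IMR_FLOOR))


@dataclass(frozen=True)
class EstimateResult:
    """Expected incident cases per target year under one scenario."""

    sex: str
    site: str
    scenario: str
    years: np.ndarray
    draws: np.ndarray  # (n_draws, n_years) total expected cases
    projected_deaths: np.ndarray  # (n_age, n_years), audit trail
    projected_imr_median: np.ndarray  # (n_age, n_years)

    @property
    def median(self) -> np.ndarray:
        return np.median(self.draws, axis=0)

    @property
    def interval(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.percentile(self.draws, 2.5, axis=0),
            np.percentile(self.draws, 97.5, axis=0),
        )

    def to_frame(self) -> pd.DataFrame:
        lo, hi = self.interval
        return pd.DataFrame(
            {
                "sex": self.sex,
                "site": self.site,
                "year": self.years,
                "scenario": self.scenario,
                "expected": self.median,
                "lo": lo,
                "hi": hi,
            }
        )


def expected_cases(
    imr_target: IMRSeries, deaths_target: MortalityProjection, scenario: str = ""
) -> EstimateResult:
    """Combine projected IMR draws with projected deaths into expected cases."""
    if imr_target.ages != deaths_target.ages:
        raise ValueError("IMR and death projection age grids differ")
    if not np.all(np.isin(imr_target.years, deaths_target.years)):
        raise ValueError("death projection does not cover all IMR target years")
    cols = [deaths_target.year_index(int(y)) for y in imr_target.years]
    deaths = deaths_target.expected[:, cols]  # (A, Y)
    totals = np.einsum("say,ay->sy", imr_target.draws, deaths)
    return EstimateResult(
        sex=deaths_target.sex, site=deaths_target.site, scenario=scenario,
        years=imr_target.years.copy(), draws=totals,
        projected_deaths=deaths, projected_imr_median=imr_target.median,
    )


def run_all_scenarios(
    fit: IMRResults,
    deaths: MortalityProjection,
    target_years,
    trend_window: int | None = None,
) -> dict[str, EstimateResult]:
    """Project the fitted IMR under all five scenarios and convert to cases."""
    series = fit.imr_series()
    out = {}
    for code in SCENARIO_CODES:
        spec = ScenarioSpec(code, trend_window=trend_window)
        imr_t = project_imr(series, spec, target_years)
        out[code] = expected_cases(imr_t, deaths, scenario=code)
    return out
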