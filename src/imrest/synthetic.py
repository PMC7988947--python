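"""Synthetic registry generator with the statistical structure the method assumes.

Emits mortality, incidence and population surfaces for a mid-size province
(defaults sized like a southern-Spanish registry: ~460,000 person-years per
sex, ~1,100 all-sites cancer deaths and ~2,200 incident cases per year in
men) so that every pipeline stage can be exercised and parameter recovery
verified without any external data.

Generative model, mirroring the two estimation stages:

  deaths_{a,y} ~ Poisson( N_{a,y} * rate(a, y) ),
      rate^(1/5) = A_a + D*(y - ref) + P_y + C_band(y - mid_a)
  cases_{a,y}  ~ Poisson( deaths_{a,y} * IMR(a, y) ),
      log IMR(a, y) = log base_a + b1*(y - ref) + b2*(y - ref)^2

The IMR year trend (constant / linear / quadratic) acts on the log scale,
coherent with the stage-2 log-linear Poisson model and the L/Q scenarios.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .apc import EPS
from .surfaces import AgeGrid, CountSurface, PopulationSurface

__all__ = [
    "SyntheticConfig",
    "expected_mortality",
    "expected_imr",
    "simulate_mortality",
    "simulate_incidence",
    "simulate_population",
    "make_validation_fixture",
]

# plausible mid-1990s provincial pyramid: fraction of one sex's population per
# 5-year band (0-4 ... 85+), summing to 1
_PYRAMID = np.array(
    [0.055, 0.058, 0.062, 0.068, 0.072, 0.075, 0.075, 0.072, 0.068,
     0.063, 0.058, 0.052, 0.047, 0.042, 0.036, 0.028, 0.018, 0.011]
)
_PYRAMID = _PYRAMID / _PYRAMID.sum()

# all-sites cancer mortality, deaths per 100,000 person-years by age band:
# near-zero in childhood, steep rise after 40
_RATE_PER_100K = np.array(
    [4.0, 3.0, 3.5, 5.0, 8.0, 12.0, 20.0, 35.0, 62.0, 110.0, 190.0,
     320.0, 500.0, 750.0, 1050.0, 1400.0, 1750.0, 2100.0]
)

# base IMR by age: high where survival is good (young adults), approaching
# ~1.3 at the oldest ages where incidence and mortality nearly coincide
_IMR_BASE = np.array(
    [3.5, 3.5, 3.4, 3.3, 3.2, 3.0, 2.8, 2.6, 2.4, 2.2, 2.0, 1.9,
     1.8, 1.7, 1.6, 1.5, 1.4, 1.3]
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic registry.

    ``drift`` is the yearly linear trend on the fifth-root-rate scale;
    ``imr_trend_coefs`` are (b1,) or (b1, b2) acting on log IMR per year
    relative to ``ref_year`` (the midpoint of the series by default).
    """

    seed: int = 0
    years: tuple[int, int] = (1982, 2013)
    ages: AgeGrid = field(default_factory=AgeGrid)
    sex: str = "male"
    site: str = "all sites (except non-melanoma skin)"
    population_size: float = 460_000.0
    population_profile: np.ndarray | None = None  # person-years per age band
    population_growth: float = 0.005  # yearly multiplicative growth
    age_rates_per_100k: np.ndarray | None = None  # drives A_a
    drift: float = 0.0005
    period_effects: Mapping[int, float] = field(default_factory=dict)
    cohort_effects: Mapping[int, float] = field(default_factory=dict)
    imr_base: np.ndarray | float | None = None
    imr_trend: str = "constant"  # constant | linear | quadratic
    imr_trend_coefs: tuple[float, ...] = ()
    ref_year: int | None = None

    def __post_init__(self) -> None:
        if self.years[1] < self.years[0]:
            raise ValueError("empty year range")
        if self.imr_trend not in ("constant", "linear", "quadratic"):
            raise ValueError(f"unknown imr_trend {self.imr_trend!r}")
        need = {"constant": 0, "linear": 1, "quadratic": 2}[self.imr_trend]
        if len(self.imr_trend_coefs) != need:
            raise ValueError(
                f"imr_trend={self.imr_trend!r} needs {need} coefficient(s), "
                f"got {self.imr_trend_coefs}"
            )
        if not all(np.isfinite(self.imr_trend_coefs)):
            raise ValueError("trend coefficients must be finite")
        if np.any(self._imr_base_vec() <= 0):
            raise ValueError("IMR base values must be positive")

    # -- resolved defaults ------------------------------------------------
    @property
    def year_array(self) -> np.ndarray:
        return np.arange(self.years[0], self.years[1] + 1)

    @property
    def reference_year(self) -> float:
        return float(self.ref_year) if self.ref_year is not None else float(self.year_array.mean())

    def _profile(self) -> np.ndarray:
        if self.population_profile is not None:
            return np.asarray(self.population_profile, dtype=float)
        if self.ages.n == _PYRAMID.size:
            return self.population_size * _PYRAMID
        return np.full(self.ages.n, self.population_size / self.ages.n)

    def _age_curve(self) -> np.ndarray:
        rates = self.age_rates_per_100k
        if rates is None:
            if self.ages.n == _RATE_PER_100K.size:
                rates = _RATE_PER_100K
            else:
                rates = np.full(self.ages.n, 100.0)
        rates = np.asarray(rates, dtype=float) / 1e5
        if np.any(rates <= 0):
            raise ValueError("age rates must be positive")
        return rates ** 0.2

    def _imr_base_vec(self) -> np.ndarray:
        base = self.imr_base
        if base is None:
            base = _IMR_BASE if self.ages.n == _IMR_BASE.size else 2.0
        return np.broadcast_to(np.asarray(base, dtype=float), (self.ages.n,)).copy()


# ---------------------------------------------------------------------------
# noiseless means


def expected_mortality(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """(person_years, Poisson death means), each (n_age, n_years)."""
    years = config.year_array
    A = config._age_curve()
    mids = config.ages.midpoints
    py = config._profile()[:, None] * (1.0 + config.population_growth) ** (
        years[None, :] - years[0]
    )
    eta = A[:, None] + config.drift * (years[None, :] - config.reference_year)
    if config.period_effects:
        eta = eta + np.array([config.period_effects.get(int(y), 0.0) for y in years])[None, :]
    if config.cohort_effects:
        band = (np.floor((years[None, :] - mids[:, None]) / 5.0) * 5).astype(int)
        eta = eta + np.vectorize(lambda b: config.cohort_effects.get(int(b), 0.0))(band)
    lam = py * np.maximum(eta, EPS) ** 5
    return py, lam


def expected_imr(config: SyntheticConfig) -> np.ndarray:
    """True IMR(a, y) surface, shape (n_age, n_years)."""
    years = config.year_array
    t = years - config.reference_year
    log_imr = np.log(config._imr_base_vec())[:, None] + np.zeros((1, years.size))
    if config.imr_trend == "linear":
        log_imr = log_imr + config.imr_trend_coefs[0] * t[None, :]
    elif config.imr_trend == "quadratic":
        b1, b2 = config.imr_trend_coefs
        log_imr = log_imr + b1 * t[None, :] + b2 * t[None, :] ** 2
    return np.exp(log_imr)


# ---------------------------------------------------------------------------
# samplers


def simulate_population(config: SyntheticConfig) -> PopulationSurface:
    py, _ = expected_mortality(config)
    return PopulationSurface(
        sex=config.sex, years=config.year_array, person_years=py, ages=config.ages
    )


def simulate_mortality(config: SyntheticConfig) -> CountSurface:
    """Poisson mortality surface; reproducible under a fixed seed."""
    _, lam = expected_mortality(config)
    rng = np.random.default_rng(config.seed)
    counts = rng.poisson(lam)
    return CountSurface(
        kind="mortality", sex=config.sex, site=config.site,
        years=config.year_array, counts=counts, ages=config.ages,
    )


def simulate_incidence(config: SyntheticConfig, deaths: CountSurface) -> CountSurface:
    """Poisson incident cases given a realised deaths surface.

    cases ~ Poisson(deaths * IMR); zero-death cells therefore produce zero
    expected (and realised) cases.
    """
    if deaths.counts.shape != (config.ages.n, config.year_array.size):
        raise ValueError("deaths surface does not match the config grid")
    imr = expected_imr(config)
    rng = np.random.default_rng(config.seed + 1)  # decoupled stream from mortality
    counts = rng.poisson(deaths.counts * imr)
    return CountSurface(
        kind="incidence", sex=config.sex, site=config.site,
        years=deaths.years.copy(), counts=counts, ages=config.ages,
    )


def make_validation_fixture(
    config: SyntheticConfig, holdout_years: Sequence[int] | None = None
) -> dict:
    """Complete multi-decade fixture plus ground truth for held-out years.

    The truth series is the configured (noiseless) expected incidence,
    sum_a N * rate * IMR, so parameter-recovery tests compare against the
    generative means rather than one Poisson realisation.
    """
    years = config.year_array
    if holdout_years is None:
        holdout_years = years[-5:]
    holdout_years = [int(y) for y in holdout_years]
    if any(y < years[0] or y > years[-1] for y in holdout_years):
        raise ValueError("holdout years outside the configured range")
    mortality = simulate_mortality(config)
    incidence = simulate_incidence(config, mortality)
    population = simulate_population(config)
    _, lam = expected_mortality(config)
    truth_cells = lam * expected_imr(config)
    truth = pd.Series(
        truth_cells.sum(axis=0), index=pd.Index(years, name="year"), name="expected_cases"
    ).loc[holdout_years]
    return {
        "mortality": mortality,
        "incidence": incidence,
        "population": population,
        "truth": truth,
        "config": config,
    }
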