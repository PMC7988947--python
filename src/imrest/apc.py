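"""Age-period-cohort mortality model with the NORDPRED power-5 link.

Stage 1 of the incidence-estimation pipeline: fit

    deaths_{a,p} ~ Poisson( N_{a,p} * (A_a + D*p + P_p + C_c)^5 )

to an observed mortality surface and project expected deaths beyond the
fitting window.  The fifth root of the rate is linear in an age component
A_a, a common drift D shared by the period and cohort axes, and nonlinear
period (P_p) and cohort (C_c) components.  P and C are constrained to zero
sum and zero linear slope on their respective axes, which makes D the unique
linear trend ("drift") and the decomposition identifiable.

Periods are single calendar years (the method is applied to annual series);
cohorts are year-minus-age-midpoint diagonals grouped into 5-year bands to
limit the parameter count.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.linalg import null_space

from .surfaces import AgeGrid, CountSurface, PopulationSurface

__all__ = [
    "APCModel",
    "APCResults",
    "MortalityProjection",
    "fit_apc",
    "project_deaths",
    "attenuate_drift",
    "NORDPRED_DRIFT_SCHEDULE",
]

#: fifth-root-scale floor: rates are never allowed below EPS^5
EPS = 1e-6

#: drift attenuation fractions for successive future 5-year blocks
#: ("cut trend": full drift in years 1-5 after the window, then 75%, 50%, 25%)
NORDPRED_DRIFT_SCHEDULE = (1.0, 0.75, 0.5, 0.25)


def _constraint_basis(positions: np.ndarray) -> np.ndarray:
    """Basis Z (n x n-2) of level effects with zero sum and zero linear slope.

    Any v = Z @ gamma satisfies sum(v) = 0 and sum(positions * v) = 0, so the
    linear trend along the axis is absorbed entirely by the drift term.
    """
    n = positions.size
    A = np.vstack([np.ones(n), positions.astype(float)])
    Z = null_space(A)
    if Z.shape != (n, n - 2):
        raise ValueError("degenerate constraint basis")
    return Z


@dataclass(frozen=True)
class MortalityProjection:
    """Expected deaths per (age group, year) for projection years."""

    sex: str
    site: str
    years: np.ndarray
    expected: np.ndarray  # (n_age, n_years)
    ages: AgeGrid
    fit_window: tuple[int, int]

    def __post_init__(self) -> None:
        if np.any(self.expected < 0):
            raise ValueError("negative expected deaths")
        if int(self.years[0]) <= self.fit_window[1]:
            raise ValueError("projection years must lie strictly after the fit window")

    def totals_by_year(self) -> np.ndarray:
        return self.expected.sum(axis=0)

    def year_index(self, year: int) -> int:
        idx = int(year) - int(self.years[0])
        if idx < 0 or idx >= self.years.size:
            raise KeyError(f"year {year} not in projection horizon")
        return idx


@dataclass(frozen=True)
class APCResults:
    """Fitted components of the power-5 APC decomposition.

    ``age_effects`` holds A_a on the fifth-root-rate scale; ``drift`` is the
    per-year linear trend D; ``period_effects``/``cohort_effects`` are the
    constrained nonlinear components keyed by year and cohort-band start.
    """

    sex: str
    site: str
    ages: AgeGrid
    fit_window: tuple[int, int]
    age_effects: np.ndarray
    drift: float
    period_effects: dict[int, float]
    cohort_effects: dict[int, float]
    period_ref: float  # period axis centre used for D*p
    constraints: dict = field(default_factory=dict)
    drift_schedule: tuple[float, ...] | None = None
    deviance: float = float("nan")
    method: str = "apc-power5"
    mean_rates: np.ndarray | None = None  # fallback estimator payload

    # -- linear predictor -------------------------------------------------
    def _cohort_component(self, year: int, age_index: int) -> float:
        mids = self.ages.midpoints
        band = int(np.floor((year - mids[age_index]) / 5.0) * 5)
        if band in self.cohort_effects:
            return self.cohort_effects[band]
        # unobserved cohorts inherit the nearest observed band's component
        observed = np.array(sorted(self.cohort_effects))
        return self.cohort_effects[int(observed[np.argmin(np.abs(observed - band))])]

    def _drift_contribution(self, year: int) -> float:
        """D*p with optional attenuation of post-window yearly increments."""
        last = self.fit_window[1]
        if year <= last or self.drift_schedule is None:
            return self.drift * (year - self.period_ref)
        sched = self.drift_schedule
        base = self.drift * (last - self.period_ref)
        extra = sum(
            self.drift * sched[min((k - 1) // 5, len(sched) - 1)]
            for k in range(1, year - last + 1)
        )
        return base + extra

    def fifth_root_rate(self, year: int, age_index: int) -> float:
        eta = (
            self.age_effects[age_index]
            + self._drift_contribution(year)
            + self.period_effects.get(year, 0.0)  # P_p* = 0 beyond the window
            + self._cohort_component(year, age_index)
        )
        return max(eta, EPS)

    def rates(self, years: Sequence[int]) -> np.ndarray:
        out = np.empty((self.ages.n, len(years)))
        for j, y in enumerate(years):
            for a in range(self.ages.n):
                out[a, j] = self.fifth_root_rate(int(y), a) ** 5
        return out

    def fitted_deaths(self, population: PopulationSurface) -> np.ndarray:
        years = range(self.fit_window[0], self.fit_window[1] + 1)
        pop = population.window(*self.fit_window).person_years
        return pop * self.rates(list(years))

    # -- projection -------------------------------------------------------
    def project(
        self, population: PopulationSurface, horizon: Sequence[int]
    ) -> MortalityProjection:
        """Expected deaths for the years in ``horizon`` (strictly after the
        fit window), using the observed or user-projected person-years."""
        horizon = np.asarray(sorted(int(y) for y in horizon))
        if horizon[0] <= self.fit_window[1]:
            raise ValueError(
                f"projection horizon {horizon[0]}-{horizon[-1]} overlaps "
                f"fit window ending {self.fit_window[1]}"
            )
        pop = np.column_stack([
            population.person_years[:, population.year_index(y)] for y in horizon
        ])
        if self.method == "age-specific-mean":
            expected = pop * self.mean_rates[:, None]
        else:
            expected = pop * self.rates(horizon.tolist())
        return MortalityProjection(
            sex=self.sex, site=self.site, years=horizon, expected=expected,
            ages=self.ages, fit_window=self.fit_window,
        )

    def summary(self) -> str:
        lines = [
            f"APC mortality fit ({self.method}): sex={self.sex} site={self.site}",
            f"  window: {self.fit_window[0]}-{self.fit_window[1]}",
            f"  drift D (fifth-root scale / year): {self.drift:+.6f}",
            f"  deviance: {self.deviance:.2f}",
            f"  constraints: {self.constraints}",
            "  age effects (A_a):",
        ]
        for lab, a in zip(self.ages.labels, self.age_effects):
            lines.append(f"    {lab:>6s}  {a:+.5f}")
        return "\n".join(lines)


class APCModel:
    """Poisson APC model of a mortality surface with the power-5 link.

    Parameters
    ----------
    mortality, population
        Dense surfaces on the same age grid.
    window
        Inclusive (first, last) fitting years; defaults to the full overlap.
    cohort_band
        Width in years of the cohort grouping (default 5).
    min_mean_deaths
        Strata averaging fewer deaths per year than this over the window are
        too sparse for the full decomposition; the fit falls back to the
        age-specific mean rates of the window's last five years.
    """

    def __init__(
        self,
        mortality: CountSurface,
        population: PopulationSurface,
        window: tuple[int, int] | None = None,
        cohort_band: int = 5,
        min_mean_deaths: float = 5.0,
    ) -> None:
        if mortality.ages != population.ages:
            raise ValueError("mortality and population grids differ")
        first = max(int(mortality.years[0]), int(population.years[0]))
        last = min(int(mortality.years[-1]), int(population.years[-1]))
        if window is not None:
            first, last = int(window[0]), int(window[1])
        self.window = (first, last)
        self.mortality = mortality.window(first, last)
        self.population = population.window(first, last)
        self.cohort_band = int(cohort_band)
        self.min_mean_deaths = float(min_mean_deaths)
        if self.mortality.years.size < 3:
            raise ValueError("APC fit needs at least 3 periods")

    # -- design -----------------------------------------------------------
    def _design(self):
        ages = self.mortality.ages
        years = self.mortality.years
        mids = ages.midpoints
        n_age, n_year = ages.n, years.size
        period_ref = float(years.mean())
        p_centered = years - period_ref

        cohort_vals = np.floor(
            (years[None, :] - mids[:, None]) / self.cohort_band
        ).astype(int) * self.cohort_band
        bands, counts = np.unique(cohort_vals, return_counts=True)
        # merge cohort diagonals observed in <2 cells into their neighbour
        band_map = {}
        kept = [b for b, c in zip(bands, counts) if c >= 2]
        if len(kept) < 3:
            raise ValueError("fewer than 3 usable cohort bands; widen the window")
        kept_arr = np.array(kept)
        for b in bands:
            band_map[int(b)] = int(kept_arr[np.argmin(np.abs(kept_arr - b))])

        cohort_levels = sorted(set(band_map.values()))
        c_index = {b: i for i, b in enumerate(cohort_levels)}

        Zp = _constraint_basis(p_centered)
        Zc = _constraint_basis(np.array(cohort_levels, dtype=float))

        rows = n_age * n_year
        X_age = np.zeros((rows, n_age))
        X_drift = np.zeros((rows, 1))
        X_per = np.zeros((rows, Zp.shape[1]))
        X_coh = np.zeros((rows, Zc.shape[1]))
        y = np.empty(rows)
        N = np.empty(rows)
        r = 0
        for a in range(n_age):
            for j in range(n_year):
                X_age[r, a] = 1.0
                X_drift[r, 0] = p_centered[j]
                X_per[r] = Zp[j]
                X_coh[r] = Zc[c_index[band_map[int(cohort_vals[a, j])]]]
                y[r] = self.mortality.counts[a, j]
                N[r] = self.population.person_years[a, j]
                r += 1
        X = np.hstack([X_age, X_drift, X_per, X_coh])
        meta = dict(
            n_age=n_age, years=years, period_ref=period_ref,
            Zp=Zp, Zc=Zc, cohort_levels=cohort_levels,
        )
        return X, y, N, meta

    @staticmethod
    def _deviance(y: np.ndarray, mu: np.ndarray) -> float:
        mu = np.maximum(mu, 1e-300)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / mu), 0.0)
        return float(2.0 * np.sum(term - (y - mu)))

    def _irls(self, X, y, N, max_iter=200, tol=1e-10):
        """Fisher scoring for Poisson with mu = N * eta^5, eta = X @ beta.

        Working response z = eta + (y - mu)/(5 N eta^4), weights w = 25 N eta^3,
        with eta floored at EPS and step-halving on deviance increase.
        """
        eta0 = np.maximum(((y + 0.5) / N) ** 0.2, EPS)
        beta, *_ = np.linalg.lstsq(X, eta0, rcond=None)
        eta = np.maximum(X @ beta, EPS)
        dev = self._deviance(y, N * eta**5)
        for _ in range(max_iter):
            mu = N * eta**5
            z = eta + (y - mu) / (5.0 * N * eta**4)
            w = 25.0 * N * eta**3
            sw = np.sqrt(w)
            beta_new, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
            step = 1.0
            for _ in range(30):
                trial = beta + step * (beta_new - beta)
                eta_t = np.maximum(X @ trial, EPS)
                dev_t = self._deviance(y, N * eta_t**5)
                if dev_t <= dev + 1e-12:
                    break
                step /= 2.0
            else:
                break
            improved = dev - dev_t
            beta, eta, dev = trial, eta_t, dev_t
            if improved < tol * (abs(dev) + 1.0):
                break
        return beta, dev

    # -- fitting ----------------------------------------------------------
    def fit(self) -> APCResults:
        mean_deaths = self.mortality.total / self.mortality.years.size
        if mean_deaths < self.min_mean_deaths:
            return self._fit_fallback()
        X, y, N, meta = self._design()
        beta, dev = self._irls(X, y, N)
        n_age = meta["n_age"]
        years = meta["years"]
        Zp, Zc = meta["Zp"], meta["Zc"]
        k = n_age
        age_effects = beta[:k]
        drift = float(beta[k])
        gamma_p = beta[k + 1 : k + 1 + Zp.shape[1]]
        gamma_c = beta[k + 1 + Zp.shape[1] :]
        P = Zp @ gamma_p
        C = Zc @ gamma_c
        constraints = {
            "period_sum": float(P.sum()),
            "period_slope": float((years - meta["period_ref"]) @ P),
            "cohort_sum": float(C.sum()),
            "cohort_slope": float(np.array(meta["cohort_levels"], dtype=float) @ C),
        }
        return APCResults(
            sex=self.mortality.sex, site=self.mortality.site, ages=self.mortality.ages,
            fit_window=self.window, age_effects=age_effects, drift=drift,
            period_effects={int(y_): float(v) for y_, v in zip(years, P)},
            cohort_effects={int(b): float(v) for b, v in zip(meta["cohort_levels"], C)},
            period_ref=meta["period_ref"], constraints=constraints, deviance=dev,
        )

    def _fit_fallback(self) -> APCResults:
        """Sparse-stratum fallback: age-specific mean rates of the last 5 years."""
        last5_first = max(self.window[0], self.window[1] - 4)
        d = self.mortality.window(last5_first, self.window[1]).counts
        n = self.population.window(last5_first, self.window[1]).person_years
        rates = d.sum(axis=1) / n.sum(axis=1)
        return APCResults(
            sex=self.mortality.sex, site=self.mortality.site, ages=self.mortality.ages,
            fit_window=self.window, age_effects=np.maximum(rates, 0.0) ** 0.2,
            drift=0.0, period_effects={}, cohort_effects={0: 0.0},
            period_ref=float(self.mortality.years.mean()),
            constraints={"fallback": True}, method="age-specific-mean",
            mean_rates=rates,
        )


# ---------------------------------------------------------------------------
# functional wrappers


def fit_apc(
    mortality: CountSurface,
    population: PopulationSurface,
    window: tuple[int, int] | None = None,
    **kwargs,
) -> APCResults:
    return APCModel(mortality, population, window=window, **kwargs).fit()


def project_deaths(
    fit: APCResults, population: PopulationSurface, horizon: Sequence[int]
) -> MortalityProjection:
    return fit.project(population, horizon)


def attenuate_drift(
    fit: APCResults, schedule: Sequence[float] = NORDPRED_DRIFT_SCHEDULE
) -> APCResults:
    """Return a copy whose post-window drift increments are damped by
    ``schedule`` (one fraction per future 5-year block)."""
    schedule = tuple(float(s) for s in schedule)
    if any(s < 0 or s > 1 for s in schedule):
        raise ValueError("attenuation fractions must lie in [0, 1]")
    return replace(fit, drift_schedule=schedule)
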