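"""Stage-2 model: Bayesian Poisson regression for the incidence-to-mortality ratio.

Incident cases in each (age group, year) cell are modelled as

    cases_{a,t} ~ Poisson( deaths_{a,t} * IMR(a, t) )
    log IMR(a, t) = b0 + b1*t + b2*t^2 + s(age)

with the observed deaths as offset, a second-degree polynomial in the year
of diagnosis, and a linear spline in age with four knots placed at the 10th
percentile, first tertile, second tertile and 90th percentile of the
death-weighted age distribution pooled over the fitting window ("mortality
pool").  Priors are weakly informative Normal(0, 10^2) on all coefficients.

Two fitting paths share this posterior: a deterministic penalized-IRLS MAP
estimate with a Laplace (Gaussian) approximation for draws, and an ensemble
MCMC sampler (emcee) with split-Rhat / effective-sample-size diagnostics.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .surfaces import AgeGrid, CountSurface

__all__ = [
    "SplineBasis",
    "IMRModel",
    "IMRResults",
    "IMRSeries",
    "compute_knots",
    "fit_imr",
    "imr_series",
]

PRIOR_SD = 10.0
IMR_FLOOR = 1e-6


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Smallest value whose weighted CDF reaches q (discrete distribution)."""
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cdf = np.cumsum(w) / w.sum()
    return float(v[np.searchsorted(cdf, q - 1e-12)])


@dataclass(frozen=True)
class SplineBasis:
    """Linear spline in age: columns [age, hinge(age - k) for each knot]."""

    knots: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        k = self.knots
        if len(k) != 4 or any(b <= a for a, b in zip(k, k[1:])):
            raise ValueError(f"knots must be 4 strictly increasing values, got {k}")

    def design(self, age: np.ndarray) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        cols = [age] + [np.maximum(0.0, age - k) for k in self.knots]
        return np.column_stack(cols)

    @property
    def n_terms(self) -> int:
        return 1 + len(self.knots)


def compute_knots(mortality: CountSurface, window: tuple[int, int] | None = None) -> SplineBasis:
    """Knots from the death-weighted age distribution pooled over the window.

    Ages enter at band midpoints; the quantile levels are 10%, 33.3%, 66.7%
    and 90%.  Errors when deaths are so concentrated that fewer than four
    distinct quantiles result (coarsen the grid or widen the window).
    """
    surf = mortality if window is None else mortality.window(*window)
    weights = surf.counts.sum(axis=1).astype(float)
    if weights.sum() <= 0:
        raise ValueError("no deaths in window: cannot place spline knots")
    mids = surf.ages.midpoints
    qs = (0.10, 1.0 / 3.0, 2.0 / 3.0, 0.90)
    knots = tuple(_weighted_quantile(mids, weights, q) for q in qs)
    if len(set(knots)) < 4:
        raise ValueError(
            f"degenerate knot set {knots}: deaths too concentrated in age; "
            "coarsen age bands or widen the window"
        )
    return SplineBasis(knots=knots)


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IMRSeries:
    """Posterior IMR per (age group, year): draws plus median and 95% interval."""

    ages: AgeGrid
    years: np.ndarray
    draws: np.ndarray  # (n_draws, n_age, n_years), IMR scale (> 0)

    def __post_init__(self) -> None:
        if self.draws.ndim != 3 or self.draws.shape[1:] != (self.ages.n, self.years.size):
            raise ValueError("draws must have shape (n_draws, n_age, n_years)")
        if np.any(self.draws <= 0):
            raise ValueError("IMR draws must be strictly positive")

    @property
    def median(self) -> np.ndarray:
        return np.median(self.draws, axis=0)

    @property
    def interval(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.percentile(self.draws, 2.5, axis=0),
            np.percentile(self.draws, 97.5, axis=0),
        )

    def pooled_by_year(self, death_weights: np.ndarray | None = None) -> np.ndarray:
        """Death-weighted (or unweighted) posterior-median IMR per year."""
        med = self.median
        if death_weights is None:
            return med.mean(axis=0)
        w = death_weights / death_weights.sum(axis=0, keepdims=True)
        return (med * w).sum(axis=0)


@dataclass(frozen=True)
class IMRResults:
    """Posterior draws for the IMR model coefficients.

    Coefficient order: intercept, year, year^2, age, hinge_1..hinge_4
    (plus one random intercept per age group when enabled).
    """

    sex: str
    site: str
    ages: AgeGrid
    fit_window: tuple[int, int]
    knots: SplineBasis
    draws: np.ndarray  # (n_draws, n_params)
    param_names: tuple[str, ...]
    year_ref: float
    map_estimate: np.ndarray
    diagnostics: dict = field(default_factory=dict)
    method: str = "map"
    random_intercept: bool = False

    def __post_init__(self) -> None:
        if self.draws.size == 0:
            raise ValueError("empty posterior draw array")

    @property
    def converged(self) -> bool:
        rhat = self.diagnostics.get("rhat")
        return rhat is None or bool(np.all(np.asarray(rhat) <= 1.05))

    def _design(self, years: Sequence[int]) -> np.ndarray:
        years = np.asarray([int(y) for y in years])
        t = years - self.year_ref
        mids = self.ages.midpoints
        rows = []
        for a in range(self.ages.n):
            for tt in t:
                row = [1.0, tt, tt * tt, *self.knots.design(np.array([mids[a]]))[0]]
                if self.random_intercept:
                    re = np.zeros(self.ages.n)
                    re[a] = 1.0
                    row.extend(re)
                rows.append(row)
        return np.asarray(rows)

    def linear_predictor(self, years: Sequence[int]) -> np.ndarray:
        """Per-draw log-IMR, shape (n_draws, n_age, n_years)."""
        X = self._design(years)
        eta = self.draws @ X.T
        return eta.reshape(self.draws.shape[0], self.ages.n, len(list(years)))

    def imr_series(self, years: Sequence[int] | None = None) -> IMRSeries:
        """Fitted/projected IMR per cell; defaults to the fit window years."""
        if years is None:
            years = list(range(self.fit_window[0], self.fit_window[1] + 1))
        years = [int(y) for y in years]
        if min(years) < self.fit_window[0]:
            raise ValueError("years precede the fit window")
        imr = np.exp(self.linear_predictor(years))
        return IMRSeries(ages=self.ages, years=np.asarray(years), draws=np.maximum(imr, IMR_FLOOR))

    def summary(self) -> str:
        med = np.median(self.draws, axis=0)
        lo = np.percentile(self.draws, 2.5, axis=0)
        hi = np.percentile(self.draws, 97.5, axis=0)
        rhat = self.diagnostics.get("rhat", [float("nan")] * len(self.param_names))
        lines = [
            f"IMR Poisson model ({self.method}): sex={self.sex} site={self.site}",
            f"  window: {self.fit_window[0]}-{self.fit_window[1]}  "
            f"knots: {tuple(round(k, 2) for k in self.knots.knots)}",
            f"  {'param':>12s} {'median':>10s} {'2.5%':>10s} {'97.5%':>10s} {'Rhat':>7s}",
        ]
        for name, m, l, h, r in zip(self.param_names, med, lo, hi, rhat):
            lines.append(f"  {name:>12s} {m:10.4f} {l:10.4f} {h:10.4f} {r:7.3f}")
        if not self.converged:
            lines.append("  WARNING: split-Rhat > 1.05 for some parameters (unconverged)")
        return "\n".join(lines)


class IMRModel:
    """Poisson IMR regression of incident cases on age and year with deaths offset.

    Cells with zero deaths are excluded from the likelihood (the offset
    log 0 is undefined); their IMR is still defined by the linear predictor.
    """

    def __init__(
        self,
        incidence: CountSurface,
        mortality: CountSurface,
        window: tuple[int, int] | None = None,
        knots: SplineBasis | None = None,
        random_intercept: bool = False,
    ) -> None:
        if incidence.ages != mortality.ages:
            raise ValueError("incidence and mortality grids differ")
        first = max(int(incidence.years[0]), int(mortality.years[0]))
        last = min(int(incidence.years[-1]), int(mortality.years[-1]))
        if window is not None:
            first, last = int(window[0]), int(window[1])
        if last < first:
            raise ValueError("incidence and mortality windows do not overlap")
        self.window = (first, last)
        self.incidence = incidence.window(first, last)
        self.mortality = mortality.window(first, last)
        if self.incidence.total == 0:
            raise ValueError("all-zero incidence surface")
        self.random_intercept = bool(random_intercept)
        self.knots = knots or compute_knots(self.mortality)
        self._build()

    def _build(self) -> None:
        ages = self.incidence.ages
        years = self.incidence.years
        self.year_ref = float(years.mean())
        mids = ages.midpoints
        t = years - self.year_ref
        names = ["intercept", "year", "year2", "age", *(f"hinge_{i+1}" for i in range(4))]
        X_rows, y, off = [], [], []
        spl = self.knots.design(mids)
        for a in range(ages.n):
            for j in range(years.size):
                d = self.mortality.counts[a, j]
                if d <= 0:
                    continue  # offset undefined for zero-death cells
                row = [1.0, t[j], t[j] ** 2, *spl[a]]
                if self.random_intercept:
                    re = np.zeros(ages.n)
                    re[a] = 1.0
                    row.extend(re)
                X_rows.append(row)
                y.append(self.incidence.counts[a, j])
                off.append(np.log(d))
        if self.random_intercept:
            names += [f"re_{lab}" for lab in ages.labels]
        self.param_names = tuple(names)
        self.X = np.asarray(X_rows)
        self.y = np.asarray(y, dtype=float)
        self.offset = np.asarray(off)
        if self.X.shape[0] <= self.X.shape[1]:
            raise ValueError("too few non-zero-death cells for the IMR design")

    # -- posterior --------------------------------------------------------
    def _log_posterior(self, beta: np.ndarray) -> float:
        eta = self.X @ beta + self.offset
        if np.any(eta > 500):
            return -np.inf
        mu = np.exp(eta)
        loglik = float(np.sum(self.y * eta - mu))
        logprior = float(-0.5 * np.sum((beta / PRIOR_SD) ** 2))
        return loglik + logprior

    def _map_newton(self, max_iter: int = 100, tol: float = 1e-10):
        """Penalized IRLS: Newton ascent on the Normal(0, 10^2)-prior posterior."""
        p = self.X.shape[1]
        prior_prec = np.eye(p) / PRIOR_SD**2
        beta = np.zeros(p)
        lp = self._log_posterior(beta)
        for _ in range(max_iter):
            eta = np.clip(self.X @ beta + self.offset, -500, 500)
            mu = np.exp(eta)
            grad = self.X.T @ (self.y - mu) - beta / PRIOR_SD**2
            H = self.X.T @ (self.X * mu[:, None]) + prior_prec
            step_dir = np.linalg.solve(H, grad)
            step = 1.0
            for _ in range(30):
                trial = beta + step * step_dir
                lp_t = self._log_posterior(trial)
                if lp_t >= lp - 1e-12:
                    break
                step /= 2.0
            gain = lp_t - lp
            beta, lp = trial, lp_t
            if abs(gain) < tol * (abs(lp) + 1.0):
                break
        eta = np.clip(self.X @ beta + self.offset, -500, 500)
        H = self.X.T @ (self.X * np.exp(eta)[:, None]) + prior_prec
        cov = np.linalg.inv(H)
        return beta, cov

    # -- fitting ----------------------------------------------------------
    def fit(
        self,
        method: str = "map",
        draws: int = 2000,
        warmup: int = 1000,
        chains: int = 4,
        seed: int = 0,
    ) -> IMRResults:
        """Fit the posterior.

        method="map": deterministic penalized-IRLS MAP with Laplace draws
        (fast, reproducible; suited to validation loops).
        method="mcmc": emcee ensemble sampling of the exact posterior with
        split-Rhat and ESS diagnostics.
        """
        beta_map, cov = self._map_newton()
        rng = np.random.default_rng(seed)
        if method == "map":
            sample = rng.multivariate_normal(beta_map, cov, size=draws, method="cholesky")
            diag = {"method": "laplace", "rhat": None}
            return self._results(sample, beta_map, diag, "map")
        if method != "mcmc":
            raise ValueError(f"unknown method {method!r}")
        return self._fit_mcmc(beta_map, cov, draws, warmup, chains, rng)

    def _fit_mcmc(self, beta_map, cov, draws, warmup, chains, rng):
        """Ensemble sampling in the Laplace-whitened space.

        The posterior is near-Gaussian at registry scale; sampling
        beta = beta_map + L z (L the Cholesky factor of the Laplace
        covariance) removes the coefficient correlations that otherwise slow
        the stretch move to a crawl.
        """
        import emcee

        p = beta_map.size
        L = np.linalg.cholesky(cov)

        def log_post_z(z):
            return self._log_posterior(beta_map + L @ z)

        nwalkers = max(2 * p + 2, 4 * chains)
        nwalkers -= nwalkers % (2 * chains)  # split evenly into pseudo-chains
        z0 = 0.5 * rng.standard_normal((nwalkers, p))
        # stretch-move autocorrelation is ~15-20 steps here; keep enough
        # post-warmup steps that each walker contributes >=50 effective draws
        keep_steps = max(1500, int(np.ceil(draws / nwalkers)))
        sampler = emcee.EnsembleSampler(nwalkers, p, log_post_z)
        sampler._random = np.random.RandomState(int(rng.integers(2**31 - 1)))
        sampler.run_mcmc(z0, warmup + keep_steps, progress=False)
        zchain = sampler.get_chain(discard=warmup)  # (keep_steps, nwalkers, p)
        chain = beta_map[None, None, :] + np.einsum("ij,swj->swi", L, zchain)
        diag = self._diagnostics(chain, chains)
        sample = chain.reshape(-1, p)
        if sample.shape[0] > draws:
            sel = rng.choice(sample.shape[0], size=draws, replace=False)
            sample = np.take(sample, np.sort(sel), axis=0)
        return self._results(sample, beta_map, diag, "mcmc")

    def _diagnostics(self, chain: np.ndarray, chains: int) -> dict:
        import arviz as az

        # group walkers into `chains` pseudo-chains (each walker's full
        # trajectory concatenated) for the split-Rhat / ESS computation
        n_steps, nwalkers, p = chain.shape
        k = nwalkers // chains
        posterior = (
            np.moveaxis(chain, 0, 1)          # (nwalkers, n_steps, p)
            .reshape(chains, k * n_steps, p)  # walkers laid end-to-end
        )
        idata = az.convert_to_dataset({"beta": posterior})
        rhat = az.rhat(idata)["beta"].values
        ess = az.ess(idata)["beta"].values
        return {"method": "emcee", "rhat": rhat, "ess": ess}

    def _results(self, sample, beta_map, diag, method) -> IMRResults:
        return IMRResults(
            sex=self.incidence.sex, site=self.incidence.site, ages=self.incidence.ages,
            fit_window=self.window, knots=self.knots, draws=sample,
            param_names=self.param_names, year_ref=self.year_ref,
            map_estimate=beta_map, diagnostics=diag, method=method,
            random_intercept=self.random_intercept,
        )


# ---------------------------------------------------------------------------
# functional wrappers


def fit_imr(
    incidence: CountSurface,
    mortality: CountSurface,
    window: tuple[int, int] | None = None,
    **settings,
) -> IMRResults:
    model = IMRModel(
        incidence, mortality, window=window,
        knots=settings.pop("knots", None),
        random_intercept=settings.pop("random_intercept", False),
    )
    return model.fit(**settings)


def imr_series(fit: IMRResults, years: Sequence[int] | None = None) -> IMRSeries:
    return fit.imr_series(years)
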