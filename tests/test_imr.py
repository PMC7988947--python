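import numpy as np
import pytest

from imrest import CountSurface, IMRModel, compute_knots, simulate_incidence, simulate_mortality
from imrest.imr import SplineBasis, _weighted_quantile
from imrest.synthetic import SyntheticConfig

from conftest import scale_surface

WINDOW = (1994, 2008)


def brute_force_weighted_quantile(values, weights, q):
    """Oracle: expand integer weights into repeats and walk the empirical CDF."""
    expanded = np.repeat(values, weights.astype(int))
    expanded.sort()
    cum = np.arange(1, expanded.size + 1) / expanded.size
    return expanded[np.searchsorted(cum, q - 1e-12)]


class TestKnots:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(1, 50, size=(18, 5))
        surf = CountSurface(kind="mortality", sex="male", site="x",
                            years=np.arange(2000, 2005), counts=counts)
        basis = compute_knots(surf)
        weights = counts.sum(axis=1)
        mids = surf.ages.midpoints
        for knot, q in zip(basis.knots, (0.10, 1 / 3, 2 / 3, 0.90)):
            assert knot == brute_force_weighted_quantile(mids, weights, q)

    def test_uniform_deaths_knot_positions(self):
        surf = CountSurface(kind="mortality", sex="male", site="x",
                            years=np.arange(2000, 2002), counts=np.ones((18, 2)))
        basis = compute_knots(surf)
        # equal mass on 18 midpoints: CDF(i) = (i+1)/18
        assert basis.knots == (7.5, 27.5, 57.5, 82.5)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 30, size=(18, 3)).astype(float)
        surf = CountSurface(kind="mortality", sex="male", site="x",
                            years=np.arange(2000, 2003), counts=counts)
        doubled = scale_surface(surf, 2.0)
        assert compute_knots(surf).knots == compute_knots(doubled).knots

    def test_concentrated_deaths_rejected(self):
        counts = np.zeros((18, 2))
        counts[9, :] = 100
        surf = CountSurface(kind="mortality", sex="male", site="x",
                            years=np.arange(2000, 2002), counts=counts)
        with pytest.raises(ValueError, match="coarsen"):
            compute_knots(surf)

    def test_weighted_quantile_simple(self):
        v = np.array([1.0, 2.0, 3.0])
        w = np.array([1.0, 1.0, 2.0])
        assert _weighted_quantile(v, w, 0.5) == 2.0
        assert _weighted_quantile(v, w, 0.9) == 3.0


class TestSplineBasis:
    def test_design_is_piecewise_linear_and_continuous(self):
        basis = SplineBasis(knots=(10.0, 30.0, 55.0, 80.0))
        age = np.linspace(0, 90, 901)
        rng = np.random.default_rng(0)
        coefs = rng.normal(size=basis.n_terms)
        y = basis.design(age) @ coefs
        d2 = np.diff(y, 2)
        # second differences vanish except exactly at the knots
        kink_ages = age[1:-1][np.abs(d2) > 1e-9]
        assert set(np.round(kink_ages, 6)) <= {10.0, 30.0, 55.0, 80.0}
        # continuity at the knots: jump of the function itself is zero
        for k in basis.knots:
            left = basis.design(np.array([k - 1e-9])) @ coefs
            right = basis.design(np.array([k + 1e-9])) @ coefs
            assert abs(left - right) < 1e-6

    def test_non_increasing_knots_rejected(self):
        with pytest.raises(ValueError):
            SplineBasis(knots=(10.0, 10.0, 20.0, 30.0))


@pytest.fixture(scope="module")
def constant_imr2_fit():
    cfg = SyntheticConfig(seed=13, imr_base=2.0)
    mort = simulate_mortality(cfg)
    inc = simulate_incidence(cfg, mort)
    model = IMRModel(inc, mort, window=WINDOW)
    return cfg, mort, inc, model, model.fit(method="map", draws=1000, seed=0)


class TestFit:
    def test_identity_incidence_gives_unit_imr(self, registry_fixture):
        mort = registry_fixture["mortality"]
        inc_equal = CountSurface(kind="incidence", sex=mort.sex, site=mort.site,
                                 years=mort.years.copy(), counts=mort.counts, ages=mort.ages)
        fit = IMRModel(inc_equal, mort, window=WINDOW).fit(method="map", draws=500, seed=0)
        series = fit.imr_series()
        lo, hi = series.interval
        # IMR == 1 within the 95% band across all cells
        assert np.all(lo < 1.0 + 0.1) and np.all(hi > 1.0 - 0.1)
        med = series.median
        assert np.all(np.abs(np.log(med)) < 0.1)

    def test_constant_imr_two_recovered(self, constant_imr2_fit):
        cfg, mort, inc, model, fit = constant_imr2_fit
        w = mort.window(*WINDOW).counts.astype(float)
        pooled_draws = (fit.imr_series().draws * w[None] / w.sum()).sum(axis=(1, 2))
        post_sd = pooled_draws.std()
        assert abs(np.median(pooled_draws) - 2.0) < 2 * post_sd

    def test_offset_scale_invariance(self, constant_imr2_fit):
        cfg, mort, inc, model, fit = constant_imr2_fit
        fit7 = IMRModel(scale_surface(inc, 7), scale_surface(mort, 7),
                        window=WINDOW).fit(method="map", draws=10, seed=0)
        X = model.X
        np.testing.assert_allclose(X @ fit.map_estimate, X @ fit7.map_estimate, atol=1e-3)

    def test_posterior_predictive_totals(self, constant_imr2_fit):
        cfg, mort, inc, model, fit = constant_imr2_fit
        mu = np.exp(model.X @ fit.map_estimate + model.offset)
        assert abs(mu.sum() - model.y.sum()) / model.y.sum() < 0.05

    def test_zero_death_cells_excluded_but_imr_defined(self):
        cfg = SyntheticConfig(seed=2)
        mort = simulate_mortality(cfg)
        counts = np.array(mort.counts)
        counts[0:3, :] = 0  # childhood bands: no deaths at all
        mort0 = CountSurface(kind="mortality", sex=mort.sex, site=mort.site,
                             years=mort.years, counts=counts, ages=mort.ages)
        inc = simulate_incidence(cfg, mort0)
        model = IMRModel(inc, mort0, window=WINDOW)
        n_nonzero = int((mort0.window(*WINDOW).counts > 0).sum())
        assert model.X.shape[0] == n_nonzero
        fit = model.fit(method="map", draws=50, seed=0)
        series = fit.imr_series()
        assert np.all(series.median > 0)  # defined everywhere, zero-death cells included

    def test_all_zero_incidence_rejected(self, registry_fixture):
        mort = registry_fixture["mortality"]
        zero = scale_surface(registry_fixture["incidence"], 0.0)
        zero = CountSurface(kind="incidence", sex=zero.sex, site=zero.site,
                            years=zero.years, counts=zero.counts, ages=zero.ages)
        with pytest.raises(ValueError, match="all-zero"):
            IMRModel(zero, mort, window=WINDOW)

    def test_non_overlapping_windows_rejected(self, registry_fixture):
        mort = registry_fixture["mortality"]
        inc = registry_fixture["incidence"]
        late = CountSurface(kind="incidence", sex=inc.sex, site=inc.site,
                            years=inc.years + 50, counts=inc.counts, ages=inc.ages)
        with pytest.raises(ValueError, match="overlap"):
            IMRModel(late, mort)


class TestSeries:
    def test_window_evaluation_matches_draws(self, constant_imr2_fit):
        cfg, mort, inc, model, fit = constant_imr2_fit
        series = fit.imr_series()
        # independent evaluation of one cell from the raw draws
        a, year = 10, 2000
        t = year - fit.year_ref
        mids = fit.ages.midpoints
        x = np.array([1.0, t, t * t, *fit.knots.design(np.array([mids[a]]))[0]])
        direct = np.exp(fit.draws @ x)
        j = list(series.years).index(year)
        np.testing.assert_allclose(np.median(direct), series.median[a, j], rtol=1e-12)

    def test_years_before_window_rejected(self, constant_imr2_fit):
        *_, fit = constant_imr2_fit
        with pytest.raises(ValueError, match="precede"):
            fit.imr_series(years=[1980])

    def test_interval_shrinks_with_counts(self):
        widths = []
        for factor in (1.0, 100.0):
            cfg = SyntheticConfig(seed=9, imr_base=2.0, population_size=460_000 * factor)
            mort = simulate_mortality(cfg)
            inc = simulate_incidence(cfg, mort)
            fit = IMRModel(inc, mort, window=WINDOW).fit(method="map", draws=800, seed=1)
            lo, hi = fit.imr_series().interval
            widths.append(np.mean(hi - lo))
        assert widths[1] < widths[0] / 5  # roughly sqrt(100) shrinkage


class TestMCMC:
    def test_mcmc_agrees_with_map_and_converges(self, registry_fixture):
        mort, inc = registry_fixture["mortality"], registry_fixture["incidence"]
        model = IMRModel(inc, mort, window=WINDOW)
        bayes = model.fit(method="mcmc", draws=2000, warmup=1000, seed=3)
        assert bayes.converged, f"rhat={bayes.diagnostics['rhat']}"
        # ML/MAP point estimates within 1 posterior SD of the Bayesian medians
        med = np.median(bayes.draws, axis=0)
        sd = bayes.draws.std(axis=0)
        assert np.all(np.abs(bayes.map_estimate - med) < sd)

    def test_mcmc_deterministic_under_seed(self, registry_fixture):
        mort, inc = registry_fixture["mortality"], registry_fixture["incidence"]
        model = IMRModel(inc, mort, window=WINDOW)
        a = model.fit(method="mcmc", draws=200, warmup=100, seed=5)
        b = model.fit(method="mcmc", draws=200, warmup=100, seed=5)
        np.testing.assert_array_equal(a.draws, b.draws)
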