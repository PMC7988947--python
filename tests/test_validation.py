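import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from imrest import (
    LagDesign,
    build_windows,
    estimate_for_target,
    mape,
    relative_deviation,
    run_back_validation,
    select_best_scenario,
)
from imrest.reporting import load_printed_pairs, round_half_away


class TestRelativeDeviation:
    @pytest.mark.parametrize(
        "observed, expected, printed",
        [(1963, 1888, -3.8), (4424, 4936, 11.6), (4220, 4082, -3.3),
         (615, 703, 14.3), (557, 487, -12.6)],
    )
    def test_reference_values(self, observed, expected, printed):
        assert round_half_away(relative_deviation(observed, expected), 1) == printed

    def test_identity_is_zero(self):
        assert relative_deviation(123, 123) == 0.0

    def test_zero_observed_rejected(self):
        with pytest.raises(ValueError):
            relative_deviation(0, 10)


class TestMape:
    def test_reference_yearly_pairs(self):
        pairs = load_printed_pairs("yearly")
        results = {}
        for sex, grp in pairs.groupby("sex"):
            obs = dict(zip(grp["year"], grp["observed"]))
            exp = dict(zip(grp["year"], grp["expected"]))
            results[sex] = round_half_away(mape(obs, exp), 2)
        assert results["male"] == 6.34
        assert results["female"] == 3.85

    def test_perfect_forecast_gives_zero(self):
        obs = {2000: 10, 2001: 20}
        assert mape(obs, dict(obs)) == 0.0

    def test_mismatched_years_rejected(self):
        with pytest.raises(ValueError, match="year sets"):
            mape({2000: 1}, {2001: 1})

    def test_zero_observed_year_dropped_with_warning(self):
        obs = {2000: 0, 2001: 100}
        exp = {2000: 5, 2001: 110}
        with pytest.warns(UserWarning, match="zero-observed"):
            assert mape(obs, exp) == 10.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_permutation_and_scale_invariance(self, seed):
        rng = np.random.default_rng(seed)
        years = np.arange(2000, 2000 + rng.integers(3, 12))
        obs = rng.uniform(10, 1000, years.size)
        exp = rng.uniform(10, 1000, years.size)
        base = mape(dict(zip(years, obs)), dict(zip(years, exp)))
        perm = rng.permutation(years.size)
        shuffled = mape(dict(zip(years[perm], obs[perm])), dict(zip(years[perm], exp[perm])))
        scaled = mape(dict(zip(years, 7.5 * obs)), dict(zip(years, 7.5 * exp)))
        assert base == pytest.approx(shuffled, rel=1e-12)
        assert base == pytest.approx(scaled, rel=1e-12)
        assert (base == 0.0) == bool(np.all(obs == exp))


class TestBestScenario:
    def test_argmin(self):
        assert select_best_scenario({"C1": 2.0, "L": 1.0}) == "L"

    def test_tie_prefers_simpler_assumption(self):
        assert select_best_scenario({"C3": 1.0, "C1": 1.0}) == "C1"
        assert select_best_scenario({c: 3.0 for c in ("C1", "C3", "C5", "L", "Q")}) == "C1"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best_scenario({})


class TestWindows:
    def test_reference_design_for_2013(self):
        w = build_windows(2013)
        assert w["mortality_window"] == (1991, 2010)
        assert w["mortality_projection"] == (2011, 2013)
        assert w["imr_window"] == (1994, 2008)
        assert w["imr_projection"] == (2009, 2013)

    def test_earliest_target_2004_fits_data_availability(self):
        # rolling 2013 -> 2004 never needs mortality before 1982 or incidence before 1985
        for target in range(2004, 2014):
            w = build_windows(target, first_mortality_year=1982, first_incidence_year=1985)
            assert w["mortality_window"][0] >= 1982
            assert w["imr_window"][0] >= 1985
        w2004 = build_windows(2004)
        assert w2004["mortality_window"] == (1982, 2001)
        assert w2004["imr_window"] == (1985, 1999)

    def test_target_before_first_feasible_year_rejected(self):
        with pytest.raises(ValueError, match="before first available"):
            build_windows(2003, first_mortality_year=1982)

    def test_incidence_lag_shorter_than_mortality_rejected(self):
        with pytest.raises(ValueError):
            LagDesign(mortality_lag=5, incidence_lag=3)


class TestBackValidation:
    def test_leakage_guard_truncation_changes_nothing(self, registry_fixture):
        mort = registry_fixture["mortality"]
        inc = registry_fixture["incidence"]
        pop = registry_fixture["population"]
        target = 2013
        full = estimate_for_target(mort, inc, pop, target, seed=3)
        truncated = estimate_for_target(
            mort.truncate_after(target - 3), inc.truncate_after(target - 5),
            pop, target, seed=3,
        )
        for code in full:
            assert full[code].equals(truncated[code]), code

    def test_report_shape_and_aggregate_additivity(self, registry_fixture):
        mort = registry_fixture["mortality"]
        inc = registry_fixture["incidence"]
        pop = registry_fixture["population"]
        strata = {
            ("male", "lung"): mort,
            ("male", "colon"): mort,
        }
        inc_strata = {
            ("male", "lung"): inc,
            ("male", "colon"): inc,
        }
        report = run_back_validation(
            strata, inc_strata, pop, targets=[2012, 2013], draws=200, seed=1
        )
        # 2 sites + aggregate, 5 scenarios, 2 targets
        assert len(report.pairs) == 3 * 5 * 2
        agg = "all sites (except non-melanoma skin)"
        for (scen, year), grp in report.pairs.groupby(["scenario", "year"]):
            sites = grp[grp["site"] != agg]
            total = grp[grp["site"] == agg]
            assert total["expected"].iloc[0] == pytest.approx(sites["expected"].sum())
            assert total["observed"].iloc[0] == pytest.approx(sites["observed"].sum())
        best = report.best_scenarios()
        mt = report.mape_table()
        for _, row in best.iterrows():
            others = mt[(mt["sex"] == row["sex"]) & (mt["site"] == row["site"])]["mape"]
            assert row["mape"] <= others.min() + 1e-12

    def test_constant_imr_constant_scenarios_score_well(self, registry_fixture):
        report = run_back_validation(
            registry_fixture["mortality"], registry_fixture["incidence"],
            registry_fixture["population"], targets=[2011, 2012, 2013],
            draws=400, seed=2,
        )
        mt = report.mape_table().set_index("scenario")["mape"]
        assert max(mt[c] for c in ("C1", "C3", "C5")) < 10.0
        assert abs(mt["C1"] - mt["C5"]) < 5.0

    def test_linear_trend_selects_linear_scenario(self, linear_fixture):
        report = run_back_validation(
            linear_fixture["mortality"], linear_fixture["incidence"],
            linear_fixture["population"], targets=[2011, 2012, 2013],
            draws=400, seed=2,
        )
        # a steadily rising log-IMR must favour the trend scenarios (Q nests L,
        # so either may edge ahead on one realisation) over the constants
        best = report.best_scenarios()
        assert best["best_scenario"].iloc[0] in {"L", "Q"}
        mt = report.mape_table().set_index("scenario")["mape"]
        assert mt["L"] < min(mt["C1"], mt["C3"], mt["C5"])


class TestFunnel:
    def test_limits_shrink_with_volume_and_zero_deviation_inside(self, registry_fixture):
        report = run_back_validation(
            registry_fixture["mortality"], registry_fixture["incidence"],
            registry_fixture["population"], targets=[2012, 2013], draws=200, seed=4,
        )
        funnel = report.funnel()
        row = funnel.iloc[0]
        total = row["mean_annual_observed"] * 2
        assert row["limit_95"] == pytest.approx(1.96 * 100 / np.sqrt(total))
        assert row["limit_998"] > row["limit_95"]
        # a site with 100x the counts has 10x tighter limits
        assert 1.96 * 100 / np.sqrt(100 * total) == pytest.approx(row["limit_95"] / 10)
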