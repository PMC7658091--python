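import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ecoclimex as ec
from ecoclimex.core_engine import (
    annual_growth_index,
    degree_days_annual,
    diapause_series,
    ecoclimatic_index,
    growth_index_series,
    moisture_index,
    soil_moisture_series,
    stress_indices,
    temperature_index,
    weekly_evaporation,
)
from oracle import oracle_run_cell


class TestResponseCurves:
    @pytest.mark.parametrize(
        "tavg, expected",
        [(27.0, 1.0), (30.0, 1.0), (12.0, 0.0), (33.0, 0.0), (19.5, 0.5), (31.5, 0.5), (-5.0, 0.0), (50.0, 0.0)],
    )
    def test_temperature_trapezoid(self, params, tavg, expected):
        assert temperature_index(tavg, params) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "S, expected",
        [(0.75, 1.0), (0.3, 0.5), (1.6, 0.0), (0.05, 0.0), (1.25, 0.5)],
    )
    def test_moisture_trapezoid(self, params, S, expected):
        assert moisture_index(S, params) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(-60, 60))
    @settings(deadline=None, derandomize=True)
    def test_temperature_index_in_unit_interval(self, t):
        ti = temperature_index(t, ec.default_parameters())
        assert 0.0 <= ti <= 1.0


class TestEvaporation:
    def test_saturated_air_gives_zero(self):
        assert weekly_evaporation(20.0, 100.0, 100.0) == 0.0

    def test_frozen_cutoff(self):
        assert weekly_evaporation(-5.0, 50.0, 50.0) == 0.0

    def test_stated_formula_value(self):
        # 0.8 * 7 * 10 * 0.5
        assert weekly_evaporation(10.0, 50.0, 50.0, k_e=0.8) == pytest.approx(28.0)


class TestSoilBucket:
    def test_drainage_to_empty(self):
        S = soil_moisture_series(np.zeros(52), np.full(52, 10.0), S0=0.5)
        assert S[-1] == 0.0
        assert (S >= 0).all() and (np.diff(S) <= 0).all()

    def test_balance_identity(self):
        flux = np.full(52, 7.0)
        S = soil_moisture_series(flux, flux, S0=0.5)
        np.testing.assert_allclose(S, 0.5)

    def test_surplus_saturates_at_cap(self):
        """Sustained surplus pins the bucket at the storage cap."""
        S = soil_moisture_series(
            np.full(52, 25.0), np.full(52, 5.0), capacity=100.0, S0=0.5, s_max=2.0
        )
        np.testing.assert_allclose(S, 2.0)

    def test_default_cap_is_field_capacity(self):
        S = soil_moisture_series(np.full(52, 25.0), np.full(52, 5.0))
        np.testing.assert_allclose(S, 1.0)

    @pytest.mark.parametrize("s0", [0.0, 0.5, 2.0])
    def test_steady_state_forgets_initial_condition(self, s0):
        """With positive evaporation the periodic fixed point is unique."""
        rng = np.random.default_rng(7)
        rain = rng.uniform(0, 10, 52)
        evap = rng.uniform(5, 15, 52)
        ref = soil_moisture_series(rain, evap, S0=0.5, s_max=2.0)
        S = soil_moisture_series(rain, evap, S0=s0, s_max=2.0)
        np.testing.assert_allclose(S, ref, atol=1e-9)


class TestDiapause:
    def test_warm_year_never_induces(self, params):
        DI = diapause_series(np.full(52, 20.0), ec.day_length(47.38), params)
        np.testing.assert_array_equal(DI, 1.0)

    def test_equatorial_days_never_induce(self, params):
        DI = diapause_series(np.full(52, 2.0), np.full(52, 12.5), params)
        np.testing.assert_array_equal(DI, 1.0)

    def test_alpine_hand_trace(self, params):
        """Cold short-day weeks 44-52 and 1-10 induce; warmth at week 12 terminates."""
        tavg = np.full(52, 10.0)
        tavg[43:52] = 2.0  # weeks 44..52
        tavg[0:10] = 2.0   # weeks 1..10
        tavg[10] = 4.0     # week 11: still below DPT1, cannot terminate
        daylength = ec.day_length(47.38)
        DI = diapause_series(tavg, daylength, params)
        expected = np.ones(52)
        expected[43:] = 0.0
        expected[:11] = 0.0
        np.testing.assert_array_equal(DI, expected)


class TestGrowthIndices:
    def test_product_identity_and_annihilation(self):
        TI = np.full(52, 0.5)
        MI = np.full(52, 0.5)
        DI = np.ones(52)
        DI[10] = 0.0
        GI = growth_index_series(TI, MI, DI)
        assert GI[0] == pytest.approx(0.25)
        assert GI[10] == 0.0

    @pytest.mark.parametrize(
        "gi, expected",
        [(np.ones(52), 100.0), (np.zeros(52), 0.0),
         (np.concatenate([np.ones(26), np.zeros(26)]), 50.0)],
    )
    def test_annual_growth_index(self, gi, expected):
        assert annual_growth_index(gi) == pytest.approx(expected)


class TestStress:
    def _benign(self):
        return dict(
            tmin=np.full(52, 0.0), tmax=np.full(52, 20.0),
            tavg=np.full(52, 10.0), S=np.full(52, 0.8),
        )

    def test_benign_climate_accrues_nothing(self, params):
        out = stress_indices(**self._benign(), p=params)
        assert all(x == 0.0 for x in out)

    def test_single_cold_week(self, params):
        kw = self._benign()
        kw["tmin"] = kw["tmin"].copy()
        kw["tmin"][2] = -20.0
        CS, *_ = stress_indices(**kw, p=params)
        assert CS == pytest.approx(2.0)  # 100 * 0.01 * (-18 - (-20))

    def test_single_hot_week(self, params):
        kw = self._benign()
        kw["tmax"] = kw["tmax"].copy()
        kw["tmax"][30] = 35.0
        _, HS, *_ = stress_indices(**kw, p=params)
        assert HS == pytest.approx(2.0)

    def test_dry_and_wet_and_hotwet(self, params):
        kw = self._benign()
        kw["S"] = np.full(52, 0.05)
        _, _, DS, _, _ = stress_indices(**kw, p=params)
        assert DS == pytest.approx(100 * 0.01 * 0.05 * 52)
        kw["S"] = np.full(52, 1.8)
        kw["tavg"] = np.full(52, 30.0)
        _, _, _, WS, HW = stress_indices(**kw, p=params)
        assert WS == pytest.approx(100 * 0.002 * 0.3 * 52)
        assert HW == pytest.approx(100 * 0.007 * 2.0 * 52)

    def test_cap_at_100(self, params):
        kw = self._benign()
        kw["tmin"] = np.full(52, -60.0)
        CS, *_ = stress_indices(**kw, p=params)
        assert CS == 100.0


class TestDegreeDays:
    def test_at_threshold(self, params):
        DD, gens = degree_days_annual(np.full(52, 12.0), params)
        assert DD == 0.0 and gens == 0.0

    def test_constant_warm_year(self, params):
        DD, gens = degree_days_annual(np.full(52, 24.0), params)
        assert DD == pytest.approx(7 * 12 * 52)
        assert gens == pytest.approx(4368 / 595)

    def test_closed_form_inversion_one_generation(self, params):
        DD, gens = degree_days_annual(np.full(52, 12.0 + 595.0 / 364.0), params)
        assert gens == pytest.approx(1.0)


class TestEcoclimaticIndex:
    def test_maximum(self, params):
        assert ecoclimatic_index(100.0, 0, 0, 0, 0, 0, 600.0, params) == 100.0

    def test_thermal_constant_gate(self, params):
        assert ecoclimatic_index(40.0, 0, 0, 0, 0, 0, 364.0, params) == 0.0

    def test_single_stress_product(self, params):
        assert ecoclimatic_index(50.0, 20, 0, 0, 0, 0, 600.0, params) == pytest.approx(40.0)


class TestRunCell:
    def test_constant_optimal_climate(self, params):
        climate = ec.WeeklyClimate(
            tmin=np.full(52, 28.5), tmax=np.full(52, 28.5),
            rain=np.zeros(52), rh09=np.full(52, 100.0), rh15=np.full(52, 100.0),
            daylength=np.full(52, 16.0),
        )
        r = ec.run_cell(climate, params)
        assert r.EI == 100.0
        assert r.generations == pytest.approx(7 * 16.5 * 52 / 595)
        assert r.growth_weeks == 52

    def test_cold_year_is_unsuitable(self, params):
        climate = ec.WeeklyClimate(
            tmin=np.full(52, 10.0), tmax=np.full(52, 10.0),
            rain=np.full(52, 20.0), rh09=np.full(52, 90.0), rh15=np.full(52, 80.0),
            daylength=ec.day_length(47.0),
        )
        r = ec.run_cell(climate, params)
        assert r.EI == 0.0 and r.DD_annual == 0.0 and r.growth_weeks == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_independent_scalar_oracle(self, params, seed):
        """run_cell agrees with a straight-line scalar re-implementation."""
        rng = np.random.default_rng(seed)
        tmin = rng.uniform(-25, 20, 52)
        tmax = tmin + rng.uniform(0, 15, 52)
        climate = ec.WeeklyClimate(
            tmin=tmin, tmax=tmax,
            rain=rng.uniform(0, 40, 52),
            rh09=rng.uniform(30, 100, 52), rh15=rng.uniform(30, 100, 52),
            daylength=ec.day_length(46.5),
        )
        got = ec.run_cell(climate, params)
        want = oracle_run_cell(
            list(climate.tmin), list(climate.tmax), list(climate.rain),
            list(climate.rh09), list(climate.rh15), list(climate.daylength),
            params,
        )
        for key, expected in want.items():
            assert getattr(got, key) == pytest.approx(expected, abs=1e-10), key


class TestRunGrid:
    def test_singleton_grid_equals_run_cell(self, params):
        grid = ec.make_synthetic_grid(ec.SyntheticConfig(n_lon=1, n_lat=1, seed=3))
        res = ec.run_grid(grid, params)
        climate = ec.build_weekly_climate(
            grid.tmin[:, 0, 0], grid.tmax[:, 0, 0], grid.prec[:, 0, 0], grid.lat[0]
        )
        cell = ec.run_cell(climate, params)
        assert res.EI[0, 0] == pytest.approx(cell.EI, abs=1e-12)
        assert res.generations[0, 0] == pytest.approx(cell.generations, abs=1e-12)

    def test_grid_equals_mapped_scalar_path(self, params, desk_grid, desk_result):
        """Vectorized grid run equals looping run_cell over cells, to 1e-10."""
        ii, jj = np.nonzero(desk_grid.land_mask)
        rng = np.random.default_rng(0)
        for k in rng.choice(ii.size, size=40, replace=False):
            i, j = ii[k], jj[k]
            climate = ec.build_weekly_climate(
                desk_grid.tmin[:, i, j], desk_grid.tmax[:, i, j],
                desk_grid.prec[:, i, j], desk_grid.lat[i],
            )
            cell = ec.run_cell(climate, params)
            for layer in ("EI", "GI_A", "DD_annual", "generations", "growth_weeks"):
                assert getattr(desk_result, layer)[i, j] == pytest.approx(
                    getattr(cell, layer), abs=1e-10
                ), layer

    def test_all_alpine_grid_is_unsuitable(self, params):
        cfg = ec.SyntheticConfig(n_lon=5, n_lat=5, valley_floor_m=2000.0,
                                 ridge_amplitude_m=300.0, seed=1)
        res = ec.run_grid(ec.make_synthetic_grid(cfg), params)
        assert np.nanmax(res.EI) == 0.0


class TestEngineInvariants:
    def test_index_ranges_and_ei_bound(self, desk_result):
        m = desk_result.land_mask
        for layer in ("EI", "GI_A", "CS", "HS", "DS", "WS", "HW"):
            vals = getattr(desk_result, layer)[m]
            assert (vals >= 0).all() and (vals <= 100).all(), layer
        assert (desk_result.EI[m] <= desk_result.GI_A[m] + 1e-12).all()

    def test_pdd_gate_iff_unsuitable(self, desk_result, params):
        """With all stresses below 100, EI = 0 exactly when DD < PDD."""
        m = desk_result.land_mask
        gate = desk_result.DD_annual[m] < params.PDD
        zero = desk_result.EI[m] == 0.0
        # the synthetic climate has positive growth wherever a generation fits
        np.testing.assert_array_equal(gate, zero)

    @given(st.floats(0.5, 5.0))
    @settings(deadline=None, derandomize=True, max_examples=20)
    def test_warming_monotone_below_lower_optimum(self, delta):
        """Uniform warming of a cool, moisture-neutral year never lowers
        GI_A, degree days, generations or EI while tavg stays <= DV1."""
        p = ec.default_parameters()
        w = np.arange(52)
        tavg = 8.0 + 10.0 * np.cos(2 * np.pi * (w - 27) / 52)  # max 18 < 27 - 5
        def run(shift):
            climate = ec.WeeklyClimate(
                tmin=tavg + shift - 4, tmax=tavg + shift + 4,
                rain=np.full(52, 15.0),
                rh09=np.full(52, 100.0), rh15=np.full(52, 100.0),
                daylength=ec.day_length(47.0),
            )
            return ec.run_cell(climate, p)
        base, warm = run(0.0), run(delta)
        assert warm.GI_A >= base.GI_A - 1e-12
        assert warm.DD_annual >= base.DD_annual
        assert warm.generations >= base.generations
        assert warm.EI >= base.EI - 1e-12
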