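"""Reduced-form vegetation simulator: elementary relations, demographic
steps, and whole-cell trajectories."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dvmuq import standard_values
from dvmuq.dgvm_core import (
    DataError,
    GridCellState,
    SimConfig,
    annual_production,
    bioclim_allows,
    colimitation_root,
    default_pft_table,
    enforce_fpc_constraints,
    establishment,
    lambert_beer_fpc,
    mortality,
    mortality_rate,
    run_grid,
    run_gridcell,
    update_allometry,
)


@pytest.fixture(scope="module")
def pfts():
    return default_pft_table()


@pytest.fixture(scope="module")
def params(param_specs):
    return {s.name: s.standard for s in param_specs}


class TestLambertBeer:
    def test_no_leaves_no_cover(self):
        assert lambert_beer_fpc(0.0, 0.5) == 0.0

    def test_asymptote(self):
        assert lambert_beer_fpc(1e6, 0.5) == pytest.approx(1.0)

    def test_closed_form(self):
        assert lambert_beer_fpc(2.0, 0.5) == pytest.approx(1 - np.exp(-1), abs=1e-12)

    def test_negative_lai_rejected(self):
        with pytest.raises(ValueError):
            lambert_beer_fpc(-0.1, 0.5)

    @settings(derandomize=True, max_examples=50)
    @given(
        lai=st.floats(0, 20), dlai=st.floats(0.001, 5),
        k=st.floats(0.01, 2), dk=st.floats(0.001, 1),
    )
    def test_monotone_in_both_arguments(self, lai, dlai, k, dk):
        base = lambert_beer_fpc(lai, k)
        assert lambert_beer_fpc(lai + dlai, k) >= base
        assert lambert_beer_fpc(lai, k + dk) >= base
        assert 0 <= base < 1


class TestColimitation:
    def test_theta_near_one_approaches_min(self):
        je, jc = 0.3, 0.8
        assert colimitation_root(je, jc, 1.0) == pytest.approx(min(je, jc), rel=1e-9)

    def test_root_below_both_rates(self):
        phi = colimitation_root(0.4, 0.6, 0.7)
        assert 0 < phi < 0.4

    def test_theta_out_of_range(self):
        for theta in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                colimitation_root(0.3, 0.4, theta)


class TestProduction:
    def _climate(self, n_cells=1):
        tas = np.full((12, n_cells), 15.0)
        pr = np.full((12, n_cells), 50.0)
        clt = np.full((12, n_cells), 0.5)
        return tas, pr, clt

    def test_no_quantum_efficiency_no_production(self, params, pfts):
        tas, pr, clt = self._climate()
        p = dict(params, alpha_C3=0.0)
        npp = annual_production(
            tas, pr, clt, 370.0, p, pfts[0], np.array([0.8]),
            np.array([55.0]), SimConfig(),
        )
        assert npp == pytest.approx(0.0)

    def test_co2_response_monotone(self, params, pfts):
        tas, pr, clt = self._climate()
        fpc = np.array([0.6])
        lat = np.array([55.0])
        npp = [
            annual_production(tas, pr, clt, c, params, pfts[0], fpc, lat, SimConfig())
            for c in (370.0, 740.0)
        ]
        assert npp[1] >= npp[0]
        assert npp[0] > 0

    def test_zero_cover_zero_production(self, params, pfts):
        tas, pr, clt = self._climate()
        npp = annual_production(
            tas, pr, clt, 370.0, params, pfts[0], np.array([0.0]),
            np.array([55.0]), SimConfig(),
        )
        assert npp == pytest.approx(0.0)

    def test_invalid_fpc_rejected(self, params, pfts):
        tas, pr, clt = self._climate()
        with pytest.raises(ValueError):
            annual_production(
                tas, pr, clt, 370.0, params, pfts[0], np.array([1.2]),
                np.array([55.0]), SimConfig(),
            )


class TestAllometry:
    def test_zero_pools_zero_dimensions(self, params, pfts):
        h, ca, d, lai = update_allometry(
            np.zeros(1), np.zeros(1), np.zeros(1), params, pfts[0]
        )
        assert h == 0 and d == 0 and lai == 0

    def test_crown_cap_binds_for_large_trees(self, params, pfts):
        # a tree tall enough that k_allom1 * h^k_rp >> CA_max
        h, ca, d, lai = update_allometry(
            np.array([50.0]), np.array([150.0]), np.array([150.0]), params, pfts[0]
        )
        assert h[0] > 2.0
        assert min(params["k_allom1"] * h[0] ** params["k_rp"], params["CA_max"]) == ca[0]
        assert ca[0] == params["CA_max"]

    def test_height_diameter_relation(self, params, pfts):
        h, ca, d, lai = update_allometry(
            np.array([1.0]), np.array([20.0]), np.array([5.0]), params, pfts[0]
        )
        assert h[0] == pytest.approx(pfts[0].k_allom2 * d[0] ** params["k_allom3"])

    def test_leaf_area_capped_by_sapwood(self, params, pfts):
        # huge leaf pool, little sapwood: the la:sa constraint must bind
        h, ca, d, lai = update_allometry(
            np.array([500.0]), np.array([5.0]), np.array([5.0]), params, pfts[0]
        )
        sap_cross = 5.0 / (pfts[0].wood_density * h[0])
        assert lai[0] * ca[0] == pytest.approx(params["k_la_sa"] * sap_cross)

    def test_grass_lai_from_sla(self, params, pfts):
        grass = pfts[-1]
        assert not grass.woody
        h, ca, d, lai = update_allometry(
            np.array([0.1]), np.zeros(1), np.zeros(1), params, grass
        )
        assert ca[0] == 1.0 and lai[0] == pytest.approx(0.1 * grass.sla)

    def test_negative_pools_rejected(self, params, pfts):
        with pytest.raises(ValueError):
            update_allometry(np.array([-1.0]), np.zeros(1), np.zeros(1), params, pfts[0])


class TestBioclim:
    def test_cold_limit_blocks_establishment(self, pfts):
        tne = pfts[0]
        est, _ = bioclim_allows(
            tne, np.array([tne.tc_min_est - 1.0]), np.array([15.0]), np.array([2000.0])
        )
        assert not est[0]

    def test_infinite_limits_always_allow(self):
        from dvmuq.dgvm_core import PFTConfig

        anything = PFTConfig(
            id="ANY", name="any", woody=True, phenology="evergreen",
            tc_min_est=-np.inf, tc_max_est=np.inf, gdd5_min=0.0,
            tw_max=np.inf, tc_min_surv=-np.inf, k_allom2=40.0, sla=10.0,
            wood_density=200.0, maint_resp=0.02,
        )
        est, surv = bioclim_allows(
            anything, np.array([-60.0]), np.array([45.0]), np.array([0.0])
        )
        assert est[0] and surv[0]

    def test_survival_flips_when_warming_crosses_limit(self, pfts):
        bne = pfts[3]
        tw = np.linspace(bne.tw_max - 2.0, bne.tw_max + 2.0, 21)
        flags = [
            bioclim_allows(bne, np.array([-10.0]), np.array([t]), np.array([800.0]))[1][0]
            for t in tw
        ]
        assert flags[0] and not flags[-1]
        assert sorted(flags, reverse=True) == flags  # single crossing


class TestMortality:
    def test_rate_limits(self):
        assert mortality_rate(0.0, 0.05, 0.5) == 0.05
        assert mortality_rate(1e9, 0.05, 0.5) == pytest.approx(0.0, abs=1e-9)
        assert mortality_rate(2.0, 0.05, 0.5) == pytest.approx(0.025)

    def test_step_never_increases_fpc(self, params, pfts):
        state = GridCellState.bare(4, 6)
        state.density[:] = 0.05
        state.fpc[:] = 0.1
        state.greff[:] = 0.2
        heat = np.zeros((4, 6), dtype=bool)
        heat[0, 3] = True
        survive = np.ones((4, 6), dtype=bool)
        survive[1, 4] = False
        out = mortality(state, params, heat, survive, SimConfig())
        assert np.all(out.fpc <= state.fpc + 1e-15)
        assert out.fpc[1, 4] == 0.0  # bioclim removal
        assert out.fpc[0, 3] < state.fpc[0, 3] * (1 - 0.99 * 0.0)  # heat loss


class TestEstablishment:
    def _ok(self, n=1):
        return np.ones((n, 6), dtype=bool)

    def test_bare_cell_full_rate(self, params, pfts):
        state = GridCellState.bare(1, 6)
        out = establishment(state, params, self._ok(), pfts, SimConfig())
        woody = [j for j, p in enumerate(pfts) if p.woody]
        np.testing.assert_allclose(out.density[0, woody], params["est_max"])

    def test_closed_canopy_blocks_woody(self, params, pfts):
        state = GridCellState.bare(1, 6)
        state.fpc[0, :5] = 0.2  # woody sum = 1.0
        out = establishment(state, params, self._ok(), pfts, SimConfig())
        np.testing.assert_array_equal(out.density[0, :5], 0.0)

    def test_attenuation_halves_at_0975(self, params, pfts):
        state = GridCellState.bare(1, 6)
        state.fpc[0, 3] = 0.975
        out = establishment(state, params, self._ok(), pfts, SimConfig())
        expect = params["est_max"] * (1 - 0.975) * 0.5
        assert out.density[0, 0] == pytest.approx(expect)

    def test_step_never_decreases_fpc(self, params, pfts, rng):
        state = GridCellState.bare(5, 6)
        state.fpc[:] = rng.random((5, 6)) * 0.15
        state.density[:] = 0.01
        out = establishment(state, params, self._ok(5), pfts, SimConfig())
        assert np.all(out.fpc >= state.fpc - 1e-15)

    def test_grass_fills_nonwoody_space(self, params, pfts):
        state = GridCellState.bare(1, 6)
        state.fpc[0, :5] = 0.19  # total woody 0.95, free space 0.05
        out = establishment(state, params, self._ok(), pfts, SimConfig())
        assert out.density[0, 5] == pytest.approx(params["est_max"] * 0.05)


class TestFPCConstraints:
    def _state(self, woody_each, grass):
        state = GridCellState.bare(1, 6)
        state.fpc[0, :5] = woody_each
        state.fpc[0, 5] = grass
        state.density[0] = 0.1
        return state

    def test_feasible_untouched(self, pfts):
        state = self._state(0.14, 0.2)  # woody 0.7, grass 0.2
        out = enforce_fpc_constraints(state, pfts)
        np.testing.assert_allclose(out.fpc, state.fpc)

    def test_grass_yields_first(self, pfts):
        state = self._state(0.19, 0.15)  # woody 0.95, grass 0.15
        out = enforce_fpc_constraints(state, pfts)
        np.testing.assert_allclose(out.fpc[0, :5], 0.19)
        assert out.fpc[0, 5] == pytest.approx(0.05)

    def test_woody_rescaled_when_alone_exceeds_one(self, pfts):
        state = self._state(0.22, 0.1)  # woody 1.1
        out = enforce_fpc_constraints(state, pfts)
        np.testing.assert_allclose(out.fpc[0, :5], 0.22 / 1.1)
        assert out.fpc[0, 5] == 0.0
        assert out.fpc.sum() == pytest.approx(1.0)


class TestRunGrid:
    def test_hostile_climate_stays_bare(self, params, small_grid):
        from dvmuq.climate_synth import generate_scenario, get_scenario
        import xarray as xr

        spec = get_scenario("B1").with_noise_scale(0.0)
        cube = generate_scenario(spec, small_grid, range(2001, 2031), seed=0)
        frozen = cube.copy()
        frozen["tas"] = frozen.tas - 80.0  # below every establishment window
        traj = run_gridcell(params, frozen)
        np.testing.assert_array_equal(traj, 0.0)

    def test_no_establishment_stays_bare(self, params, forcing_cube):
        p = dict(params, est_max=0.0)
        traj = run_gridcell(p, forcing_cube)
        np.testing.assert_array_equal(traj, 0.0)

    def test_boreal_pft_establishes_under_default_config(self, params, forcing_cube):
        result = run_grid(params, forcing_cube)
        bne = result.pft_ids.index("BNE")
        sel = result.years == 2000
        assert result.fpc[sel, :, bne].max() > 0.05

    def test_invariants_every_cell_year(self, params, forcing_cube):
        result = run_grid(params, forcing_cube, record_steps=True)
        sums = result.fpc.sum(axis=2)
        assert sums.min() >= 0.0 and sums.max() <= 1.0 + 1e-9
        assert result.diagnostics["est_fpc_delta_min"].min() >= -1e-12
        assert result.diagnostics["mort_fpc_delta_max"].max() <= 1e-12

    def test_determinism(self, params, forcing_cube):
        a = run_grid(params, forcing_cube, seed=1)
        b = run_grid(params, forcing_cube, seed=1)
        np.testing.assert_array_equal(a.fpc, b.fpc)

    def test_nan_climate_reported_with_location(self, params, forcing_cube):
        bad = forcing_cube.copy(deep=True)
        arr = bad.tas.values
        arr[3, 5, 0, 0] = np.nan
        with pytest.raises(DataError, match="year"):
            run_grid(params, bad)

    def test_higher_co2_never_lowers_production(self, params, pfts):
        # monotone CO2 response propagated through a short run
        tas = np.full((12, 1), 14.0)
        pr = np.full((12, 1), 60.0)
        clt = np.full((12, 1), 0.4)
        lat = np.array([50.0])
        cfg = SimConfig()
        for fpc in (0.1, 0.5, 0.9):
            npps = [
                annual_production(
                    tas, pr, clt, c, params, pfts[0], np.array([fpc]), lat, cfg
                )[0]
                for c in (300.0, 370.0, 500.0, 900.0)
            ]
            assert all(b >= a for a, b in zip(npps, npps[1:]))
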