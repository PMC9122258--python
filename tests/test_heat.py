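import numpy as np
import pandas as pd
import pytest

from thermosalmon import heat, scenarios, solar, synth
from thermosalmon.heat import (
    EvaporationParams,
    ModelConfig,
    SubstrateParams,
    bed_flux,
    default_candidates,
    run_model,
    saturation_vapor_pressure,
    step_temperature,
    surface_fluxes,
)
from thermosalmon.hydraulics import FlowState

MET = {"air_c": 18.0, "rh_pct": 70.0, "wind_mps": 2.0, "solar_wm2": 600.0}


class TestSurfaceFluxes:
    def test_latent_independent_of_wind_with_zero_slope(self):
        # calibrated mass-transfer wind function: slope coefficient 0.0
        evap = EvaporationParams(wind_offset_coeff=2.21e-9, wind_slope_coeff=0.0)
        results = []
        for wind in (0.0, 3.0, 12.0):
            met = dict(MET, wind_mps=wind)
            fx = surface_fluxes(met, 20.0, 0.2, 0.3, 0.5, evap=evap)
            results.append(float(fx.latent))
        assert results[0] == results[1] == results[2]

    def test_zero_gradients_zero_turbulent_fluxes(self):
        met = dict(MET, air_c=20.0, rh_pct=100.0)
        fx = surface_fluxes(met, 20.0, 0.0, 0.0, 0.5)
        assert float(fx.latent) == pytest.approx(0.0, abs=1e-12)
        assert float(fx.sensible) == pytest.approx(0.0, abs=1e-12)

    def test_back_radiation_stefan_boltzmann(self):
        fx = surface_fluxes(MET, 20.0, 0.0, 0.0, 0.5)
        expected = -0.96 * 5.670374419e-8 * 293.15**4
        assert float(fx.back_radiation) == pytest.approx(expected, rel=1e-12)

    def test_full_shade_blocks_direct_only(self):
        fx_clear = surface_fluxes(MET, 18.0, 0.0, 0.0, 0.5, view_to_sky=1.0)
        fx_shade = surface_fluxes(MET, 18.0, 1.0, 0.0, 0.5, view_to_sky=1.0)
        # diffuse fraction at C=0 is 0.3: shaded shortwave = diffuse only
        assert float(fx_shade.shortwave) == pytest.approx(
            0.95 * 0.3 * MET["solar_wm2"], rel=1e-12
        )
        assert float(fx_clear.shortwave) == pytest.approx(0.95 * MET["solar_wm2"], rel=1e-12)

    def test_more_cloud_does_not_increase_direct_beam(self):
        direct = []
        for c in (0.0, 0.4, 0.8):
            fx = surface_fluxes(dict(MET), 18.0, 0.5, c, 0.5, view_to_sky=0.0)
            direct.append(float(fx.shortwave))
        assert direct[0] >= direct[1] >= direct[2]

    def test_invalid_evaporation_params(self):
        with pytest.raises(ValueError):
            EvaporationParams(wind_offset_coeff=-1.0)

    def test_saturation_vapor_pressure_reference(self):
        # Magnus form at 20 degC ~ 23.4 hPa
        assert saturation_vapor_pressure(20.0) == pytest.approx(23.4, abs=0.2)


class TestBedFlux:
    def test_isothermal_no_flux(self):
        sub = SubstrateParams(deep_alluvium_temp=12.0)
        flux, ts_next = bed_flux(sub, 12.0, 12.0)
        assert float(flux) == 0.0
        assert float(ts_next) == pytest.approx(12.0)

    def test_warm_water_over_cool_bed(self):
        sub = SubstrateParams.physical_sediment()
        flux, ts_next = bed_flux(sub, 20.0, 14.0)
        assert float(flux) < 0.0  # heat leaves the water
        assert float(ts_next) > 14.0  # substrate warms

    def test_steady_state_two_resistor_closed_form(self):
        sub = SubstrateParams.physical_sediment()
        tw, ts = 20.0, 16.0
        for _ in range(20000):
            flux, ts = bed_flux(sub, tw, ts, dt=120.0)
        g = sub.conductance
        t_eq = (g * tw + g * sub.deep_alluvium_temp) / (2 * g)
        assert float(ts) == pytest.approx(t_eq, abs=1e-6)
        expected_flux = g * g * (sub.deep_alluvium_temp - tw) / (2 * g)
        assert float(flux) == pytest.approx(expected_flux, rel=1e-6)
        assert sub.deep_alluvium_temp < float(ts) < tw

    def test_hyporheic_term_increases_coupling(self):
        base = SubstrateParams.physical_sediment()
        hyp = SubstrateParams.physical_sediment(hyporheic_pct=0.05)
        f0, _ = bed_flux(base, 20.0, 14.0, discharge=16.0, width=80.0)
        f1, _ = bed_flux(hyp, 20.0, 14.0, discharge=16.0, width=80.0)
        assert float(f1) < float(f0) < 0.0

    def test_printed_pair_vs_physical_preset(self):
        printed = SubstrateParams()
        physical = SubstrateParams.physical_sediment()
        assert printed.thermal_conductivity == physical.thermal_diffusivity == 0.0064
        assert printed.thermal_diffusivity == physical.thermal_conductivity == 1.54

    def test_invariants(self):
        with pytest.raises(ValueError):
            SubstrateParams(layer_thickness=0.0)
        with pytest.raises(ValueError):
            SubstrateParams(hyporheic_pct=1.5)
        with pytest.raises(ValueError):
            SubstrateParams(porosity=0.0)


def _flow(n, depth=0.5, velocity=0.4, width=80.0):
    return FlowState(
        discharge=np.full(n, 16.0),
        depth=np.full(n, depth),
        velocity=np.full(n, velocity),
        width=np.full(n, width),
    )


class TestStepTemperature:
    def test_uniform_no_flux_is_conserved(self):
        temps = np.full(20, 17.5)
        out = temps
        for _ in range(500):
            out = step_temperature(out, np.zeros(20), _flow(20), 120.0, 500.0)
        assert np.max(np.abs(out - 17.5)) < 1e-9

    def test_constant_flux_exact_heating(self):
        # dT = phi * dt / (rho c d), no advection
        phi, dt, d = 200.0, 120.0, 0.5
        temps = np.full(5, 15.0)
        out = step_temperature(temps, np.full(5, phi), _flow(5, depth=d, velocity=0.0), dt, 500.0)
        expected = 15.0 + phi * dt / (heat.RHO_CP_WATER * d)
        assert out == pytest.approx(np.full(5, expected), rel=1e-12)

    def test_step_profile_advects_at_velocity(self):
        # method-of-characteristics oracle: front midpoint arrives at node j
        # after (j - j0) * dx / v seconds (upwind smears but preserves timing)
        n, dx, v, dt = 60, 100.0, 0.5, 50.0
        temps = np.where(np.arange(n) < 5, 20.0, 10.0)
        flow = _flow(n, velocity=v)
        target = 40
        crossing_step = None
        state = temps.copy()
        for k in range(1, 20000):
            state = step_temperature(state, np.zeros(n), flow, dt, dx)
            state[0] = 20.0
            if crossing_step is None and state[target] >= 15.0:
                crossing_step = k
                break
        assert crossing_step is not None
        arrival = crossing_step * dt
        expected = (target - 5 + 0.5) * dx / v
        assert arrival == pytest.approx(expected, rel=0.08)

    def test_cfl_violation_reports_node(self):
        flow = _flow(4, velocity=5.0)
        with pytest.raises(RuntimeError, match="CFL violation at node"):
            step_temperature(np.full(4, 15.0), np.zeros(4), flow, 120.0, 500.0)


@pytest.fixture(scope="module")
def twin_cfg():
    return synth.SyntheticConfig(
        seed=11, n_nodes=10, start_date="2019-06-10", end_date="2019-06-21", flush_days=2
    )


@pytest.fixture(scope="module")
def twin_dataset(twin_cfg):
    return synth.make_dataset(twin_cfg)


class TestRunModel:
    def test_output_window_excludes_flush(self, small_field, small_cfg):
        assert small_field.data.index.min() == pd.Timestamp(small_cfg.start_date)
        expected_hours = 12 * 24
        assert small_field.data.shape[0] == expected_hours

    def test_node_count_matches_reach(self, small_field, small_cfg):
        assert small_field.data.shape[1] == small_cfg.n_nodes

    def test_82_node_run_produces_82_series(self):
        cfg = synth.SyntheticConfig(
            seed=3, n_nodes=82, start_date="2019-06-10", end_date="2019-06-16", flush_days=2
        )
        ds = synth.make_dataset(cfg)
        field = synth.run_truth(ds, SubstrateParams.physical_sediment())
        assert field.data.shape[1] == 82

    def test_zero_flux_no_tribs_conserves_boundary(self, small_dataset, small_cfg):
        # constant boundary, surface fluxes disabled, no tributaries: the
        # whole reach relaxes to the boundary value exactly
        boundary = small_dataset.boundary.copy()
        boundary["temp_c"] = 17.0
        cfg = ModelConfig(flush_days=small_cfg.flush_days, disable_surface_fluxes=True)
        field = run_model(
            small_dataset.reach, small_dataset.met, boundary, [],
            small_dataset.shade, SubstrateParams(), small_cfg.dates, config=cfg,
        )
        assert np.max(np.abs(field.data.to_numpy() - 17.0)) < 1e-6

    def test_missing_forcing_rejected(self, small_dataset, small_cfg):
        met = small_dataset.met.drop(small_dataset.met.index[30:40])  # 10 h gap
        with pytest.raises(ValueError, match="missing forcing"):
            run_model(
                small_dataset.reach, met, small_dataset.boundary,
                small_dataset.tributaries, small_dataset.shade,
                SubstrateParams(), small_cfg.dates,
                config=ModelConfig(flush_days=small_cfg.flush_days),
            )

    def test_dt_halving_convergence(self, twin_dataset, twin_cfg):
        sub = SubstrateParams.physical_sediment()
        fields = {}
        for dt in (120.0, 60.0):
            cfg = ModelConfig(
                flush_days=twin_cfg.flush_days, dt_seconds=dt,
                latitude=twin_cfg.latitude, longitude=twin_cfg.longitude,
                utc_offset=twin_cfg.utc_offset,
            )
            fields[dt] = run_model(
                twin_dataset.reach, twin_dataset.met, twin_dataset.boundary,
                twin_dataset.tributaries, twin_dataset.shade, sub, twin_cfg.dates,
                config=cfg, view_to_sky=twin_dataset.view_to_sky,
            )
        diff = np.abs(fields[120.0].data.to_numpy() - fields[60.0].data.to_numpy())
        assert diff.max() < 0.01

    def test_warmer_air_never_cools_water(self, twin_dataset, twin_cfg):
        sub = SubstrateParams.physical_sediment()
        cfg = ModelConfig(
            flush_days=twin_cfg.flush_days, latitude=twin_cfg.latitude,
            longitude=twin_cfg.longitude, utc_offset=twin_cfg.utc_offset,
        )
        base = run_model(
            twin_dataset.reach, twin_dataset.met, twin_dataset.boundary,
            twin_dataset.tributaries, twin_dataset.shade, sub, twin_cfg.dates,
            config=cfg, view_to_sky=twin_dataset.view_to_sky,
        )
        met_warm = twin_dataset.met.copy()
        met_warm["air_c"] += 2.0
        warm = run_model(
            twin_dataset.reach, met_warm, twin_dataset.boundary,
            twin_dataset.tributaries, twin_dataset.shade, sub, twin_cfg.dates,
            config=cfg, view_to_sky=twin_dataset.view_to_sky,
        )
        assert (warm.data.to_numpy() >= base.data.to_numpy() - 1e-9).all()

    def test_vegetation_removal_raises_daily_maxima(self, twin_dataset, twin_cfg):
        sub = SubstrateParams.physical_sediment()
        cfg = ModelConfig(
            flush_days=twin_cfg.flush_days, latitude=twin_cfg.latitude,
            longitude=twin_cfg.longitude, utc_offset=twin_cfg.utc_offset,
        )
        hours = twin_cfg.hourly_index()
        results = {}
        for mode in ("current", "loss"):
            lc = scenarios.modify_vegetation(twin_dataset.landcover, mode)
            shade, vts = solar.build_shade_series(
                twin_dataset.reach, lc, hours, twin_cfg.latitude, twin_cfg.longitude,
                twin_cfg.utc_offset,
            )
            results[mode] = run_model(
                twin_dataset.reach, twin_dataset.met, twin_dataset.boundary,
                twin_dataset.tributaries, shade, sub, twin_cfg.dates,
                config=cfg, view_to_sky=vts,
            )
        dmax_current = results["current"].daily_max().to_numpy()
        dmax_loss = results["loss"].daily_max().to_numpy()
        assert (dmax_loss >= dmax_current - 1e-9).all()


@pytest.fixture(scope="module")
def twin_runs(twin_dataset):
    candidates = default_candidates(SubstrateParams.physical_sediment())
    fields = {i: synth.run_truth(twin_dataset, c) for i, c in enumerate(candidates)}
    return candidates, fields


class TestCalibrate:
    def test_zero_noise_recovers_truth(self, twin_runs, twin_cfg, twin_dataset):
        candidates, fields = twin_runs
        truth_idx = 5  # thickness 0.5, hyporheic 0.02
        stations = synth.station_nodes(twin_cfg)
        obs = fields[truth_idx].data[stations]
        result = heat.calibrate(candidates, obs, lambda c: fields[candidates.index(c)])
        assert result.selected_index == truth_idx

    def test_duplicate_candidates_first_listed_wins(self, twin_runs, twin_cfg):
        candidates, fields = twin_runs
        dup = [candidates[0], candidates[0], candidates[3]]
        stations = synth.station_nodes(twin_cfg)
        obs = fields[0].data[stations]
        mapping = {id(dup[0]): fields[0], id(dup[2]): fields[3]}
        result = heat.calibrate(dup, obs, lambda c: mapping[id(c)])
        assert result.selected_index == 0

    def test_noisy_daily_rmse_near_noise_floor(self, twin_runs, twin_cfg):
        candidates, fields = twin_runs
        truth_idx = 0
        stations = synth.station_nodes(twin_cfg)
        rng = np.random.default_rng(99)
        clean = fields[truth_idx].data[stations]
        obs = clean + rng.normal(0.0, 0.1, clean.shape)
        result = heat.calibrate(candidates, obs, lambda c: fields[candidates.index(c)])
        # daily means average 24 hourly draws: residual ~ 0.1/sqrt(24)
        daily_rmse = result.stage2.loc[result.selected_index, "rmse_c"]
        assert daily_rmse < 0.1 / np.sqrt(24) + 0.02

    def test_misaligned_observations_rejected(self, twin_runs, twin_cfg):
        candidates, fields = twin_runs
        stations = synth.station_nodes(twin_cfg)
        obs = fields[0].data[stations].copy()
        obs.index = obs.index + pd.Timedelta(minutes=7)
        with pytest.raises(ValueError, match="aligned"):
            heat.calibrate(candidates, obs, lambda c: fields[candidates.index(c)])

    def test_two_candidates_minimum(self, twin_runs, twin_cfg):
        candidates, fields = twin_runs
        stations = synth.station_nodes(twin_cfg)
        obs = fields[0].data[stations]
        with pytest.raises(ValueError, match="2 candidates"):
            heat.calibrate([candidates[0]], obs, lambda c: fields[0])

    def test_validation_report_shares_format(self, twin_runs, twin_cfg):
        # a second-period run with frozen parameters emits the same
        # fit-metric report structure
        candidates, fields = twin_runs
        stations = synth.station_nodes(twin_cfg)
        obs = fields[2].data[stations]
        report = heat.station_fit_report(fields[2], obs)
        for station, entry in report.items():
            assert set(entry) == {"hourly", "daily"}
            for res in entry.values():
                assert set(res) == {"bias_c", "rmse_c", "nse"}
            assert entry["hourly"]["rmse_c"] == pytest.approx(0.0, abs=1e-12)
            assert entry["hourly"]["nse"] == pytest.approx(1.0)
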