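import numpy as np
import pytest
import xarray as xr
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from pahfire.emissions import SECTORS, inventory_from_values
from pahfire.fate_boxmodel import (
    PHASES,
    ConcentrationState,
    FateConfig,
    GridMismatchError,
    PplferSystem,
    diagnose_degradation_products,
    heterogeneous_loss_rate,
    make_environment,
    partition_coefficient,
    particulate_fraction,
    pyrene_product_ratios,
    run_scenario,
    state_from_arrays,
    step_cell,
    surface_burden,
    zero_state,
)
from pahfire.gridutil import SECONDS_IN_MONTH, cell_area_m2, regular_grid


def f1(da):
    """Scalar value of a size-1 selection."""
    return float(np.asarray(da).reshape(()))


def one_cell_env(
    temperature=288.0, oc=5.0, bc=1.0, oh=1e6, o3=30.0, no3=2.5e8,
    k_dep_gas=1e-6, k_dep_particle=1e-5, mixing_height=1000.0,
):
    lat, lon = np.array([0.0]), np.array([0.0])
    shape = (12, 1, 1)
    monthly = {
        "temperature": np.full(shape, temperature),
        "oc": np.full(shape, oc),
        "bc": np.full(shape, bc),
        "oh": np.full(shape, oh),
        "o3": np.full(shape, o3),
        "no3": np.full(shape, no3),
    }
    return make_environment(
        lat, lon, monthly,
        mixing_height=mixing_height, k_dep_gas=k_dep_gas, k_dep_particle=k_dep_particle,
    )


def one_cell_inventory(species, kg_per_month):
    values = np.zeros((len(SECTORS), len(species), 12, 1, 1))
    for i, kg in enumerate(kg_per_month):
        values[SECTORS.index("fires"), i, :, 0, 0] = kg
    return inventory_from_values(values, species, np.array([0.0]), np.array([0.0]))


class TestPartitionCoefficient:
    def test_zero_descriptors_give_intercept(self, registry):
        species = registry["NAP"]
        zeroed = type(species)(
            **{**species.__dict__, "pplfer": (0.0,) * 5}
        )
        system = PplferSystem(intercept=-3.0, temperature_slope=2.0)
        assert partition_coefficient(zeroed, 298.15, system) == pytest.approx(
            10.0**-3.0, rel=1e-12
        )

    def test_strictly_decreasing_in_temperature(self, registry):
        for species in registry.parents:
            assert partition_coefficient(species, 270.0) > partition_coefficient(
                species, 300.0
            )

    def test_hand_evaluation_at_298K(self, registry):
        species = registry["BAP"]
        system = PplferSystem()
        # independent hand evaluation of the documented linear form
        log_kp = system.intercept + sum(
            c * d for c, d in zip(system.coefficients, species.pplfer)
        )
        assert partition_coefficient(species, 298.15, system) == pytest.approx(
            10.0**log_kp, rel=1e-12
        )

    def test_out_of_range_temperature(self, registry):
        with pytest.raises(ValueError, match="temperature"):
            partition_coefficient(registry["NAP"], 100.0)

    def test_nonpositive_temperature_slope_rejected(self):
        with pytest.raises(ValueError, match="temperature_slope"):
            PplferSystem(temperature_slope=0.0)


class TestParticulateFraction:
    def test_zero_pm_gives_zero(self):
        assert particulate_fraction(0.1, 0.0) == 0.0

    def test_kp_cpm_one_gives_half(self):
        assert particulate_fraction(0.1, 10.0) == pytest.approx(0.5, abs=1e-15)

    def test_closed_form_one_third(self):
        assert particulate_fraction(0.01, 50.0) == pytest.approx(1.0 / 3.0, rel=1e-15)

    def test_strictly_increasing_in_pm(self):
        pm = np.linspace(0.0, 100.0, 50)
        phi = particulate_fraction(0.05, pm)
        assert (np.diff(phi) > 0).all()
        assert particulate_fraction(1e9, 1e9) == pytest.approx(1.0, abs=1e-12)

    @given(
        kp=st.floats(min_value=0.0, max_value=1e3, allow_nan=False),
        c_pm=st.floats(min_value=0.0, max_value=1e3, allow_nan=False),
    )
    def test_bounded_unit_interval(self, kp, c_pm):
        phi = particulate_fraction(kp, c_pm)
        assert 0.0 <= phi <= 1.0


class TestStepCell:
    def _single_state(self, species, gas, oc=0.0, bc=0.0):
        conc = np.zeros((len(species), 3, 1, 1))
        conc[:, 0, 0, 0] = gas
        conc[:, 1, 0, 0] = oc
        conc[:, 2, 0, 0] = bc
        zeros = np.zeros((len(species), 1, 1))
        return state_from_arrays(conc, zeros, zeros, species, [0.0], [0.0])

    def test_inert_state_unchanged(self, registry):
        env = one_cell_env(oc=0.0, bc=0.0, oh=0.0, o3=0.0, no3=0.0, k_dep_gas=0.0, k_dep_particle=0.0)
        state = self._single_state(["PYR"], gas=3.0)
        rate = xr.zeros_like(state.total())
        out = step_cell(state, env, rate, 3600.0, registry)
        assert f1(out.gas().sel(species="PYR")) == pytest.approx(3.0, rel=1e-12)

    def test_negative_concentration_rejected(self, registry):
        state = self._single_state(["PYR"], gas=1.0)
        state.ds["conc"].values[0, 0, 0, 0] = -1.0
        env = one_cell_env()
        rate = xr.zeros_like(state.total())
        with pytest.raises(ValueError, match="negative"):
            step_cell(state, env, rate, 3600.0, registry)

    def test_nonpositive_dt_rejected(self, registry):
        state = self._single_state(["PYR"], gas=1.0)
        env = one_cell_env()
        rate = xr.zeros_like(state.total())
        with pytest.raises(ValueError, match="dt"):
            step_cell(state, env, rate, 0.0, registry)

    def test_single_step_matches_ode_oracle(self, registry):
        """The kinetic part of one step must agree with a stiff-safe numerical
        integration of the same per-phase linear ODE to 1e-6 relative."""
        species = registry["PYR"]
        env = one_cell_env()
        gas0, oc0, bc0, e_rate, dt = 2.0, 0.5, 0.2, 1e-4, 3600.0

        # independent oracle: rates recomputed by hand, ODE solved numerically
        k_g = species.k_oh * 1e6 + species.k_no3 * 2.5e8 + 1e-6
        cfg = FateConfig()
        k_p = species.gamma_o3 * cfg.k_het_per_ppb * 30.0 + 1e-5
        sol = solve_ivp(
            lambda t, y: [e_rate - k_g * y[0], -k_p * y[1], -k_p * y[2]],
            (0.0, dt), [gas0, oc0, bc0], method="LSODA", rtol=1e-12, atol=1e-18,
        )
        gas_k, oc_k, bc_k = sol.y[:, -1]
        total = gas_k + oc_k + bc_k
        kp_eq = partition_coefficient(species, 288.0, cfg.pplfer)
        phi = kp_eq * 6.0 / (1.0 + kp_eq * 6.0)
        expected_gas = (1.0 - phi) * total
        expected_oc = phi * (5.0 / 6.0) * total
        expected_bc = phi * (1.0 / 6.0) * total

        state = self._single_state(["PYR"], gas=gas0, oc=oc0, bc=bc0)
        rate = xr.full_like(state.total(), e_rate)
        out = step_cell(state, env, rate, dt, registry)
        assert f1(out.gas().sel(species="PYR")) == pytest.approx(expected_gas, rel=1e-6)
        assert f1(out.conc.sel(species="PYR", phase="particle_oc")) == pytest.approx(
            expected_oc, rel=1e-6
        )
        assert f1(out.conc.sel(species="PYR", phase="particle_bc")) == pytest.approx(
            expected_bc, rel=1e-6
        )

    def test_steady_state_reaches_e_over_k(self, registry):
        """Constant emission against first-order loss settles at E/k."""
        k = 1e-4
        env = one_cell_env(oc=0.0, bc=0.0, oh=0.0, o3=0.0, no3=0.0, k_dep_gas=k, k_dep_particle=0.0)
        e_rate = 2.0e-3
        state = self._single_state(["PYR"], gas=0.0)
        rate = xr.full_like(state.total(), e_rate)
        for _ in range(100):  # 100 h >> 1/k = 2.8 h
            state = step_cell(state, env, rate, 3600.0, registry)
        assert f1(state.gas().sel(species="PYR")) == pytest.approx(e_rate / k, rel=1e-3)


class TestDegradationDiagnosis:
    def test_zero_ratios_zero_products(self, registry):
        state = zero_state(["PYR"], [0.0], [0.0])
        state.ds["conc"].values[:] = 1.0
        out = diagnose_degradation_products(state, 0.0, 0.0)
        assert float(out.npah.sum()) == 0.0
        assert float(out.dnpah.sum()) == 0.0

    def test_simple_multiplication(self, registry):
        state = zero_state(["PYR"], [0.0], [0.0])
        state.ds["conc"].values[0, 0] = 10.0  # 10 ng/m3 in gas phase
        out = diagnose_degradation_products(state, 0.04, 0.01)
        assert f1(out.npah.sel(species="PYR")) == pytest.approx(0.4, rel=1e-12)
        assert f1(out.dnpah.sel(species="PYR")) == pytest.approx(0.1, rel=1e-12)

    def test_negative_ratio_rejected(self):
        state = zero_state(["PYR"], [0.0], [0.0])
        with pytest.raises(ValueError):
            diagnose_degradation_products(state, -0.1, 0.0)

    def test_doubled_no3_raises_product_share(self, registry):
        r_n1, r_dn1 = pyrene_product_ratios(1e6, 2.5e8, registry)
        r_n2, r_dn2 = pyrene_product_ratios(1e6, 5.0e8, registry)
        assert r_n2 > r_n1
        assert r_dn2 > r_dn1

    def test_heterogeneous_rate_linear_in_o3(self):
        assert heterogeneous_loss_rate(1e-3, 30.0) == pytest.approx(
            2.0 * heterogeneous_loss_rate(1e-3, 15.0), rel=1e-12
        )


def scalar_scenario_oracle(registry, species_name, kg_per_month, env_params, config):
    """Standalone scalar reimplementation of the per-cell scheme, with plain
    Python floats and explicit loops."""
    import math

    species = registry[species_name]
    area = float(cell_area_m2(np.array([0.0]), np.array([0.0])).values[0, 0])
    volume = area * env_params["mixing_height"]
    system = config.pplfer
    log_kp = (
        system.intercept
        + sum(c * d for c, d in zip(system.coefficients, species.pplfer))
        + system.temperature_slope * (1000.0 / env_params["temperature"] - 1000.0 / 298.15)
    )
    kp = 10.0**log_kp
    c_pm = env_params["oc"] + env_params["bc"]
    phi = kp * c_pm / (1.0 + kp * c_pm)
    w_oc = env_params["oc"] / c_pm if c_pm > 0 else 0.5
    k_g = (
        species.k_oh * env_params["oh"]
        + species.k_no3 * env_params["no3"]
        + env_params["k_dep_gas"]
    )
    k_p = (
        species.gamma_o3 * config.k_het_per_ppb * env_params["o3"]
        + env_params["k_dep_particle"]
    )

    months = [11, 12] + list(range(1, 13))
    gas = p_oc = p_bc = 0.0
    acc = 0.0
    total_seconds = 0.0
    for idx, m in enumerate(months):
        analysis = idx >= config.spinup_months
        seconds = float(SECONDS_IN_MONTH[m - 1])
        nsteps = max(1, int(round(seconds / config.dt_seconds)))
        dt = seconds / nsteps
        e_rate = kg_per_month * 1e12 / volume / seconds
        for _ in range(nsteps):
            gas = gas * math.exp(-k_g * dt) + e_rate * (1.0 - math.exp(-k_g * dt)) / k_g
            p_oc = p_oc * math.exp(-k_p * dt)
            p_bc = p_bc * math.exp(-k_p * dt)
            total = gas + p_oc + p_bc
            gas = (1.0 - phi) * total
            p_oc = phi * w_oc * total
            p_bc = phi * (1.0 - w_oc) * total
            if analysis:
                acc += (gas + p_oc + p_bc) * dt
        if analysis:
            total_seconds += seconds
    return acc / total_seconds


class TestRunScenario:
    def test_zero_inventory_gives_zero_state(self, registry, uniform_environment, parent_names, small_grid):
        lat, lon = small_grid
        values = np.zeros((len(SECTORS), len(parent_names), 12, len(lat), len(lon)))
        inv = inventory_from_values(values, parent_names, lat, lon)
        state = run_scenario(inv, uniform_environment, registry)
        assert float(np.abs(state.conc.values).max()) == 0.0
        assert float(np.abs(state.npah.values).max()) == 0.0

    def test_uniform_world_gives_uniform_output(self, registry, parent_names):
        lat, lon = regular_grid(4, 8)
        values = np.full((len(SECTORS), len(parent_names), 12, 4, 8), 1.0)
        inv = inventory_from_values(values, parent_names, lat, lon)
        shape = (12, 4, 8)
        env = make_environment(
            lat, lon,
            {
                "temperature": np.full(shape, 288.0),
                "oc": np.full(shape, 5.0),
                "bc": np.full(shape, 1.0),
                "oh": np.full(shape, 1e6),
                "o3": np.full(shape, 30.0),
                "no3": np.full(shape, 2.5e8),
            },
        )
        state = run_scenario(inv, env, registry)
        total = state.total().sel(species="PHEN").values
        # same latitude band -> identical cells (area varies only with lat)
        for row in total:
            np.testing.assert_allclose(row, row[0], rtol=1e-12)

    def test_one_cell_matches_scalar_oracle(self, registry):
        env_params = dict(
            temperature=288.0, oc=5.0, bc=1.0, oh=1e6, o3=30.0, no3=2.5e8,
            k_dep_gas=1e-6, k_dep_particle=1e-5, mixing_height=1000.0,
        )
        env = one_cell_env(**env_params)
        config = FateConfig()
        kg_per_month = 50.0
        inv = one_cell_inventory(["PYR"], [kg_per_month])
        state = run_scenario(inv, env, registry, config)
        expected = scalar_scenario_oracle(registry, "PYR", kg_per_month, env_params, config)
        assert f1(state.total().sel(species="PYR")) == pytest.approx(expected, rel=1e-9)

    def test_grid_mismatch_rejected(self, registry, parent_names, uniform_environment):
        lat, lon = regular_grid(6, 6)
        values = np.zeros((len(SECTORS), len(parent_names), 12, 6, 6))
        inv = inventory_from_values(values, parent_names, lat, lon)
        with pytest.raises(GridMismatchError):
            run_scenario(inv, uniform_environment, registry)

    def test_superposition(self, registry, uniform_environment, parent_names, small_grid):
        lat, lon = small_grid
        rng = np.random.default_rng(3)
        shape = (len(SECTORS), len(parent_names), 12, len(lat), len(lon))
        inv_a = inventory_from_values(rng.uniform(0, 2, shape), parent_names, lat, lon)
        inv_b = inventory_from_values(rng.uniform(0, 2, shape), parent_names, lat, lon)
        inv_ab = inventory_from_values(
            inv_a.data.values + inv_b.data.values, parent_names, lat, lon
        )
        sa = run_scenario(inv_a, uniform_environment, registry)
        sb = run_scenario(inv_b, uniform_environment, registry)
        sab = run_scenario(inv_ab, uniform_environment, registry)
        np.testing.assert_allclose(
            sab.conc.values, sa.conc.values + sb.conc.values, rtol=1e-9, atol=1e-18
        )

    def test_more_pm_raises_particulate_fraction(self, registry):
        inv = one_cell_inventory(["BAP"], [10.0])
        low = run_scenario(inv, one_cell_env(oc=2.0, bc=0.5), registry)
        high = run_scenario(inv, one_cell_env(oc=40.0, bc=10.0), registry)

        def pfrac(state):
            return float(state.particle().sum() / state.total().sum())

        assert pfrac(high) > pfrac(low)

    def test_more_oxidant_lowers_parent_raises_product_ratio(self, registry):
        inv = one_cell_inventory(["PYR"], [10.0])
        base = run_scenario(inv, one_cell_env(no3=2.5e8), registry)
        rich = run_scenario(inv, one_cell_env(no3=2.5e9), registry)
        assert f1(rich.total().sel(species="PYR")) < f1(base.total().sel(species="PYR"))
        ratio_base = f1(base.npah.sel(species="PYR")) / f1(base.total().sel(species="PYR"))
        ratio_rich = f1(rich.npah.sel(species="PYR")) / f1(rich.total().sel(species="PYR"))
        assert ratio_rich > ratio_base

    def test_mass_sanity_zero_losses(self, registry):
        """With no losses the gas phase accumulates emissions linearly; the
        annual mean equals the analytic accumulation over the schedule."""
        env = one_cell_env(oc=0.0, bc=0.0, oh=0.0, o3=0.0, no3=0.0, k_dep_gas=0.0, k_dep_particle=0.0)
        config = FateConfig()
        kg = 10.0
        inv = one_cell_inventory(["PYR"], [kg])
        state = run_scenario(inv, env, registry, config)

        area = float(cell_area_m2(np.array([0.0]), np.array([0.0])).values[0, 0])
        volume = area * 1000.0
        months = [11, 12] + list(range(1, 13))
        conc = 0.0
        acc = 0.0
        total_seconds = 0.0
        for idx, m in enumerate(months):
            seconds = float(SECONDS_IN_MONTH[m - 1])
            nsteps = max(1, int(round(seconds / config.dt_seconds)))
            dt = seconds / nsteps
            e_rate = kg * 1e12 / volume / seconds
            for _ in range(nsteps):
                conc += e_rate * dt
                if idx >= config.spinup_months:
                    acc += conc * dt
            if idx >= config.spinup_months:
                total_seconds += seconds
        assert f1(state.total().sel(species="PYR")) == pytest.approx(
            acc / total_seconds, rel=1e-9
        )


class TestSurfaceBurden:
    def test_zero_state_zero_burden(self, registry):
        state = zero_state(["PYR", "BAP"], [0.0], [0.0])
        burdens = surface_burden(state)
        assert burdens == {"PYR": 0.0, "BAP": 0.0}

    def test_unit_arithmetic(self):
        state = zero_state(["PYR"], [0.0], [0.0])
        state.ds["conc"].values[0, 0, 0, 0] = 1.0  # 1 ng/m3
        areas = xr.DataArray(
            [[1.0e6]], coords={"lat": [0.0], "lon": [0.0]}, dims=("lat", "lon")
        )
        burdens = surface_burden(state, cell_areas=areas, mixing_height=1000.0)
        assert burdens["PYR"] == pytest.approx(1.0e-3, rel=1e-12)

    def test_matches_brute_force_loop(self, registry, small_grid):
        lat, lon = small_grid
        rng = np.random.default_rng(5)
        species = ["PYR", "BAP"]
        conc = rng.uniform(0, 2, (2, 3, len(lat), len(lon)))
        zeros = np.zeros((2, len(lat), len(lon)))
        state = state_from_arrays(conc, zeros, zeros, species, lat, lon)
        areas = cell_area_m2(lat, lon)
        burdens = surface_burden(state, cell_areas=areas, mixing_height=500.0)
        for isp, sp in enumerate(species):
            expected = 0.0
            for i in range(len(lat)):
                for j in range(len(lon)):
                    total = conc[isp, :, i, j].sum()
                    expected += total * float(areas.values[i, j]) * 500.0
            expected *= 1e-12
            assert burdens[sp] == pytest.approx(expected, rel=1e-9)

    def test_nonpositive_geometry_rejected(self):
        state = zero_state(["PYR"], [0.0], [0.0])
        with pytest.raises(ValueError):
            surface_burden(state, mixing_height=0.0)


class TestStateIO:
    def test_netcdf_roundtrip(self, tmp_path, small_grid):
        lat, lon = small_grid
        rng = np.random.default_rng(11)
        species = ["PYR", "BAP"]
        state = state_from_arrays(
            rng.uniform(0, 1, (2, 3, len(lat), len(lon))),
            rng.uniform(0, 0.1, (2, len(lat), len(lon))),
            rng.uniform(0, 0.1, (2, len(lat), len(lon))),
            species, lat, lon, period="annual-mean",
        )
        path = tmp_path / "state.nc"
        state.to_netcdf(path, seed=7)
        back = ConcentrationState.from_netcdf(path)
        np.testing.assert_array_equal(back.conc.values, state.conc.values)
        assert back.period == "annual-mean"
        assert list(back.conc.phase.values) == list(PHASES)
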