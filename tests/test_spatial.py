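"""Tests of the reaction-diffusion engine: stencils, conservation, limits."""

import numpy as np
import pytest

from dropdiv.kinetics import (
    CircuitParams,
    KineticParams,
    SpeciesSet,
    init_circuit,
    simulate_well_mixed,
)
from dropdiv.spatial import (
    DiffusionMap,
    GridSpec,
    RDConfig,
    StabilityError,
    laplacian,
    radial_profile,
    simulate_rd,
    step_rd,
    uniform_fields,
)


@pytest.fixture
def small_grid():
    return GridSpec(nx=24, ny=24, spacing=2.0, droplet_radius=14.0)


@pytest.fixture
def params():
    return KineticParams(circuits={"AB": CircuitParams()}, k_cat=2e-3, k_h_rna=0.5)


def brute_force_laplacian(f, h):
    """Reference loop implementation with reflected neighbors."""
    ny, nx = f.shape
    out = np.zeros_like(f)
    for i in range(ny):
        for j in range(nx):
            up = f[i - 1, j] if i > 0 else f[i, j]
            dn = f[i + 1, j] if i < ny - 1 else f[i, j]
            lf = f[i, j - 1] if j > 0 else f[i, j]
            rt = f[i, j + 1] if j < nx - 1 else f[i, j]
            out[i, j] = (up + dn + lf + rt - 4 * f[i, j]) / h**2
    return out


class TestLaplacian:
    def test_uniform_field_is_flat(self, small_grid):
        f = np.full((24, 24), 3.7)
        np.testing.assert_allclose(laplacian(f, small_grid), 0.0, atol=1e-14)

    def test_spike_stencil_identity(self, small_grid):
        f = np.zeros((24, 24))
        f[10, 12] = 1.0
        lap = laplacian(f, small_grid)
        h2 = small_grid.spacing**2
        assert lap[10, 12] == pytest.approx(-4.0 / h2)
        for i, j in [(9, 12), (11, 12), (10, 11), (10, 13)]:
            assert lap[i, j] == pytest.approx(1.0 / h2)
        assert abs(lap.sum()) < 1e-12

    def test_matches_brute_force_on_random_field(self, small_grid):
        f = np.random.default_rng(3).random((24, 24))
        np.testing.assert_allclose(
            laplacian(f, small_grid),
            brute_force_laplacian(f, small_grid.spacing),
            rtol=1e-12,
            atol=1e-12,
        )

    def test_shape_mismatch_rejected(self, small_grid):
        with pytest.raises(ValueError):
            laplacian(np.zeros((10, 10)), small_grid)


class TestStepping:
    def test_zero_state_is_fixed_point(self, small_grid, params):
        dmap = DiffusionMap()
        state = uniform_fields(
            small_grid, {"AB": 0.0}, {"AB": (0.0, 0.0, 0.0)}, enzyme=0.25
        )
        out = step_rd(state, 0.01, small_grid, dmap, params)
        for sp, arr in out.circuits["AB"].items():
            np.testing.assert_allclose(arr, 0.0)

    def test_unstable_dt_rejected_with_advice(self, small_grid, params):
        dmap = DiffusionMap()
        state = uniform_fields(
            small_grid, {"AB": 0.2}, {"AB": (1.0, 0.0, 0.0)}, enzyme=0.0
        )
        with pytest.raises(StabilityError, match="stability bound"):
            step_rd(state, 1e3, small_grid, dmap, params)

    def test_pure_diffusion_conserves_mass(self, small_grid):
        """Non-reacting mobile species under no-flux walls keep their total
        to ~1e-10 relative, explicit stepping."""
        inert = KineticParams(
            circuits={"AB": CircuitParams(k_on=0.0, k_d=0.0)},
            k_cat=0.0,
            k_h_rna=0.0,
        )
        dmap = DiffusionMap()
        state = uniform_fields(
            small_grid, {"AB": 0.2}, {"AB": (1.0, 0.0, 0.0)}, enzyme=0.0
        )
        m0 = state.circuits["AB"]["T"][0].sum()
        dt = 0.2 * small_grid.spacing**2 / (4 * dmap.d_max)
        for _ in range(60):
            state = step_rd(state, dt, small_grid, dmap, inert)
        m1 = state.circuits["AB"]["T"][0].sum()
        assert abs(m1 / m0 - 1) < 1e-10

    def test_reaction_only_matches_per_cell_ode(self, small_grid, params):
        """With D = 0 everywhere, every cell follows the well-mixed ODE."""
        dmap = DiffusionMap(0.0, 0.0, 0.0, 0.0)
        cfg = RDConfig(
            grid=small_grid,
            dmap=dmap,
            params=params,
            linker_doses={"AB": 0.2},
            trigger_doses={"AB": (1.0, 0.0, 0.5)},
            enzyme=0.25,
            t_end=400.0,
            dt=0.2,
            trace_interval=50.0,
            triggers_outside=False,
        )
        res = simulate_rd(cfg)
        init = SpeciesSet(
            {"AB": init_circuit(0.2, 1.0, 0.0, free_trigger_extra=0.5)}, enzyme=0.25
        )
        t = res.traces["time"].to_numpy()
        w_ode = simulate_well_mixed(init, params, t, rtol=1e-10).uncleaved_fraction(
            "AB"
        )
        np.testing.assert_allclose(
            res.traces["w_AB"].to_numpy(), w_ode, atol=2e-3
        )

    def test_high_diffusion_limit_matches_well_mixed(self, small_grid, params):
        """Very fast diffusion homogenizes the domain: droplet means track
        the ODE with domain-averaged initial concentrations within 1%."""
        frac = small_grid.mask.mean()
        dmap = DiffusionMap(500.0, 500.0, 500.0, 500.0)
        cfg = RDConfig(
            grid=small_grid,
            dmap=dmap,
            params=params,
            linker_doses={"AB": 0.2},
            trigger_doses={"AB": (1.0, 1.2, 0.0)},
            enzyme=0.25,
            t_end=2500.0,
            dt=1.0,
            trace_interval=100.0,
            triggers_outside=False,
        )
        res = simulate_rd(cfg)
        init = SpeciesSet({"AB": init_circuit(0.2 * frac, 1.0, 1.2)}, enzyme=0.25)
        t = res.traces["time"].to_numpy()
        w_ode = simulate_well_mixed(init, params, t, rtol=1e-8).uncleaved_fraction(
            "AB"
        )
        w_rd = res.traces["w_AB"].to_numpy()
        assert np.abs(w_rd - w_ode).max() < 0.01

    def test_imex_agrees_with_explicit(self, small_grid, params):
        dmap = DiffusionMap()
        kwargs = dict(
            grid=small_grid,
            dmap=dmap,
            params=params,
            linker_doses={"AB": 0.2},
            trigger_doses={"AB": (0.0, 0.0, 1.0)},
            enzyme=0.0,
            t_end=60.0,
            trace_interval=10.0,
        )
        dt = 0.5 * small_grid.spacing**2 / (4 * dmap.d_max)
        exp = simulate_rd(
            RDConfig(dt=dt, engine="explicit", **kwargs)
        ).traces["w_AB"]
        imx = simulate_rd(RDConfig(dt=dt, engine="imex", **kwargs)).traces["w_AB"]
        np.testing.assert_allclose(exp, imx, atol=5e-3)


class TestRadialProfile:
    def test_uniform_field_flat(self, small_grid):
        prof = radial_profile(np.full((24, 24), 2.5), small_grid, n_bins=5)
        filled = prof.dropna(subset=["mean"])
        np.testing.assert_allclose(filled["mean"], 2.5)

    def test_recovers_linear_slope(self):
        grid = GridSpec(nx=64, ny=64, spacing=1.0, droplet_radius=28.0)
        field = 1.0 + 0.1 * grid.radius_map
        prof = radial_profile(field, grid, n_bins=8).dropna(subset=["mean"])
        slope = np.polyfit(prof["r_mid"], prof["mean"], 1)[0]
        assert slope == pytest.approx(0.1, rel=0.05)

    def test_weighted_annulus_means_equal_droplet_mean(self, small_grid):
        f = np.random.default_rng(1).random((24, 24))
        prof = radial_profile(f, small_grid, n_bins=6).dropna(subset=["mean"])
        weighted = (prof["mean"] * prof["n_cells"]).sum() / prof["n_cells"].sum()
        assert weighted == pytest.approx(f[small_grid.mask].mean(), rel=1e-12)

    def test_empty_annulus_reported_missing(self):
        grid = GridSpec(nx=24, ny=24, spacing=2.0, droplet_radius=14.0)
        prof = radial_profile(np.ones((24, 24)), grid, n_bins=40)
        assert prof["mean"].isna().any()
        assert (prof.loc[prof["mean"].isna(), "n_cells"] == 0).all()


class TestGridValidation:
    def test_droplet_must_fit_inside_domain(self):
        with pytest.raises(ValueError, match="inside the domain"):
            GridSpec(nx=16, ny=16, spacing=1.0, droplet_radius=10.0)
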