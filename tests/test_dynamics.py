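"""Derived dynamics: projection, turnover, rates, stable states, grids."""

import numpy as np
import pytest

from dynocc.dynamics import (decline_proportion, mask_grid, project_psi,
                             rate_of_change, stable_state, turnover)


class TestProjection:
    def test_one_step_arithmetic(self):
        psi = project_psi(0.5, [0.2], [0.3])
        assert psi[-1] == pytest.approx(0.45)

    def test_frozen_dynamics_constant_trajectory(self):
        psi = project_psi(0.37, [0.0] * 5, [0.0] * 5)
        np.testing.assert_allclose(psi, 0.37, atol=1e-15)

    def test_equilibrium_start_is_fixed_point(self):
        g, e = 0.25, 0.4
        eq = g / (g + e)
        psi = project_psi(eq, [g] * 6, [e] * 6)
        np.testing.assert_allclose(psi, eq, atol=1e-12)

    def test_convergence_toward_equilibrium(self):
        g, e = 0.3, 0.2
        eq = g / (g + e)
        psi = project_psi(0.05, [g] * 30, [e] * 30)
        gaps = np.abs(psi - eq)
        assert np.all(np.diff(gaps) <= 1e-15)
        assert gaps[-1] < 1e-6

    def test_broadcasts_over_draws_and_cells(self):
        rng = np.random.default_rng(0)
        psi1 = rng.uniform(0.1, 0.9, (5, 7))
        g = rng.uniform(0.1, 0.9, (5, 7, 3))
        e = rng.uniform(0.1, 0.9, (5, 7, 3))
        psi = project_psi(psi1, g, e)
        assert psi.shape == (5, 7, 4)
        assert np.all((psi >= 0) & (psi <= 1))


class TestTurnover:
    def test_arithmetic_case(self):
        assert turnover(0.45, 0.2, 0.3) == pytest.approx(0.245)

    def test_no_dynamics_no_turnover(self):
        assert turnover(0.6, 0.0, 0.0) == 0.0

    def test_certain_flip(self):
        assert turnover(1.0, 0.0, 1.0) == 1.0

    def test_bounds_property(self):
        rng = np.random.default_rng(1)
        psi, g, e = rng.uniform(0, 1, (3, 1000))
        tau = turnover(psi, g, e)
        assert np.all((tau >= 0) & (tau <= 1))
        assert np.all(tau <= np.maximum(g, e) + np.minimum(g, e) + 1e-15)


class TestRateOfChange:
    def test_halving(self):
        assert rate_of_change(0.4, 0.2) == pytest.approx(0.5)

    def test_equal_is_one(self):
        assert rate_of_change(0.33, 0.33) == pytest.approx(1.0)

    def test_equilibrium_trajectory_lambda_one(self):
        g, e = 0.2, 0.3
        eq = g / (g + e)
        psi = project_psi(eq, [g] * 4, [e] * 4)
        assert rate_of_change(psi[0], psi[-1]) == pytest.approx(1.0, abs=1e-12)

    def test_zero_start_flagged_nan(self):
        assert np.isnan(rate_of_change(0.0, 0.5))


class TestDeclineProportion:
    def test_half_declining(self):
        assert decline_proportion([0.5, 1.2, 0.9, 1.0]) == 0.5

    def test_strict_inequality_at_one(self):
        assert decline_proportion([1.0, 1.0]) == 0.0

    def test_all_declining(self):
        assert decline_proportion([0.2, 0.9]) == 1.0


class TestStableState:
    def test_arithmetic(self):
        assert stable_state(0.2, 0.3) == pytest.approx(0.4)

    def test_balanced_rates(self):
        assert stable_state(0.37, 0.37) == pytest.approx(0.5)

    def test_no_extirpation_full_occupancy(self):
        assert stable_state(0.4, 0.0) == pytest.approx(1.0)

    def test_degenerate_flagged(self):
        assert np.isnan(stable_state(0.0, 0.0))

    def test_is_fixed_point_of_projection(self):
        rng = np.random.default_rng(2)
        g, e = rng.uniform(0.05, 0.9, (2, 50))
        eq = stable_state(g, e)
        stepped = project_psi(eq, g[:, None], e[:, None])[..., -1]
        np.testing.assert_allclose(stepped, eq, atol=1e-12)


class TestGridMasking:
    def test_development_and_water_removed(self, tiny_scenario):
        from dynocc.simulate import generate_grid
        grid = generate_grid(tiny_scenario, seed=0, n_cells=100)
        kept = mask_grid(grid)
        assert (kept["high_development_fraction"] <= 0.40).all()
        assert (~kept["water"]).all()
        removed = len(grid) - len(kept)
        expected = int(((grid["high_development_fraction"] > 0.4)
                        | grid["water"]).sum())
        assert removed == expected


@pytest.fixture(scope="module")
def fitted():
    """One small fit shared by the grid-prediction tests."""
    from dynocc.fit import fit_dynamic_occupancy
    from dynocc.io import RunConfig
    from dynocc.simulate import Scenario, simulate_study
    sc = Scenario(
        name="tiny", n_sites=20, n_periods=4, occasions_per_period=6,
        sites_per_period=[20] * 4,
        beta_psi1=[0.3, -0.4, 0.4, 0.3], beta_p=[0.9, 0.3, -0.2],
        beta_gamma=[-0.8, 0.3, 0.6, -0.3, -0.3, 0.2, -0.2, 0.3, -0.3, 0.2],
        beta_epsilon=[-0.9, 0.3, 0.7, -0.3, -0.4, -0.2, 0.2, -0.2, 0.3, -0.2],
        sigma_eta=0.5, precip_site_sd=4.0)
    study = simulate_study(sc, seed=5)
    cfg = RunConfig.from_dict(
        {"mcmc": {"chains": 2, "warmup": 200, "draws": 300, "seed": 5}})
    fit = fit_dynamic_occupancy(study["history"], study["site_cov"],
                                study["season_cov"], cfg,
                                precip_site=study["precip_site"])
    return sc, study, fit


class TestPredictGrid:
    def test_mask_count_and_output_shapes(self, fitted):
        from dynocc.dynamics import predict_grid
        from dynocc.simulate import generate_grid
        sc, study, fit = fitted
        grid = generate_grid(sc, seed=9, n_cells=50)
        pred = predict_grid(fit, grid, study["season_cov"], max_draws=50)
        n_keep = int(((grid["high_development_fraction"] <= 0.4)
                      & ~grid["water"]).sum())
        assert len(pred.cell_ids) == n_keep
        assert pred.psi.shape == (50, n_keep, 4)
        assert np.all((pred.psi >= 0) & (pred.psi <= 1))
        tab = pred.summary()
        assert len(tab) == n_keep

    def test_identical_cells_give_identical_maps(self, fitted):
        import pandas as pd
        from dynocc.dynamics import predict_grid
        sc, study, fit = fitted
        row = {"moth": 2, "cover": 60.0, "road_dist": 0.5, "zone_area": 2.0,
               "high_development_fraction": 0.1, "water": False}
        grid = pd.DataFrame([row] * 6,
                            index=pd.Index([f"c{i}" for i in range(6)],
                                           name="cell_id"))
        pred = predict_grid(fit, grid, study["season_cov"], max_draws=40)
        assert np.ptp(pred.psi, axis=1).max() == 0.0
        assert np.ptp(pred.psi_eq_summer, axis=1).max() == 0.0

    def test_grid_cell_matching_a_site_reproduces_its_psi1(self, fitted):
        """A cell with a fitted site's covariates must get that site's
        psi1 posterior (detection effects and eta do not enter maps)."""
        import pandas as pd
        from scipy.special import expit
        from dynocc.dynamics import predict_grid
        sc, study, fit = fitted
        site = study["site_cov"].iloc[[0]]
        grid = site.assign(high_development_fraction=0.0, water=False)
        grid.index = pd.Index(["cell0"], name="cell_id")
        pred = predict_grid(fit, grid, study["season_cov"], max_draws=4000)
        s = fit.layout.slices
        pooled = fit.samples.pooled()
        psi1_site = expit(pooled[:, s["beta_psi1"]] @ fit.blocks.X_psi1[0])
        assert np.median(pred.psi[:, 0, 0]) == pytest.approx(
            np.median(psi1_site), abs=0.02)
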