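"""Synthetic-data generator: determinism, support, generative consistency."""

import numpy as np
import pytest

from dynocc.detections import build_history, filter_independent
from dynocc.simulate import (Scenario, expand_to_photos, generate_covariates,
                             generate_grid, recovery_scenario,
                             scenario_from_paper, simulate_latent,
                             simulate_study)


class TestCovariates:
    def test_deterministic_given_seed(self, tiny_scenario):
        a = generate_covariates(tiny_scenario, seed=3)
        b = generate_covariates(tiny_scenario, seed=3)
        assert a[0].equals(b[0]) and a[1].equals(b[1])

    def test_supports(self, tiny_scenario):
        site_cov, season_cov = generate_covariates(tiny_scenario, seed=1)
        assert site_cov["cover"].between(0, 100).all()
        assert site_cov["moth"].isin(range(5)).all()
        assert (site_cov["zone_area"] > 0).all()
        assert (site_cov["road_dist"] >= 0).all()
        assert (season_cov["precip"] >= 0).all()
        assert season_cov["tsd"].is_monotonic_increasing

    def test_requested_site_count(self):
        sc = Scenario(n_sites=240)
        site_cov, _ = generate_covariates(sc, seed=0)
        assert len(site_cov) == 240

    def test_degenerate_scenario_rejected(self):
        sc = Scenario(beta_gamma=[-20.0] + [0.0] * 9)
        with pytest.raises(ValueError, match="degenerate"):
            generate_covariates(sc, seed=0)


class TestLatentStates:
    def test_no_colonization_when_gamma_suppressed(self, tiny_scenario):
        import dataclasses
        sc = dataclasses.replace(tiny_scenario,
                                 beta_gamma=[-20.0] + [0.0] * 9)
        site_cov, season_cov = generate_covariates(tiny_scenario, seed=2)
        truth = simulate_latent(sc, site_cov, season_cov, seed=2)
        z = truth.z
        colonized = (z[:, 1:] == 1) & (z[:, :-1] == 0)
        assert colonized.sum() == 0

    def test_certain_initial_occupancy(self, tiny_scenario):
        import dataclasses
        sc = dataclasses.replace(tiny_scenario, beta_psi1=[20.0, 0, 0, 0])
        site_cov, season_cov = generate_covariates(tiny_scenario, seed=2)
        truth = simulate_latent(sc, site_cov, season_cov, seed=2)
        assert truth.z[:, 0].all()

    def test_initial_frequency_matches_psi1(self):
        """Large-n first-period occupancy frequency within 3 binomial sd."""
        from scipy.special import expit
        sc = recovery_scenario(n_sites=2000)
        study = simulate_study(sc, seed=6)
        z1 = study["truth"].z[:, 0]
        from dynocc.design import build_design_blocks
        blocks, _ = build_design_blocks(study["site_cov"], study["season_cov"],
                                        precip_site=study["precip_site"])
        psi1 = expit(blocks.X_psi1 @ np.asarray(sc.beta_psi1))
        expected = psi1.mean()
        sd = np.sqrt(np.sum(psi1 * (1 - psi1))) / len(psi1)
        assert abs(z1.mean() - expected) < 3 * sd


class TestDetectionsAndPhotos:
    def test_unoccupied_sites_silent(self, tiny_scenario):
        import dataclasses
        sc = dataclasses.replace(tiny_scenario,
                                 beta_psi1=[-20.0, 0, 0, 0],
                                 beta_gamma=[-20.0] + [0.0] * 9)
        study = simulate_study(sc, seed=4, with_photos=True, check=False)
        assert np.nansum(study["history"].y) == 0
        assert study["photos"] == []

    def test_certain_detection_when_occupied(self, tiny_scenario):
        import dataclasses
        sc = dataclasses.replace(tiny_scenario, beta_psi1=[20.0, 0, 0, 0],
                                 beta_p=[20.0, 0, 0], sigma_eta=1e-6)
        study = simulate_study(sc, seed=4, check=False)
        y = study["history"].y
        occupied = study["truth"].z == 1
        assert np.all(np.nan_to_num(y[occupied], nan=1.0) == 1.0)
        assert occupied[:, 0].all()  # psi1 forced to one

    def test_single_burst_collapses_to_one_event(self, tiny_scenario):
        """All gaps far below the window: the filter must return exactly
        one event per detected occasion."""
        study = simulate_study(tiny_scenario, seed=8)
        photos = expand_to_photos(study["history"], tiny_scenario, seed=8,
                                  enable_revisits=False)
        events = filter_independent(photos, 20)
        n_detected_occasions = int(np.nansum(study["history"].y))
        assert len(events) == n_detected_occasions

    def test_photo_roundtrip_reproduces_history(self, tiny_scenario):
        """Burst expansion -> independence filter -> history rebuild
        gives back exactly the simulated occasion-level y."""
        study = simulate_study(tiny_scenario, seed=9)
        photos = expand_to_photos(study["history"], tiny_scenario, seed=9,
                                  enable_revisits=False)
        events = filter_independent(photos, 20)
        rebuilt = build_history(events, study["deployments"],
                                tiny_scenario.periods, tiny_scenario.species,
                                tiny_scenario.occasion_length)
        np.testing.assert_array_equal(
            np.nan_to_num(rebuilt.y, nan=-1.0),
            np.nan_to_num(study["history"].y, nan=-1.0))

    def test_end_to_end_determinism(self, tiny_scenario):
        a = simulate_study(tiny_scenario, seed=11, with_photos=True)
        b = simulate_study(tiny_scenario, seed=11, with_photos=True)
        np.testing.assert_array_equal(
            np.nan_to_num(a["history"].y), np.nan_to_num(b["history"].y))
        assert a["photos"] == b["photos"]
        assert (a["truth"].z == b["truth"].z).all()


class TestScenarios:
    def test_paper_scenario_carries_published_medians(self):
        sc = scenario_from_paper()
        assert sc.beta_gamma[2] == 1.63        # season effect on colonization
        assert sc.beta_epsilon[4] == -1.18     # zone-area effect on extirpation
        sc.validate()

    def test_default_schedule_matches_published_design(self):
        sc = Scenario()
        assert sc.n_sites == 240
        assert [sc.active_sites(t) for t in range(8)] == [
            100, 100, 100, 200, 240, 240, 240, 100]
        assert sc.periods[0] == "S2019" and sc.periods[-1] == "W2023"

    def test_staggered_sites_missing_before_rollin(self):
        sc = Scenario(n_sites=240)
        study = simulate_study(sc, seed=1)
        y = study["history"].y
        # site 230 first deployed in period 4 (S2021)
        assert np.isnan(y[230, :4]).all()
        assert not np.isnan(y[230, 4]).all()
        # draw-down: only first 100 sites in final winter
        assert np.isnan(y[150, 7]).all()

    def test_grid_mask_fields(self, tiny_scenario):
        grid = generate_grid(tiny_scenario, seed=2, n_cells=80)
        assert grid["high_development_fraction"].between(0, 1).all()
        assert grid["water"].dtype == bool
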