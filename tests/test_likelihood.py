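"""Marginalized likelihood: closed forms, enumeration oracle, gradients."""

import numpy as np
import pytest

from conftest import brute_force_loglik, random_instance
from dynocc.design import DesignBlocks
from dynocc.model import (ModelData, ParamLayout, log_posterior_and_grad,
                          site_loglik)


class TestSiteLoglikClosedForms:
    def test_single_period_single_detection(self):
        # P(y=1) = psi1 * p
        assert site_loglik([[1.0]], 0.5, [], [], 0.8) == pytest.approx(
            np.log(0.5 * 0.8))

    def test_single_period_double_nondetection(self):
        # P(00) = psi1 (1-p)^2 + (1 - psi1)
        assert site_loglik([[0.0, 0.0]], 0.5, [], [], 0.5) == pytest.approx(
            np.log(0.5 * 0.25 + 0.5))

    def test_detection_after_certain_absence_impossible(self):
        # psi1 ~ 0 and no colonization: a detection has probability ~ 0
        ll = site_loglik([[1.0]], 1e-13, [], [], 0.5)
        assert ll < -25

    def test_missing_occasions_contribute_factor_one(self):
        y_missing = np.array([[1.0, np.nan, np.nan]])
        y_short = np.array([[1.0]])
        assert site_loglik(y_missing, 0.4, [], [], 0.6) == pytest.approx(
            site_loglik(y_short, 0.4, [], [], 0.6))

    def test_fully_missing_period_emission_one_for_both_states(self):
        # two periods, second fully missing: equals the single-period value
        # marginalized over the transition
        y = np.array([[0.0], [np.nan]])
        ll = site_loglik(y, 0.5, [0.2], [0.3], 0.5)
        assert ll == pytest.approx(np.log(0.5 * 0.5 + 0.5))

    def test_two_season_reduction_matches_hand_expansion(self):
        # T=2, J=1: sum over 4 latent paths by hand
        psi1, g, e, p = 0.3, 0.2, 0.4, 0.7
        y = np.array([[0.0], [1.0]])
        manual = (psi1 * (1 - p) * (1 - e) * p) + ((1 - psi1) * g * p)
        assert site_loglik(y, psi1, [g], [e], p) == pytest.approx(np.log(manual))


class TestEnumerationOracle:
    def test_random_instances_match_brute_force(self):
        rng = np.random.default_rng(20240721)
        for _ in range(100):
            y, psi1, g, e, p = random_instance(rng)
            fast = site_loglik(y, psi1, g, e, p)
            slow = brute_force_loglik(y, psi1, g, e, p)
            assert fast == pytest.approx(slow, abs=1e-10)


def _random_model_data(rng, n=6, T=4):
    Xp1 = np.column_stack([np.ones(n), rng.standard_normal((n, 3))])
    Xp = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
    Xt = np.column_stack([np.ones(n * (T - 1)), rng.standard_normal((n * (T - 1), 9))])
    blocks = DesignBlocks(X_psi1=Xp1, X_p=Xp, X_trans=Xt, n_sites=n,
                          n_periods=T, site_ids=[str(i) for i in range(n)])
    m = rng.integers(0, 6, (n, T)).astype(float)
    d = np.array([[rng.integers(0, mi + 1) for mi in row] for row in m], float)
    return ModelData(d=d, m=m, blocks=blocks)


class TestLogPosterior:
    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        data = _random_model_data(rng)
        theta = 0.4 * rng.standard_normal(data.layout.dim)
        _, grad = log_posterior_and_grad(theta, data)
        h = 1e-6
        for k in range(data.layout.dim):
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h
            tm[k] -= h
            fd = (log_posterior_and_grad(tp, data)[0]
                  - log_posterior_and_grad(tm, data)[0]) / (2 * h)
            assert grad[k] == pytest.approx(fd, rel=1e-5, abs=1e-7)

    def test_likelihood_factorizes_over_sites(self):
        rng = np.random.default_rng(4)
        data = _random_model_data(rng, n=5)
        theta = 0.3 * rng.standard_normal(data.layout.dim)
        lp, _ = log_posterior_and_grad(theta, data)
        # permute sites (and their random-effect coordinates) together
        perm = rng.permutation(5)
        blocks = data.blocks
        X3 = blocks.trans_3d()[perm].reshape(blocks.X_trans.shape)
        permuted = ModelData(
            d=data.d[perm], m=data.m[perm],
            blocks=DesignBlocks(X_psi1=blocks.X_psi1[perm], X_p=blocks.X_p[perm],
                                X_trans=X3, n_sites=5, n_periods=blocks.n_periods,
                                site_ids=[blocks.site_ids[i] for i in perm]))
        theta_perm = theta.copy()
        eta = theta[permuted.layout.slices["eta_raw"]]
        theta_perm[permuted.layout.slices["eta_raw"]] = eta[perm]
        lp2, _ = log_posterior_and_grad(theta_perm, permuted)
        assert lp2 == pytest.approx(lp, abs=1e-12 * max(1, abs(lp)))

    def test_doubling_sites_doubles_likelihood_term(self):
        rng = np.random.default_rng(5)
        data = _random_model_data(rng, n=3)
        layout = data.layout
        theta = 0.3 * rng.standard_normal(layout.dim)
        theta[layout.slices["eta_raw"]] = 0.0

        blocks = data.blocks
        doubled = ModelData(
            d=np.vstack([data.d, data.d]), m=np.vstack([data.m, data.m]),
            blocks=DesignBlocks(
                X_psi1=np.vstack([blocks.X_psi1] * 2),
                X_p=np.vstack([blocks.X_p] * 2),
                X_trans=np.vstack([blocks.X_trans] * 2),
                n_sites=6, n_periods=blocks.n_periods,
                site_ids=blocks.site_ids + [f"{s}b" for s in blocks.site_ids]))
        theta2 = np.concatenate([theta[:28], np.zeros(6)])

        def loglik_only(th, dat):
            # subtract the prior evaluated at the same structural params
            lp, _ = log_posterior_and_grad(th, dat)
            empty = ModelData(d=np.zeros_like(dat.d), m=np.zeros_like(dat.m),
                              blocks=dat.blocks)
            prior, _ = log_posterior_and_grad(th, empty)
            return lp - prior

        assert loglik_only(theta2, doubled) == pytest.approx(
            2 * loglik_only(theta, data), rel=1e-10)

    def test_detection_monotone_in_positive_p_coefficient(self):
        from scipy.special import expit
        X_p = np.array([[1.0, 0.7, 0.2]])
        base = expit(X_p @ np.array([0.2, 0.5, 0.1]))
        raised = expit(X_p @ np.array([0.2, 0.9, 0.1]))
        assert raised > base
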