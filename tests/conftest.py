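"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from dynocc.simulate import Scenario


def brute_force_loglik(y, psi1, gamma, epsilon, p) -> float:
    """Likelihood by explicit enumeration over every latent occupancy
    sequence — the independent oracle for the forward algorithm."""
    y = np.atleast_2d(np.asarray(y, float))
    T, J = y.shape
    p = np.broadcast_to(np.asarray(p, float), y.shape)
    gamma = np.asarray(gamma, float).reshape(-1)
    epsilon = np.asarray(epsilon, float).reshape(-1)
    total = 0.0
    for z in itertools.product((0, 1), repeat=T):
        prob = psi1 if z[0] else 1.0 - psi1
        for t in range(T - 1):
            if z[t] == 0:
                prob *= gamma[t] if z[t + 1] else 1.0 - gamma[t]
            else:
                prob *= 1.0 - epsilon[t] if z[t + 1] else epsilon[t]
        for t in range(T):
            for j in range(J):
                if np.isnan(y[t, j]):
                    continue
                if z[t] == 1:
                    prob *= p[t, j] if y[t, j] else 1.0 - p[t, j]
                elif y[t, j] == 1:
                    prob = 0.0
        total += prob
    return float(np.log(total)) if total > 0 else -np.inf


def random_instance(rng, max_T=4, max_J=3, missing_frac=0.3):
    """One random small likelihood instance (y, psi1, gamma, epsilon, p)."""
    T = int(rng.integers(1, max_T + 1))
    J = int(rng.integers(1, max_J + 1))
    y = rng.integers(0, 2, (T, J)).astype(float)
    y[rng.random((T, J)) < missing_frac] = np.nan
    return (y, float(rng.uniform(0.05, 0.95)),
            rng.uniform(0.05, 0.95, T - 1), rng.uniform(0.05, 0.95, T - 1),
            rng.uniform(0.05, 0.95, (T, J)))


@pytest.fixture
def tiny_scenario() -> Scenario:
    """Small, fast scenario: 20 sites, 4 periods, 6 weekly occasions."""
    return Scenario(
        name="tiny", n_sites=20, n_periods=4, occasions_per_period=6,
        sites_per_period=[20] * 4,
        beta_psi1=[0.3, -0.4, 0.4, 0.3],
        beta_p=[0.9, 0.3, -0.2],
        beta_gamma=[-0.8, 0.3, 0.6, -0.3, -0.3, 0.2, -0.2, 0.3, -0.3, 0.2],
        beta_epsilon=[-0.9, 0.3, 0.7, -0.3, -0.4, -0.2, 0.2, -0.2, 0.3, -0.2],
        sigma_eta=0.5, precip_site_sd=4.0,
    )


@pytest.fixture
def site_cov_small() -> pd.DataFrame:
    return pd.DataFrame(
        {"moth": [0, 2, 4, 1], "cover": [80.0, 55.0, 30.0, 95.0],
         "road_dist": [0.2, 1.0, 0.5, 2.0], "zone_area": [1.0, 4.0, 0.5, 9.0]},
        index=pd.Index(["A", "B", "C", "D"], name="site_id"))


@pytest.fixture
def season_cov_small() -> pd.DataFrame:
    return pd.DataFrame(
        {"precip": [20.0, 35.0, 25.0], "season_class": ["summer", "winter", "summer"],
         "tsd": [4.0, 4.5, 5.0]},
        index=pd.Index(["S2019", "W2020", "S2020"], name="period"))
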