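"""Derived occupancy dynamics and prediction-grid maps.

From the fitted dynamic parameters, occupancy propagates by

    psi[t+1] = psi[t] * (1 - epsilon[t]) + (1 - psi[t]) * gamma[t],

turnover between consecutive periods is
tau'[t] = psi[t] * epsilon[t] + (1 - psi[t]) * gamma[t], the seasonal
rate of change is lambda = psi_last / psi_first (within a season
class), and the stable-state (equilibrium) occupancy is
psi_eq = gamma / (gamma + epsilon) — the unique fixed point of the
projection map under constant rates.

All derived quantities are computed draw-wise from the posterior and
summarized afterwards (medians of derived values, never derived values
of medians), which is the exact propagation of posterior uncertainty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import TRANSITION_COLUMNS, build_design_blocks
from .fit import FitResult

logger = logging.getLogger("dynocc")


# ---------------------------------------------------------------------------
# elementary recursions (broadcast over any leading shape)
# ---------------------------------------------------------------------------

def project_psi(psi1, gamma, epsilon) -> np.ndarray:
    """Occupancy trajectory psi[0..T-1] from psi1 and the T-1 dynamic rates.

    ``gamma``/``epsilon`` have the transition axis last; the result has
    a period axis of length T last.
    """
    psi1 = np.asarray(psi1, float)
    gamma = np.asarray(gamma, float)
    epsilon = np.asarray(epsilon, float)
    if gamma.shape != epsilon.shape:
        raise ValueError("gamma and epsilon must have the same shape")
    n_trans = gamma.shape[-1] if gamma.ndim else 0
    out = np.empty(np.broadcast_shapes(psi1.shape, gamma.shape[:-1] if gamma.ndim else ())
                   + (n_trans + 1,))
    out[..., 0] = psi1
    for t in range(n_trans):
        cur = out[..., t]
        out[..., t + 1] = cur * (1 - epsilon[..., t]) + (1 - cur) * gamma[..., t]
    return out


def turnover(psi_t, gamma_t, epsilon_t) -> np.ndarray:
    """Probability a site changes occupancy status across a transition."""
    psi_t = np.asarray(psi_t, float)
    return psi_t * np.asarray(epsilon_t, float) + (1 - psi_t) * np.asarray(gamma_t, float)


def rate_of_change(psi_first, psi_last) -> np.ndarray:
    """lambda = psi_last / psi_first; NaN where psi_first is zero (flagged)."""
    psi_first = np.asarray(psi_first, float)
    psi_last = np.asarray(psi_last, float)
    bad = psi_first == 0
    if np.any(bad):
        logger.warning("rate_of_change undefined for %d cell(s) with psi_first = 0",
                       int(bad.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(bad, np.nan, psi_last / np.where(bad, 1.0, psi_first))


def decline_proportion(lambdas) -> float:
    """Proportion of valid cells with lambda strictly below 1."""
    lam = np.asarray(lambdas, float)
    valid = np.isfinite(lam)
    if not valid.any():
        raise ValueError("no valid cells for decline proportion")
    return float((lam[valid] < 1.0).sum() / valid.sum())


def stable_state(gamma, epsilon) -> np.ndarray:
    """Equilibrium occupancy gamma / (gamma + epsilon); NaN where both zero."""
    gamma = np.asarray(gamma, float)
    epsilon = np.asarray(epsilon, float)
    denom = gamma + epsilon
    bad = denom == 0
    if np.any(bad):
        logger.warning("stable_state undefined where gamma = epsilon = 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(bad, np.nan, gamma / np.where(bad, 1.0, denom))


# ---------------------------------------------------------------------------
# grid prediction
# ---------------------------------------------------------------------------

@dataclass
class GridPrediction:
    """Draw-wise derived series over retained grid cells."""

    cell_ids: list[str]
    periods: list[str]
    psi: np.ndarray          # (draws, cells, T)
    tau: np.ndarray          # (draws, cells, T-1)
    lambda_summer: np.ndarray    # (draws, cells)
    lambda_winter: np.ndarray
    psi_eq_summer: np.ndarray    # (draws, cells)
    psi_eq_winter: np.ndarray

    def summary(self) -> pd.DataFrame:
        """Cellwise posterior medians and 95% intervals."""
        def q(a, axis=0):
            return (np.median(a, axis=axis),
                    np.percentile(a, 2.5, axis=axis),
                    np.percentile(a, 97.5, axis=axis))

        out = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        for t, period in enumerate(self.periods):
            med, lo, hi = q(self.psi[:, :, t])
            out[f"psi_{period}"] = med
            out[f"psi_{period}_lo"] = lo
            out[f"psi_{period}_hi"] = hi
        for name in ("lambda_summer", "lambda_winter", "psi_eq_summer", "psi_eq_winter"):
            med, lo, hi = q(getattr(self, name))
            out[name] = med
            out[f"{name}_lo"] = lo
            out[f"{name}_hi"] = hi
        out["tau_mean"] = np.median(self.tau.mean(axis=2), axis=0)
        return out

    def decline_proportions(self) -> dict[str, float]:
        """c_s / c_w on posterior-median lambda, plus draw-wise posteriors."""
        out = {
            "c_summer": decline_proportion(np.median(self.lambda_summer, axis=0)),
            "c_winter": decline_proportion(np.median(self.lambda_winter, axis=0)),
        }
        out["c_summer_drawwise_mean"] = float(np.mean(
            [decline_proportion(d) for d in self.lambda_summer]))
        out["c_winter_drawwise_mean"] = float(np.mean(
            [decline_proportion(d) for d in self.lambda_winter]))
        return out


def mask_grid(grid: pd.DataFrame, max_development: float = 0.40) -> pd.DataFrame:
    """Drop water cells and cells whose high-development fraction exceeds
    the surveyed upper limit, before any proportion is computed."""
    keep = (~grid["water"].astype(bool)) & (grid["high_development_fraction"] <= max_development)
    return grid.loc[keep]


def _season_indices(season_classes: list[str]) -> dict[str, tuple[int, int]]:
    """First and last period index per season class."""
    out = {}
    for cls in ("summer", "winter"):
        idx = [i for i, c in enumerate(season_classes) if c == cls]
        if len(idx) >= 2:
            out[cls] = (idx[0], idx[-1])
    return out


def predict_grid(fit: FitResult, grid: pd.DataFrame, season_cov: pd.DataFrame,
                 *, max_development: float = 0.40, max_draws: int = 500
                 ) -> GridPrediction:
    """Derived occupancy dynamics across a covariate grid.

    Cells are masked first (development > ``max_development`` or
    water).  Grid covariates are standardized through the *fit-time*
    spec store; values outside the fitted range only warn
    (extrapolation).  For each retained posterior draw (evenly thinned
    to at most ``max_draws``), cellwise linear predictors give psi1 and
    the per-transition gamma/epsilon, which are projected to psi
    trajectories, turnover, seasonal rates of change, and the two
    seasonal stable states.

    Seasonal stable states use the season's *entering* transition
    (autumn for winter, spring for summer) with precipitation and tsd
    fixed at the mean of that transition class's standardized values.
    """
    retained = mask_grid(grid, max_development)
    if retained.empty:
        raise ValueError("mask removed every grid cell")
    for name in ("moth", "cover", "road_dist", "zone_area"):
        spec = fit.store.specs[name]
        z = spec.transform(retained[name])
        if np.any(np.abs(z) > 4):
            logger.warning("grid covariate %s extrapolates beyond the fitted range", name)

    if len(season_cov) != fit.blocks.n_periods:
        raise ValueError("season covariates do not match the fitted period count")
    periods = list(season_cov.index)
    classes = list(season_cov["season_class"])
    gblocks, _ = build_design_blocks(
        retained[["moth", "cover", "road_dist", "zone_area"]], season_cov,
        store=fit.store)

    pooled = fit.samples.pooled()
    if len(pooled) > max_draws:
        sel = np.linspace(0, len(pooled) - 1, max_draws).astype(int)
        pooled = pooled[sel]
    s = fit.layout.slices
    b_psi1 = pooled[:, s["beta_psi1"]]
    b_g = pooled[:, s["beta_gamma"]]
    b_e = pooled[:, s["beta_epsilon"]]

    n_cells = len(retained)
    T = len(periods)
    psi1 = expit(b_psi1 @ gblocks.X_psi1.T)                    # (draws, cells)
    lin_g = np.einsum("dk,ctk->dct", b_g, gblocks.trans_3d())  # (draws, cells, T-1)
    lin_e = np.einsum("dk,ctk->dct", b_e, gblocks.trans_3d())
    gamma = expit(lin_g)
    epsilon = expit(lin_e)

    psi = project_psi(psi1, gamma, epsilon)                    # (draws, cells, T)
    tau = turnover(psi[..., :-1], gamma, epsilon)

    lam = {}
    for cls, (first, last) in _season_indices(classes).items():
        lam[cls] = rate_of_change(psi[..., first], psi[..., last])

    # seasonal stable states: entering transition with class-mean climate
    season_dummy = {"winter": 0.0, "summer": 1.0}  # autumn enters winter, spring enters summer
    trans_classes = np.array([0.0 if c == "summer" else 1.0 for c in classes[:-1]])
    X3 = gblocks.trans_3d()                                    # (cells, T-1, 10)
    k_precip = TRANSITION_COLUMNS.index("precip")
    k_tsd = TRANSITION_COLUMNS.index("tsd")
    psi_eq = {}
    for cls in ("summer", "winter"):
        dummy = season_dummy[cls]
        sel_t = trans_classes == dummy
        if not sel_t.any():
            continue
        precip_bar = X3[0, sel_t, k_precip].mean()
        tsd_bar = X3[0, sel_t, k_tsd].mean()
        Xeq = X3[:, 0, :].copy()                               # (cells, 10)
        Xeq[:, TRANSITION_COLUMNS.index("season")] = dummy
        Xeq[:, k_precip] = precip_bar
        Xeq[:, k_tsd] = tsd_bar
        Xeq[:, TRANSITION_COLUMNS.index("precip:season")] = precip_bar * dummy
        Xeq[:, TRANSITION_COLUMNS.index("moth:tsd")] = (
            Xeq[:, TRANSITION_COLUMNS.index("moth")] * tsd_bar)
        g_eq = expit(b_g @ Xeq.T)                              # (draws, cells)
        e_eq = expit(b_e @ Xeq.T)
        psi_eq[cls] = stable_state(g_eq, e_eq)

    nan = np.full((pooled.shape[0], n_cells), np.nan)
    return GridPrediction(
        cell_ids=list(retained.index), periods=periods,
        psi=psi, tau=tau,
        lambda_summer=lam.get("summer", nan), lambda_winter=lam.get("winter", nan),
        psi_eq_summer=psi_eq.get("summer", nan), psi_eq_winter=psi_eq.get("winter", nan),
    )
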