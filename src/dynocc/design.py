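"""Covariate standardization and linear-predictor design blocks.

Every continuous covariate is mean-centred and scaled to unit standard
deviation before entering a linear predictor, so coefficients are
comparable as the effect of a one-standard-deviation change.  The
standardization constants are computed once at fit time and stored, and
prediction grids are always transformed through the *stored* constants.

The four submodels use fixed column layouts:

* initial occupancy psi1:  [1, moth, cover, road_dist]
* detection p:             [1, cover, zone_area]
* colonization gamma and extirpation epsilon, per site x transition:
  [1, precip, season, precip*season, zone_area, cover,
   zone_area*cover, moth, tsd, moth*tsd]

``season`` is the transition class dummy: 0 for the autumn transition
(summer -> winter, carrying the preceding summer's rain) and 1 for the
spring transition (winter -> summer, carrying the preceding winter's
snow).  Interaction columns are elementwise products of the
standardized main-effect columns.  The ordinal moth-damage score (0-4)
is treated as a standardized numeric covariate so it can enter
interactions on the same scale as the other terms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit  # noqa: F401  (re-exported helpers)

PSI1_COLUMNS = ["intercept", "moth", "cover", "road_dist"]
P_COLUMNS = ["intercept", "cover", "zone_area"]
TRANSITION_COLUMNS = [
    "intercept", "precip", "season", "precip:season",
    "zone_area", "cover", "zone_area:cover",
    "moth", "tsd", "moth:tsd",
]


@dataclass(frozen=True)
class StandardizationSpec:
    """Stored (mean, sd) of one covariate; transform is (x - mean)/sd."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.sd) or self.sd <= 0:
            raise ValueError("standardization sd must be positive and finite")

    def transform(self, values) -> np.ndarray:
        return (np.asarray(values, float) - self.mean) / self.sd


def standardize(values, spec: StandardizationSpec | None = None
                ) -> tuple[np.ndarray, StandardizationSpec]:
    """Standardize ``values``, either freshly (sample sd, n-1 denominator)
    or through a stored spec (prediction time)."""
    values = np.asarray(values, float)
    if spec is None:
        if np.unique(values).size < 2:
            raise ValueError("cannot standardize a constant vector")
        spec = StandardizationSpec(float(values.mean()), float(values.std(ddof=1)))
    return spec.transform(values), spec


@dataclass
class SpecStore:
    """Named standardization specs persisted next to fit outputs."""

    specs: dict[str, StandardizationSpec] = field(default_factory=dict)

    def fit_or_transform(self, name: str, values) -> np.ndarray:
        if name in self.specs:
            out, _ = standardize(values, self.specs[name])
        else:
            out, spec = standardize(values)
            self.specs[name] = spec
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({k: {"mean": s.mean, "sd": s.sd} for k, s in self.specs.items()},
                      fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SpecStore":
        with open(path) as fh:
            raw = json.load(fh)
        return cls({k: StandardizationSpec(v["mean"], v["sd"]) for k, v in raw.items()})


def encode_transition_season(season_classes) -> np.ndarray:
    """Dummy-code the T-1 transitions of an alternating period sequence:
    0 = autumn (from a summer period), 1 = spring (from a winter period)."""
    classes = list(season_classes)
    for a, b in zip(classes, classes[1:]):
        if a == b:
            raise ValueError("season classes must alternate")
    return np.array([0.0 if c == "summer" else 1.0 for c in classes[:-1]])


@dataclass
class DesignBlocks:
    """Design matrices for the four submodels.

    ``X_trans`` has one row per (site, transition), site-major: row
    ``i * (T-1) + t`` is site i's transition from period t to t+1.
    Colonization and extirpation share the matrix but have separate
    coefficient vectors.
    """

    X_psi1: np.ndarray          # (n_sites, 4)
    X_p: np.ndarray             # (n_sites, 3)
    X_trans: np.ndarray         # (n_sites * (T-1), 10)
    n_sites: int
    n_periods: int
    site_ids: list[str] = field(default_factory=list)

    @property
    def X_gamma(self) -> np.ndarray:
        return self.X_trans

    @property
    def X_epsilon(self) -> np.ndarray:
        return self.X_trans

    def trans_3d(self) -> np.ndarray:
        """X_trans reshaped to (n_sites, T-1, 10)."""
        return self.X_trans.reshape(self.n_sites, self.n_periods - 1, -1)


def build_design_blocks(site_cov: pd.DataFrame, season_cov: pd.DataFrame,
                        store: SpecStore | None = None,
                        site_order: list[str] | None = None,
                        precip_site: pd.DataFrame | None = None
                        ) -> tuple[DesignBlocks, SpecStore]:
    """Assemble all design blocks from covariate tables.

    ``site_cov`` is indexed by site_id (columns moth, cover, road_dist,
    zone_area); ``season_cov`` is indexed by period in order (columns
    precip, season_class, tsd).  The transition at index t carries
    period t's precipitation total and tsd.  A fresh ``store`` computes
    standardization constants; a populated one (prediction) reuses them.

    Precipitation is statewide per period by default; ``precip_site``
    (site_id index, one column per period, aligned with ``site_cov``
    and ``season_cov``) supplies site-varying seasonal totals instead,
    since the transition predictors index precipitation by both site
    and time.
    """
    if store is None:
        store = SpecStore()
    if site_order is not None:
        missing = [s for s in site_order if s not in site_cov.index]
        if missing:
            raise ValueError(f"sites lacking covariates: {missing}")
        site_cov = site_cov.loc[site_order]
    n = len(site_cov)
    T = len(season_cov)

    moth = store.fit_or_transform("moth", site_cov["moth"])
    cover = store.fit_or_transform("cover", site_cov["cover"])
    road = store.fit_or_transform("road_dist", site_cov["road_dist"])
    zone = store.fit_or_transform("zone_area", site_cov["zone_area"])

    X_psi1 = np.column_stack([np.ones(n), moth, cover, road])
    X_p = np.column_stack([np.ones(n), cover, zone])

    if T < 2:
        blocks = DesignBlocks(X_psi1=X_psi1, X_p=X_p,
                              X_trans=np.zeros((0, len(TRANSITION_COLUMNS))),
                              n_sites=n, n_periods=T, site_ids=list(site_cov.index))
        return blocks, store

    season = encode_transition_season(season_cov["season_class"])      # (T-1,)
    if precip_site is not None:
        raw_precip = precip_site.loc[site_cov.index, season_cov.index[:-1]].to_numpy(float)
        precip = store.fit_or_transform("precip", raw_precip.ravel()).reshape(n, T - 1)
    else:
        precip = store.fit_or_transform("precip", season_cov["precip"].to_numpy()[:-1])
    tsd = store.fit_or_transform("tsd", season_cov["tsd"].to_numpy()[:-1])

    # site-major rows: broadcast site terms over transitions and vice versa
    ones = np.ones((n, T - 1))
    P = ones * precip          # (n, T-1)
    S = ones * season
    TSD = ones * tsd
    Z = zone[:, None] * ones
    C = cover[:, None] * ones
    M = moth[:, None] * ones
    cols = [ones, P, S, P * S, Z, C, Z * C, M, TSD, M * TSD]
    X_trans = np.stack(cols, axis=2).reshape(n * (T - 1), len(cols))

    blocks = DesignBlocks(X_psi1=X_psi1, X_p=X_p, X_trans=X_trans,
                          n_sites=n, n_periods=T,
                          site_ids=list(site_cov.index))
    return blocks, store


def linear_predictor(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """X @ beta with an explicit conformability check."""
    X = np.atleast_2d(np.asarray(X, float))
    beta = np.asarray(beta, float)
    if X.shape[1] != beta.shape[0]:
        raise ValueError(f"design has {X.shape[1]} columns but beta has {beta.shape[0]}")
    return X @ beta


def blocks_to_frame(blocks: DesignBlocks, periods: list[str]) -> dict[str, pd.DataFrame]:
    """Audit export: each block as a labelled DataFrame."""
    trans_rows = [(s, f"{periods[t]}->{periods[t + 1]}")
                  for s in blocks.site_ids for t in range(blocks.n_periods - 1)]
    idx = pd.MultiIndex.from_tuples(trans_rows, names=["site_id", "transition"])
    return {
        "psi1": pd.DataFrame(blocks.X_psi1, index=blocks.site_ids, columns=PSI1_COLUMNS),
        "p": pd.DataFrame(blocks.X_p, index=blocks.site_ids, columns=P_COLUMNS),
        "transition": pd.DataFrame(blocks.X_trans, index=idx, columns=TRANSITION_COLUMNS),
    }
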