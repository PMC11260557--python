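"""Synthetic camera-trap study generator.

Emulates the statistical structure the analysis assumes: a
multi-season paired-camera survey (default eight alternating
summer/winter periods with a staggered site roll-in of 100 -> 200 ->
240 sites and a final-winter draw-down to 100, each period sampled for
twelve weekly occasions), site covariates with realistic marginal
shapes, latent occupancy evolving by the logit-linear colonization/
extirpation model, and detections emitted either directly at occasion
level or expanded into clustered photo bursts so the independence
filter is exercised end-to-end.

Covariate distributions (all scenario-configurable):

* zone_area  ~ log-normal(log 1.5 km^2, sd 1.0) — road-bounded parcels
  are small and right-skewed in a densely roaded landscape;
* cover      ~ 100 x Beta(2.5, 1.2) — forest-dominated sites;
* road_dist  ~ exponential(mean 0.6 km), most sites near a road;
* moth       ~ categorical on 0..4, weights favouring light damage;
* precip     ~ normal per season class (summer rain mean 22 in, sd 5;
  winter snow mean 32 in, sd 10), truncated at zero;
* tsd        grows by half a year per period from 4.0 years at the
  first summer (a 2015 outbreak observed from 2019).

The generating truth (parameters and the latent z) is always retained
so both state-level and emission-level recovery can be tested.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import build_design_blocks
from .detections import DetectionHistory
from .io import PhotoRecord, Deployment, season_class, season_sequence
from .model import Params

# Table-style default calendar: (period label, active sites, start, nights)
DEFAULT_SCHEDULE = [
    ("S2019", "2019-06-10", 84),
    ("W2020", "2019-12-02", 84),
    ("S2020", "2020-06-08", 84),
    ("W2021", "2020-11-14", 84),
    ("S2021", "2021-05-26", 84),
    ("W2022", "2021-11-01", 84),
    ("S2022", "2022-05-29", 84),
    ("W2023", "2022-11-28", 84),
]
DEFAULT_SITES_PER_PERIOD = [100, 100, 100, 200, 240, 240, 240, 100]


@dataclass
class Scenario:
    """Complete description of one synthetic study."""

    name: str = "default"
    n_sites: int = 240
    n_periods: int = 8
    occasions_per_period: int = 12
    occasion_length: int = 7
    first_period: str = "S2019"
    sites_per_period: list[int] = field(
        default_factory=lambda: list(DEFAULT_SITES_PER_PERIOD))
    beta_psi1: list[float] = field(default_factory=lambda: [0.0, -0.5, 0.5, 0.5])
    beta_p: list[float] = field(default_factory=lambda: [0.5, 0.3, -0.3])
    beta_gamma: list[float] = field(
        default_factory=lambda: [-1.0, 0.3, 0.8, 0.4, -0.4, 0.3, -0.3, 0.3, 0.4, 0.3])
    beta_epsilon: list[float] = field(
        default_factory=lambda: [-1.0, 0.3, 0.8, -0.4, -0.5, -0.3, -0.3, -0.2, 0.4, -0.2])
    sigma_eta: float = 0.5
    # covariate distributions
    zone_area_logmean: float = np.log(1.5)
    zone_area_logsd: float = 1.0
    cover_beta: tuple[float, float] = (2.5, 1.2)
    road_dist_mean: float = 0.6
    moth_weights: tuple[float, ...] = (0.35, 0.25, 0.18, 0.12, 0.10)
    precip_summer: tuple[float, float] = (22.0, 5.0)
    precip_winter: tuple[float, float] = (32.0, 10.0)
    precip_site_sd: float = 0.0   # spatial sd of seasonal totals around the statewide value
    tsd_start: float = 4.0
    tsd_step: float = 0.5
    # photo-burst process
    burst_mean_photos: float = 4.0
    burst_gap_mean_min: float = 2.0
    burst_max_span_min: float = 15.0  # keep bursts inside the independence window
    revisit_prob: float = 0.3
    revisit_gap_min: float = 240.0
    species: str = "bobcat"

    @property
    def periods(self) -> list[str]:
        return season_sequence(self.first_period, self.n_periods)

    def active_sites(self, t: int) -> int:
        if t < len(self.sites_per_period):
            return min(self.sites_per_period[t], self.n_sites)
        return self.n_sites

    def validate(self, covariates_check: bool = True) -> None:
        """Guard against degenerate scenarios: at covariate means every
        probability must be well inside (0.01, 0.99)."""
        for name in ("beta_psi1", "beta_p", "beta_gamma", "beta_epsilon"):
            intercept = getattr(self, name)[0]
            prob = expit(intercept)
            if not (0.01 < prob < 0.99):
                raise ValueError(
                    f"degenerate scenario: {name} implies probability {prob:.3g} "
                    "at covariate means")
        if self.sigma_eta <= 0:
            raise ValueError("sigma_eta must be positive")
        if len(self.beta_gamma) != 10 or len(self.beta_epsilon) != 10:
            raise ValueError("transition submodels need 10 coefficients")

    def params(self, eta: np.ndarray | None = None) -> Params:
        return Params(
            beta_psi1=np.asarray(self.beta_psi1, float),
            beta_p=np.asarray(self.beta_p, float),
            beta_gamma=np.asarray(self.beta_gamma, float),
            beta_epsilon=np.asarray(self.beta_epsilon, float),
            sigma_eta=self.sigma_eta,
            eta=eta if eta is not None else np.zeros(0),
        )


def scenario_from_paper() -> Scenario:
    """Scenario whose true coefficients are published posterior medians
    for bobcat, enabling qualitative comparison of derived dynamics.

    Reported medians cover a subset of terms (season and
    precipitation-by-season on colonization, cover on colonization,
    tsd on colonization, zone area / cover / their interaction on
    extirpation, moth and road distance on initial occupancy, cover on
    detection); unreported coefficients are zero.  Intercepts are not
    published and are set to plausible values for a sparsely detected
    felid (initial occupancy near 0.25, weekly detection near 0.25).
    """
    sc = Scenario(
        name="bobcat-paper",
        beta_psi1=[-1.1, -0.76, 0.0, 1.14],
        beta_p=[-1.1, -0.06, 0.0],
        # [1, precip, season, precip:season, zone, cover, zone:cover, moth, tsd, moth:tsd]
        beta_gamma=[-2.0, 0.0, 1.63, 1.27, 0.0, -1.07, 0.0, 0.0, 1.14, 0.0],
        beta_epsilon=[-1.0, 0.0, 0.0, 0.0, -1.18, -0.32, -0.36, 0.0, 0.0, 0.0],
        sigma_eta=1.0,
    )
    sc.validate()
    return sc


def recovery_scenario(n_sites: int = 120) -> Scenario:
    """Moderate-effect scenario used for parameter-recovery experiments:
    every covariate acts (|beta| well below 2), detection is informative,
    and all sites run for all periods so every coefficient is identified."""
    return Scenario(
        name="recovery",
        n_sites=n_sites,
        sites_per_period=[n_sites] * 8,
        beta_psi1=[0.2, -0.6, 0.5, 0.4],
        beta_p=[0.8, 0.3, -0.25],
        beta_gamma=[-0.9, 0.4, 0.8, -0.5, -0.4, 0.3, -0.3, 0.35, -0.45, 0.3],
        beta_epsilon=[-1.1, 0.35, 0.9, -0.4, -0.55, -0.3, 0.25, -0.3, 0.45, -0.25],
        sigma_eta=0.5,
        # seasonal totals vary spatially (coastal-inland gradients), which
        # is what makes the precipitation coefficients identifiable
        precip_site_sd=4.0,
    )


@dataclass
class TruthSet:
    """Generating parameters and latent states, kept for recovery tests."""

    params: Params
    z: np.ndarray              # (n_sites, n_periods) 0/1
    seed: int
    scenario: str

    def to_json(self, path) -> None:
        payload = {
            "scenario": self.scenario,
            "seed": self.seed,
            "beta_psi1": self.params.beta_psi1.tolist(),
            "beta_p": self.params.beta_p.tolist(),
            "beta_gamma": self.params.beta_gamma.tolist(),
            "beta_epsilon": self.params.beta_epsilon.tolist(),
            "sigma_eta": self.params.sigma_eta,
            "eta": self.params.eta.tolist(),
            "z": self.z.astype(int).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


# ---------------------------------------------------------------------------
# generation stages
# ---------------------------------------------------------------------------

def generate_covariates(scenario: Scenario, seed: int, check: bool = True
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Site and season covariate tables for one scenario draw.

    ``check=False`` skips the degeneracy guard, for deliberately extreme
    scenarios (e.g. colonization forced to zero in diagnostics).
    """
    if check:
        scenario.validate()
    rng = np.random.default_rng([seed, 1])
    n = scenario.n_sites
    site_ids = [f"site{i:04d}" for i in range(n)]
    site_cov = pd.DataFrame({
        "moth": rng.choice(5, size=n, p=np.asarray(scenario.moth_weights)
                           / np.sum(scenario.moth_weights)),
        "cover": 100.0 * rng.beta(*scenario.cover_beta, size=n),
        "road_dist": rng.exponential(scenario.road_dist_mean, size=n),
        "zone_area": rng.lognormal(scenario.zone_area_logmean,
                                   scenario.zone_area_logsd, size=n),
    }, index=pd.Index(site_ids, name="site_id"))

    rows = []
    for t, period in enumerate(scenario.periods):
        cls = season_class(period)
        mu, sd = (scenario.precip_summer if cls == "summer"
                  else scenario.precip_winter)
        rows.append({
            "period": period,
            "precip": max(float(rng.normal(mu, sd)), 0.0),
            "season_class": cls,
            "tsd": scenario.tsd_start + scenario.tsd_step * t,
        })
    season_cov = pd.DataFrame(rows).set_index("period")
    return site_cov, season_cov


def generate_precip_field(scenario: Scenario, site_cov: pd.DataFrame,
                          season_cov: pd.DataFrame, seed: int
                          ) -> pd.DataFrame | None:
    """Site-by-period seasonal precipitation totals, when the scenario
    carries spatial variation (``precip_site_sd > 0``); None otherwise."""
    if scenario.precip_site_sd <= 0:
        return None
    rng = np.random.default_rng([seed, 6])
    base = season_cov["precip"].to_numpy()
    noise = rng.normal(0.0, scenario.precip_site_sd,
                       (len(site_cov), len(season_cov)))
    return pd.DataFrame(np.maximum(base + noise, 0.0),
                        index=site_cov.index, columns=season_cov.index)


def generate_grid(scenario: Scenario, seed: int, n_cells: int = 200,
                  p_high_dev: float = 0.15, p_water: float = 0.05) -> pd.DataFrame:
    """Prediction-grid covariates with development/water mask fields."""
    rng = np.random.default_rng([seed, 4])
    cells = pd.DataFrame({
        "moth": rng.choice(5, size=n_cells, p=np.asarray(scenario.moth_weights)
                           / np.sum(scenario.moth_weights)),
        "cover": 100.0 * rng.beta(*scenario.cover_beta, size=n_cells),
        "road_dist": rng.exponential(scenario.road_dist_mean, size=n_cells),
        "zone_area": rng.lognormal(scenario.zone_area_logmean,
                                   scenario.zone_area_logsd, size=n_cells),
        "high_development_fraction": np.where(
            rng.random(n_cells) < p_high_dev,
            rng.uniform(0.4, 1.0, n_cells), rng.uniform(0.0, 0.4, n_cells)),
        "water": rng.random(n_cells) < p_water,
    }, index=pd.Index([f"cell{i:05d}" for i in range(n_cells)], name="cell_id"))
    return cells


def make_deployments(scenario: Scenario) -> list[Deployment]:
    """Deployment windows following the scenario's staggered calendar."""
    deps = []
    site_ids = [f"site{i:04d}" for i in range(scenario.n_sites)]
    n_occ_days = scenario.occasions_per_period * scenario.occasion_length
    for t, period in enumerate(scenario.periods):
        start = dt.date.fromisoformat(DEFAULT_SCHEDULE[t % len(DEFAULT_SCHEDULE)][1])
        active = scenario.active_sites(t)
        for s in site_ids[:active]:
            deps.append(Deployment(s, period, start,
                                   start + dt.timedelta(days=n_occ_days)))
    return deps


def _linear_probs(scenario: Scenario, site_cov, season_cov, eta,
                  precip_site=None):
    blocks, _ = build_design_blocks(site_cov, season_cov,
                                    precip_site=precip_site)
    pr = scenario.params()
    psi1 = expit(blocks.X_psi1 @ pr.beta_psi1)
    p = expit(blocks.X_p @ pr.beta_p + eta)
    n, T = blocks.n_sites, blocks.n_periods
    gamma = expit((blocks.X_trans @ pr.beta_gamma).reshape(n, T - 1))
    epsilon = expit((blocks.X_trans @ pr.beta_epsilon).reshape(n, T - 1))
    return psi1, p, gamma, epsilon


def simulate_latent(scenario: Scenario, site_cov: pd.DataFrame,
                    season_cov: pd.DataFrame, seed: int,
                    precip_site: pd.DataFrame | None = None) -> TruthSet:
    """Draw site random effects and the latent occupancy chain."""
    rng = np.random.default_rng([seed, 2])
    n, T = scenario.n_sites, scenario.n_periods
    eta = scenario.sigma_eta * rng.standard_normal(n)
    psi1, _, gamma, epsilon = _linear_probs(scenario, site_cov, season_cov, eta,
                                            precip_site)
    z = np.zeros((n, T), dtype=int)
    z[:, 0] = rng.random(n) < psi1
    for t in range(T - 1):
        stay = rng.random(n) < (1 - epsilon[:, t])
        colonize = rng.random(n) < gamma[:, t]
        z[:, t + 1] = np.where(z[:, t] == 1, stay, colonize)
    return TruthSet(params=scenario.params(eta), z=z, seed=seed,
                    scenario=scenario.name)


def simulate_detections(truth: TruthSet, scenario: Scenario,
                        site_cov: pd.DataFrame, season_cov: pd.DataFrame,
                        seed: int,
                        precip_site: pd.DataFrame | None = None) -> DetectionHistory:
    """Occasion-level detection history implied by the truth."""
    rng = np.random.default_rng([seed, 3])
    n, T = truth.z.shape
    J = scenario.occasions_per_period
    _, p, _, _ = _linear_probs(scenario, site_cov, season_cov, truth.params.eta,
                               precip_site)
    y = np.full((n, T, J), np.nan)
    deps = make_deployments(scenario)
    deployed = np.zeros((n, T), bool)
    site_idx = {f"site{i:04d}": i for i in range(n)}
    period_idx = {pd_: t for t, pd_ in enumerate(scenario.periods)}
    for d in deps:
        deployed[site_idx[d.site_id], period_idx[d.primary_period]] = True
    for t in range(T):
        active = deployed[:, t]
        draws = rng.random((n, J)) < p[:, None]
        y[active, t, :] = (draws[active] & (truth.z[:, t + 0][active, None] == 1))
    return DetectionHistory(y=y, site_ids=sorted(site_idx, key=site_idx.get),
                            periods=scenario.periods,
                            occasions=_occasion_calendar(scenario, deps))


def _occasion_calendar(scenario, deps):
    from .detections import tile_occasions
    return {(d.site_id, d.primary_period):
            tile_occasions(d.start, d.end, scenario.occasion_length)
            for d in deps}


def expand_to_photos(history: DetectionHistory, scenario: Scenario, seed: int,
                     enable_revisits: bool = True) -> list[PhotoRecord]:
    """Expand each detected occasion into a clustered photo burst.

    Each y=1 occasion receives one burst: 1 + Poisson(burst_mean_photos)
    photos with exponential inter-photo gaps far below the independence
    window, started uniformly inside the occasion's first half.  With
    probability ``revisit_prob`` (when ``enable_revisits``) a second
    burst follows after a gap well above the window, so filtering plus
    history rebuilding reproduces the same occasion-level y while the
    independent-event count can exceed the occasion count.
    """
    rng = np.random.default_rng([seed, 5])
    photos: list[PhotoRecord] = []
    for (site, period), occ in sorted(history.occasions.items()):
        i = history.site_ids.index(site)
        t = history.periods.index(period)
        for j, (a, b) in enumerate(occ):
            if j >= history.y.shape[2] or history.y[i, t, j] != 1.0:
                continue
            half = (b - a) / 2
            start = a + half * rng.random()
            bursts = [start]
            if enable_revisits and rng.random() < scenario.revisit_prob:
                bursts.append(start + dt.timedelta(
                    minutes=scenario.revisit_gap_min * (1 + rng.random())))
            for burst_start in bursts:
                n_photos = 1 + rng.poisson(scenario.burst_mean_photos)
                ts = burst_start
                span = dt.timedelta(minutes=scenario.burst_max_span_min)
                for k in range(n_photos):
                    if k:
                        ts = ts + dt.timedelta(
                            minutes=float(rng.exponential(scenario.burst_gap_mean_min)))
                    if ts >= b or ts - burst_start >= span:
                        break
                    photos.append(PhotoRecord(
                        site_id=site, species=scenario.species, timestamp=ts,
                        camera_id=f"{site}-cam{1 + int(rng.random() < 0.5)}"))
    photos.sort()
    return photos


def simulate_study(scenario: Scenario, seed: int, with_photos: bool = False,
                   check: bool = True):
    """One full synthetic study: covariates, truth, history (and photos).

    Returns a dict with keys site_cov, season_cov, truth, history,
    deployments, and (if requested) photos.  (seed, scenario) fully
    determines every output.
    """
    site_cov, season_cov = generate_covariates(scenario, seed, check=check)
    precip_site = generate_precip_field(scenario, site_cov, season_cov, seed)
    truth = simulate_latent(scenario, site_cov, season_cov, seed, precip_site)
    history = simulate_detections(truth, scenario, site_cov, season_cov, seed,
                                  precip_site)
    out = {
        "site_cov": site_cov,
        "season_cov": season_cov,
        "precip_site": precip_site,
        "truth": truth,
        "history": history,
        "deployments": make_deployments(scenario),
    }
    if with_photos:
        out["photos"] = expand_to_photos(history, scenario, seed)
    return out


def write_study(study: dict, outdir, scenario: Scenario) -> None:
    """Emit the CSV schemas the ingestion layer consumes, plus truth JSON."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study["site_cov"].to_csv(outdir / "site_covariates.csv")
    study["season_cov"].to_csv(outdir / "season_covariates.csv")
    if study.get("precip_site") is not None:
        study["precip_site"].to_csv(outdir / "precip_site.csv")
    pd.DataFrame([{"site_id": d.site_id, "primary_period": d.primary_period,
                   "start": d.start.isoformat(), "end": d.end.isoformat()}
                  for d in study["deployments"]]).to_csv(
        outdir / "deployments.csv", index=False)
    if "photos" in study:
        pd.DataFrame([{"site_id": r.site_id, "camera_id": r.camera_id,
                       "species": r.species,
                       "timestamp": r.timestamp.isoformat()}
                      for r in study["photos"]]).to_csv(
            outdir / "photos.csv", index=False)
    study["history"].write(outdir / "history.csv", outdir / "occasions.json")
    study["truth"].to_json(outdir / "truth.json")
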