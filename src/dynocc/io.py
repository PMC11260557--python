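"""Domain records, validated CSV ingestion, and run configuration.

All tabular interchange is plain CSV (UTF-8, header row, RFC-4180);
timestamps are ISO-8601 and parsed as naive local time — camera-trap
deployments live in a single study time zone and the independence rule
operates at a scale where DST shifts are irrelevant.

Seasonal primary periods are a closed, ordered vocabulary of labels such
as ``S2019, W2020, S2020, ...`` (summer of year y is followed by the
winter labelled y+1, whose deployment spans the year boundary).  Labels
are always generated from a first season plus a count rather than parsed
free-form, so that period order can never be silently wrong.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

logger = logging.getLogger("dynocc")

SUMMER = "summer"
WINTER = "winter"


# ---------------------------------------------------------------------------
# season label vocabulary
# ---------------------------------------------------------------------------

def season_class(label: str) -> str:
    """Season class ('summer' or 'winter') of a period label like 'S2019'."""
    if not label or label[0] not in "SW" or not label[1:].isdigit():
        raise ValueError(f"malformed season label: {label!r}")
    return SUMMER if label[0] == "S" else WINTER


def next_season(label: str) -> str:
    """Successor of a period label: S<y> -> W<y+1>, W<y> -> S<y>."""
    year = int(label[1:])
    return f"W{year + 1}" if label[0] == "S" else f"S{year}"


def season_sequence(first: str, n_periods: int) -> list[str]:
    """Ordered alternating period labels starting at ``first``."""
    season_class(first)  # validate
    out = [first]
    for _ in range(n_periods - 1):
        out.append(next_season(out[-1]))
    return out


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class PhotoRecord:
    """One timestamped species photo at a camera within a site."""

    site_id: str
    species: str
    timestamp: dt.datetime
    camera_id: str = ""


@dataclass(frozen=True)
class Deployment:
    """One camera-trapping window at a site within a primary period."""

    site_id: str
    primary_period: str
    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"deployment {self.site_id}/{self.primary_period}: "
                f"end {self.end} not after start {self.start}"
            )

    @property
    def nights(self) -> int:
        return (self.end - self.start).days


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_photo_records(path, species_list: Iterable[str]) -> list[PhotoRecord]:
    """Read a photo-record CSV, keeping only species in ``species_list``.

    Rows whose species is not configured are dropped (with a logged
    count); a malformed timestamp is an error naming the offending rows.
    The result is sorted by (site, species, timestamp), the order the
    independence filter requires.
    """
    species_list = set(species_list)
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["site_id", "camera_id", "species", "timestamp"], path)
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    bad = df.index[ts.isna() & df["timestamp"].notna()]
    if len(bad):
        rows = ", ".join(str(i + 2) for i in bad[:10])  # +2: header + 1-based
        raise ValueError(f"{path}: malformed timestamp on row(s) {rows}")
    keep = df["species"].isin(species_list)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("read_photo_records: dropped %d rows of unlisted species", n_dropped)
    records = [
        PhotoRecord(site_id=r.site_id, camera_id=r.camera_id,
                    species=r.species, timestamp=t.to_pydatetime())
        for r, t in zip(df[keep].itertuples(), ts[keep])
    ]
    records.sort()
    return records


def read_deployments(path, period_sequence: Sequence[str] | None = None) -> list[Deployment]:
    """Read deployment windows; overlapping windows within one
    (site, period) are merged into their union."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["site_id", "primary_period", "start", "end"], path)
    deps: list[Deployment] = []
    for i, r in enumerate(df.itertuples()):
        start = dt.date.fromisoformat(r.start)
        end = dt.date.fromisoformat(r.end)
        if end <= start:
            raise ValueError(
                f"{path} row {i + 2}: end {end} is not after start {start}"
            )
        if period_sequence is not None and r.primary_period not in period_sequence:
            raise ValueError(
                f"{path} row {i + 2}: unknown primary period {r.primary_period!r}"
            )
        deps.append(Deployment(r.site_id, r.primary_period, start, end))
    return merge_deployments(deps)


def merge_deployments(deps: Iterable[Deployment]) -> list[Deployment]:
    """Union overlapping/touching windows per (site, period); sorted output."""
    grouped: dict[tuple[str, str], list[Deployment]] = {}
    for d in deps:
        grouped.setdefault((d.site_id, d.primary_period), []).append(d)
    out: list[Deployment] = []
    for (site, period), group in sorted(grouped.items()):
        group.sort(key=lambda d: d.start)
        cur_start, cur_end = group[0].start, group[0].end
        for d in group[1:]:
            if d.start <= cur_end:
                cur_end = max(cur_end, d.end)
            else:
                out.append(Deployment(site, period, cur_start, cur_end))
                cur_start, cur_end = d.start, d.end
        out.append(Deployment(site, period, cur_start, cur_end))
    return out


def read_site_covariates(path) -> pd.DataFrame:
    """Site covariate table indexed by site_id.

    Columns: ``moth`` (ordinal damage severity 0-4), ``cover`` (percent
    vegetation cover within the road-bounded zone, 0-100), ``road_dist``
    (km to nearest road, >= 0), ``zone_area`` (km^2 of the zone, > 0).
    """
    df = pd.read_csv(path, dtype={"site_id": str})
    _require_columns(df, ["site_id", "moth", "cover", "road_dist", "zone_area"], path)
    df = df.set_index("site_id")
    validate_site_covariates(df)
    return df


def validate_site_covariates(df: pd.DataFrame) -> None:
    if df[["moth", "cover", "road_dist", "zone_area"]].isna().any().any():
        raise ValueError("site covariates contain missing values")
    if not df["moth"].between(0, 4).all():
        raise ValueError("moth damage severity must be in 0..4")
    if not df["cover"].between(0, 100).all():
        raise ValueError("cover must be a percentage in [0, 100]")
    if (df["road_dist"] < 0).any():
        raise ValueError("road_dist must be >= 0")
    if (df["zone_area"] <= 0).any():
        raise ValueError("zone_area must be > 0")


def read_season_covariates(path, period_sequence: Sequence[str] | None = None) -> pd.DataFrame:
    """Season covariate table, one row per primary period in period order.

    Columns: ``precip`` (seasonal total, inches; rain in summer, snow in
    winter), ``season_class`` ('summer'/'winter', must alternate), ``tsd``
    (years since the defoliation event, strictly increasing).
    """
    df = pd.read_csv(path, dtype={"period": str})
    _require_columns(df, ["period", "precip", "season_class", "tsd"], path)
    df = df.set_index("period")
    if period_sequence is not None:
        missing = [p for p in period_sequence if p not in df.index]
        if missing:
            raise ValueError(f"{path}: missing season covariates for {missing}")
        df = df.loc[list(period_sequence)]
    validate_season_covariates(df)
    return df


def validate_season_covariates(df: pd.DataFrame) -> None:
    classes = list(df["season_class"])
    for a, b in zip(classes, classes[1:]):
        if a == b:
            raise ValueError("season_class must alternate along the period sequence")
    tsd = df["tsd"].to_numpy()
    if not (tsd[1:] > tsd[:-1]).all():
        raise ValueError("tsd must be strictly increasing across periods")
    if (tsd < 0).any():
        raise ValueError("tsd must be >= 0")


def read_grid(path) -> pd.DataFrame:
    """Prediction-grid covariate table indexed by cell_id.

    Carries the site covariates plus ``high_development_fraction`` in
    [0, 1] and a boolean ``water`` flag used for masking.
    """
    df = pd.read_csv(path, dtype={"cell_id": str})
    _require_columns(
        df,
        ["cell_id", "moth", "cover", "road_dist", "zone_area",
         "high_development_fraction", "water"],
        path,
    )
    df = df.set_index("cell_id")
    if not df["high_development_fraction"].between(0, 1).all():
        raise ValueError("high_development_fraction must be in [0, 1]")
    df["water"] = df["water"].astype(bool) if df["water"].dtype != bool else df["water"]
    return df


# ---------------------------------------------------------------------------
# cross-input validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationItem:
    severity: str  # "fatal" | "warning"
    message: str


@dataclass
class ValidationReport:
    items: list[ValidationItem] = field(default_factory=list)

    def add(self, severity: str, message: str) -> None:
        self.items.append(ValidationItem(severity, message))

    @property
    def fatal(self) -> bool:
        return any(i.severity == "fatal" for i in self.items)

    def __len__(self) -> int:
        return len(self.items)


def validate_inputs(records, deployments, site_cov, season_cov) -> ValidationReport:
    """Cross-check the four input tables before any processing.

    Flags photos outside every deployment window of their site
    (warnings), sites present in the data but absent from the covariate
    table (fatal), and periods lacking season covariates (fatal).
    """
    report = ValidationReport()
    windows: dict[str, list[Deployment]] = {}
    for d in deployments:
        windows.setdefault(d.site_id, []).append(d)
    for r in records:
        site_windows = windows.get(r.site_id, [])
        day = r.timestamp.date()
        if not any(d.start <= day <= d.end for d in site_windows):
            report.add("warning",
                       f"photo at {r.site_id} {r.timestamp} outside every deployment window")
    sites = {r.site_id for r in records} | {d.site_id for d in deployments}
    for s in sorted(sites):
        if s not in site_cov.index:
            report.add("fatal", f"site {s} lacks site covariates")
    for d in deployments:
        if d.primary_period not in season_cov.index:
            report.add("fatal", f"period {d.primary_period} lacks season covariates")
    return report


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class MCMCConfig:
    chains: int = 3
    warmup: int = 2500
    draws: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for diagnostics")
        if self.warmup <= 0 or self.draws <= 0:
            raise ValueError("warmup and draws must be positive")


@dataclass
class PriorConfig:
    beta_scale: float = 2.5       # normal(0, scale) on standardized-scale coefficients
    sigma_eta_scale: float = 1.0  # half-normal(0, scale) on the random-effect sd


@dataclass
class RunConfig:
    species: list[str] = field(default_factory=lambda: ["bobcat"])
    independence_window: float = 20.0    # minutes
    occasion_length: int = 7             # days
    trap_night_basis: str = "camera"     # "camera" (paired, x2) or "site"
    disturbance_origin: dt.date = dt.date(2015, 6, 1)
    first_period: str = "S2019"
    n_periods: int = 8
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    priors: PriorConfig = field(default_factory=PriorConfig)
    support_strong: float = 0.90
    support_moderate: float = 0.70

    def __post_init__(self) -> None:
        if not (0.5 < self.support_moderate < self.support_strong < 1.0):
            raise ValueError("support thresholds must satisfy 0.5 < moderate < strong < 1")
        if isinstance(self.disturbance_origin, str):
            self.disturbance_origin = dt.date.fromisoformat(self.disturbance_origin)

    @property
    def period_sequence(self) -> list[str]:
        return season_sequence(self.first_period, self.n_periods)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "mcmc" in raw:
            raw["mcmc"] = MCMCConfig(**raw["mcmc"])
        if "priors" in raw:
            raw["priors"] = PriorConfig(**raw["priors"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["disturbance_origin"] = self.disturbance_origin.isoformat()
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
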