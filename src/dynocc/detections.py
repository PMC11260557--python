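"""From photo streams to independent detections and detection histories.

Camera-trap photos arrive in bursts (an animal lingering in front of a
camera triggers many frames).  Bursts are collapsed to independent
detection events with the standard greedy rule: scanning photos of one
species at one site in time order, a photo is kept iff at least the
independence window (default 20 min) has elapsed since the last *kept*
photo.  Both cameras of a paired-camera site are pooled before
filtering, since the analysis is at site level and the second camera
exists to raise detection, not to duplicate effort.

Detection histories are binary arrays over (site, primary period,
secondary occasion), with occasions tiled as consecutive fixed-length
blocks (default one week) from each deployment window's start; cells
outside any deployment are missing.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Deployment, PhotoRecord

logger = logging.getLogger("dynocc")


@dataclass(frozen=True, order=True)
class DetectionEvent:
    """First photo of an independent detection cluster."""

    site_id: str
    species: str
    timestamp: dt.datetime


@dataclass
class DetectionHistory:
    """Binary/missing detection array y[site, period, occasion].

    ``y`` holds 0/1 as floats with NaN for occasions not covered by any
    deployment; ``occasions`` maps (site_id, period) to the list of
    (start, end) datetimes of that row's occasions.
    """

    y: np.ndarray                      # (n_sites, n_periods, max_occasions)
    site_ids: list[str]
    periods: list[str]
    occasions: dict[tuple[str, str], list[tuple[dt.datetime, dt.datetime]]] = field(
        default_factory=dict)

    @property
    def n_sites(self) -> int:
        return self.y.shape[0]

    @property
    def n_periods(self) -> int:
        return self.y.shape[1]

    def detections(self) -> np.ndarray:
        """Per (site, period) count of occasions with a detection."""
        return np.nansum(self.y, axis=2)

    def effort(self) -> np.ndarray:
        """Per (site, period) count of non-missing occasions."""
        return np.sum(~np.isnan(self.y), axis=2)

    def to_long(self) -> pd.DataFrame:
        """Long-format (site_id, period, occasion, y) with y missing dropped."""
        ii, tt, jj = np.nonzero(~np.isnan(self.y))
        return pd.DataFrame({
            "site_id": [self.site_ids[i] for i in ii],
            "period": [self.periods[t] for t in tt],
            "occasion": jj,
            "y": self.y[ii, tt, jj].astype(int),
        })

    def write(self, csv_path, calendar_path=None) -> None:
        self.to_long().to_csv(csv_path, index=False)
        if calendar_path is not None:
            cal = {
                f"{s}|{p}": [[a.isoformat(), b.isoformat()] for a, b in occ]
                for (s, p), occ in sorted(self.occasions.items())
            }
            with open(calendar_path, "w") as fh:
                json.dump(cal, fh, indent=1, sort_keys=True)


def filter_independent(records: list[PhotoRecord], window: float = 20.0
                       ) -> list[DetectionEvent]:
    """Collapse photo bursts to independent events.

    ``window`` is in minutes; a photo exactly ``window`` minutes after
    the last kept photo counts as independent ("at least" semantics).
    Records must be sorted by (site, species, timestamp) — the order
    `read_photo_records` returns.
    """
    if window <= 0:
        raise ValueError("independence window must be positive")
    delta = dt.timedelta(minutes=window)
    events: list[DetectionEvent] = []
    last_kept: dict[tuple[str, str], dt.datetime] = {}
    for r in records:
        key = (r.site_id, r.species)
        prev = last_kept.get(key)
        if prev is not None and r.timestamp < prev:
            raise ValueError("records not sorted by (site, species, timestamp)")
        if prev is None or r.timestamp - prev >= delta:
            events.append(DetectionEvent(r.site_id, r.species, r.timestamp))
            last_kept[key] = r.timestamp
    return events


def event_counts(events: list[DetectionEvent]) -> pd.Series:
    """Independent detection count per species."""
    counts = pd.Series([e.species for e in events]).value_counts().sort_index()
    counts.index.name = "species"
    return counts


def tile_occasions(start: dt.date, end: dt.date, occasion_length: int
                   ) -> list[tuple[dt.datetime, dt.datetime]]:
    """Tile [start, end) into consecutive occasions of ``occasion_length``
    days; a trailing partial occasion shorter than half the length is
    dropped, otherwise kept (truncated at the window end)."""
    t0 = dt.datetime.combine(start, dt.time.min)
    t_end = dt.datetime.combine(end, dt.time.min)
    step = dt.timedelta(days=occasion_length)
    out = []
    t = t0
    while t < t_end:
        stop = min(t + step, t_end)
        if stop - t >= step / 2:
            out.append((t, stop))
        t += step
    return out


def build_history(events: list[DetectionEvent], deployments: list[Deployment],
                  periods: list[str], species: str, occasion_length: int = 7
                  ) -> DetectionHistory:
    """Assemble the detection-history array for one species.

    y=1 iff at least one independent event of ``species`` falls inside
    the occasion; undeployed (site, period) rows are all-missing.
    Events outside every deployment window are ignored with a warning.
    """
    if occasion_length < 1:
        raise ValueError("occasion_length must be >= 1 day")
    site_ids = sorted({d.site_id for d in deployments})
    site_idx = {s: i for i, s in enumerate(site_ids)}
    period_idx = {p: t for t, p in enumerate(periods)}

    occasions: dict[tuple[str, str], list[tuple[dt.datetime, dt.datetime]]] = {}
    for d in deployments:
        if d.primary_period not in period_idx:
            raise ValueError(f"deployment period {d.primary_period!r} not in period sequence")
        key = (d.site_id, d.primary_period)
        occasions.setdefault(key, []).extend(
            tile_occasions(d.start, d.end, occasion_length))
    max_j = max((len(v) for v in occasions.values()), default=0)

    y = np.full((len(site_ids), len(periods), max_j), np.nan)
    for (s, p), occ in occasions.items():
        y[site_idx[s], period_idx[p], :len(occ)] = 0.0

    n_outside = 0
    for e in events:
        if e.species != species or e.site_id not in site_idx:
            continue
        placed = False
        for p, occ in ((p, occasions.get((e.site_id, p))) for p in periods):
            if occ is None:
                continue
            for j, (a, b) in enumerate(occ):
                if a <= e.timestamp < b:
                    y[site_idx[e.site_id], period_idx[p], j] = 1.0
                    placed = True
                    break
            if placed:
                break
        if not placed:
            n_outside += 1
    if n_outside:
        logger.warning("build_history: %d events outside all deployment windows ignored",
                       n_outside)
    return DetectionHistory(y=y, site_ids=site_ids, periods=list(periods),
                            occasions=occasions)


def naive_occupancy(history: DetectionHistory) -> pd.Series:
    """Raw per-period proportion of surveyed sites with >= 1 detection.

    A site counts as surveyed in a period if it has >= 1 non-missing
    occasion.  Periods with zero surveyed sites are NaN (flagged).
    """
    surveyed = history.effort() > 0                 # (n_sites, n_periods)
    detected = history.detections() > 0
    n_surveyed = surveyed.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(n_surveyed > 0,
                        (detected & surveyed).sum(axis=0) / np.maximum(n_surveyed, 1),
                        np.nan)
    if (n_surveyed == 0).any():
        empty = [p for p, n in zip(history.periods, n_surveyed) if n == 0]
        logger.warning("naive_occupancy undefined for unsurveyed period(s): %s", empty)
    return pd.Series(prop, index=history.periods, name="naive_occupancy")


def trap_nights(deployments: list[Deployment], basis: str = "camera",
                cameras_per_site: int = 2) -> int:
    """Total trap nights: sum of whole nights across deployments.

    ``basis='camera'`` multiplies site-nights by the number of paired
    cameras (the accounting that matches published totals for
    two-camera designs); ``basis='site'`` counts each site-night once.
    """
    if basis not in ("camera", "site"):
        raise ValueError("basis must be 'camera' or 'site'")
    nights = sum(d.nights for d in deployments)
    return nights * (cameras_per_site if basis == "camera" else 1)
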