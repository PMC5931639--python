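"""Staged sampling of street locations and year-prioritised panorama selection.

The survey design samples image locations from a city's road network in
three stages: one random point on every network link, a simple random
subsample of those points (oversampled 100% relative to the target), and
finally a selection of locations whose archived panoramas fall in the
study years, preferring years closest to the comparison surveys.  Each
selected location contributes two images at opposite compass headings
(0 and 180 degrees) so that fields of view do not overlap.

Sample-size adequacy is judged by stabilisation: the running proportion
of images containing each road-user type, as a function of images
processed, must settle within a tolerance over a trailing window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StreetNetwork",
    "SamplingPlan",
    "StabilisationCurve",
    "sample_link_points",
    "stage2_sample",
    "select_by_year",
    "expand_headings",
    "stabilisation",
]


@dataclass
class StreetNetwork:
    """A city's road network as a list of polyline links.

    ``links`` maps link ids to (k, 2) arrays of planar vertex
    coordinates; every link must have positive length.
    """

    city_id: str
    links: dict

    def __post_init__(self):
        for link_id, coords in self.links.items():
            coords = np.asarray(coords, dtype=float)
            if coords.ndim != 2 or coords.shape[0] < 2 or coords.shape[1] != 2:
                raise ValueError(f"link {link_id!r} is not a polyline")
            self.links[link_id] = coords

    @property
    def n_links(self) -> int:
        return len(self.links)

    def link_length(self, link_id) -> float:
        coords = self.links[link_id]
        return float(np.sum(np.hypot(*np.diff(coords, axis=0).T)))


@dataclass(frozen=True)
class SamplingPlan:
    """Second/third-stage sampling parameters.

    Defaults mirror the survey design: 2000 second-stage locations,
    100% oversampled relative to a target of 1000, year preference
    2011 > 2012 > 2010 > 2009 > 2008, headings 0 and 180 degrees.
    """

    stage2_n: int = 2000
    target_locations: int = 1000
    year_priority: tuple = (2011, 2012, 2010, 2009, 2008)
    headings: tuple = (0, 180)

    def __post_init__(self):
        if self.stage2_n < self.target_locations:
            raise ValueError("stage2_n must be >= target_locations")
        if len(self.year_priority) == 0:
            raise ValueError("year_priority must be non-empty")
        if len(set(self.year_priority)) != len(self.year_priority):
            raise ValueError("year_priority contains duplicates")
        if (self.headings[1] - self.headings[0]) % 360 != 180:
            raise ValueError("headings must differ by 180 degrees")


def sample_link_points(network: StreetNetwork, seed: int) -> pd.DataFrame:
    """One uniformly positioned point per network link (stage 1).

    Returns a frame with ``link_id, x, y`` — exactly one row per link.
    """
    if network.n_links == 0:
        raise ValueError(f"network for {network.city_id!r} has no links")
    rng = np.random.default_rng(seed)
    rows = []
    for link_id, coords in network.links.items():
        seg = np.diff(coords, axis=0)
        seg_len = np.hypot(seg[:, 0], seg[:, 1])
        total = float(seg_len.sum())
        if total <= 0:
            raise ValueError(f"link {link_id!r} has zero length")
        d = rng.uniform(0.0, total)
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        i = int(np.searchsorted(cum, d, side="right")) - 1
        i = min(i, len(seg) - 1)
        frac = (d - cum[i]) / seg_len[i]
        p = coords[i] + frac * seg[i]
        rows.append((link_id, p[0], p[1]))
    return pd.DataFrame(rows, columns=["link_id", "x", "y"])


def stage2_sample(points: pd.DataFrame, plan: SamplingPlan, seed: int) -> pd.DataFrame:
    """Simple random sample without replacement of ``plan.stage2_n`` points."""
    n = len(points)
    if n < plan.stage2_n:
        raise ValueError(
            f"stage-2 sample of {plan.stage2_n} requested but only {n} points "
            f"available (short by {plan.stage2_n - n})"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=plan.stage2_n, replace=False)
    return points.iloc[np.sort(idx)].reset_index(drop=True)


def select_by_year(
    metadata: pd.DataFrame, plan: SamplingPlan, seed: int
) -> tuple[pd.DataFrame, bool]:
    """Year-prioritised selection of one panorama per location (stage 3).

    ``metadata`` has one row per available panorama with columns
    ``location_id, pano_id, year, month`` (locations with no panorama
    simply have no rows).  All locations offering the first priority
    year are taken before any location that only offers the second, and
    so on; when a year rank is only partially needed the filler subset
    is a seeded random draw.  No location is selected twice.

    Returns ``(selected, shortfall)`` where ``shortfall`` flags that
    fewer than ``plan.target_locations`` eligible locations existed (all
    of them are returned in that case).
    """
    rng = np.random.default_rng(seed)
    target = plan.target_locations
    chosen: list[pd.DataFrame] = []
    taken: set = set()
    n_taken = 0
    for year in plan.year_priority:
        if n_taken >= target:
            break
        pool = metadata[(metadata["year"] == year) & ~metadata["location_id"].isin(taken)]
        # one panorama per location within the year
        pool = pool.drop_duplicates(subset="location_id")
        need = target - n_taken
        if len(pool) > need:
            idx = rng.choice(len(pool), size=need, replace=False)
            pool = pool.iloc[np.sort(idx)]
        chosen.append(pool)
        taken.update(pool["location_id"].tolist())
        n_taken += len(pool)
    selected = (
        pd.concat(chosen, ignore_index=True)
        if chosen
        else metadata.iloc[0:0].copy()
    )
    shortfall = n_taken < target
    if shortfall:
        logging.getLogger(__name__).info(
            "only %d eligible locations for a target of %d; returning all",
            n_taken, target,
        )
    return selected.reset_index(drop=True), shortfall


def expand_headings(selected: pd.DataFrame, plan: SamplingPlan) -> pd.DataFrame:
    """Two image rows per selected location, at the plan's opposite headings."""
    frames = []
    for heading in plan.headings:
        f = selected.copy()
        f["heading"] = heading
        frames.append(f)
    out = pd.concat(frames, ignore_index=True)
    out["image_id"] = out["pano_id"].astype(str) + "@" + out["heading"].astype(str)
    return out


@dataclass
class StabilisationCurve:
    """Running per-mode proportions of images with at least one observation."""

    proportions: pd.DataFrame  # one column per mode, row i = after i+1 images
    window: int
    tol: float
    stabilised_at: int | None  # 1-based image count, None if never


def stabilisation(
    presence: pd.DataFrame, window: int = 100, tol: float = 0.005
) -> StabilisationCurve:
    """Stabilisation diagnostic over an ordered stream of image annotations.

    ``presence`` is a boolean frame (rows = images in processing order,
    columns = modes, True = at least one observation).  The stream is
    declared stabilised at the smallest image count ``n >= window`` such
    that, for every mode, the running proportion varies by less than
    ``tol`` (max minus min) over the trailing ``window`` values.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    vals = presence.to_numpy(dtype=float)
    n = len(vals)
    counts = np.arange(1, n + 1)[:, None]
    running = np.cumsum(vals, axis=0) / counts
    stabilised = None
    for i in range(window - 1, n):
        w = running[i - window + 1 : i + 1]
        if np.all(w.max(axis=0) - w.min(axis=0) < tol):
            stabilised = i + 1
            break
    curve = pd.DataFrame(running, columns=presence.columns)
    return StabilisationCurve(curve, window, tol, stabilised)
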