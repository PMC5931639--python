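"""Seeded generator of synthetic study worlds.

The study design — thousands of street images per city, annotated for
road-user presence and related to survey-reported travel patterns —
cannot be rerun without a proprietary image harvest.  This module
replaces the harvest with a fully synthetic world with known ground
truth: latent cities (true mode shares, latent activity levels, a
cyclist gender split), jittered-grid street networks, panorama metadata
with a realistic year/season mix, Poisson image annotations whose rates
are monotone in the latent shares, and noisy Census/APS-style outcome
tables.  Every quantity is reproducible bit-for-bit from a single
global seed, which expands into per-city substreams by stable hashing
of the city id so that adding a city never perturbs the others.

Per-image road-user counts are Poisson with log-rate equal to a mode
base plus a city effect plus a month effect; the survey only ever
recorded count bins, so the Poisson choice is a modelling decision of
this package (the simplest that reproduces the observed bin sparsity).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import aggregation
from .sampling import SamplingPlan, StreetNetwork, sample_link_points, stage2_sample, select_by_year

__all__ = [
    "GeneratorConfig",
    "NoiseConfig",
    "LatentCity",
    "World",
    "generate_world",
    "simulate_annotations",
    "simulate_outcomes",
    "simulate_genders",
    "city_rates",
]

SHARE_MODES = ["walk", "cycle", "bus", "other_pt", "motorcycle", "car"]


@dataclass(frozen=True)
class NoiseConfig:
    """Observation-noise scales for the simulated surveillance outcomes."""

    census_sd: float = 0.15  # logistic-normal SD on the log-share scale
    aps_sd: float = 0.15  # lognormal SD on APS measures
    gender_ratio_sd: float = 0.10

    def validate(self):
        for name in ("census_sd", "aps_sd", "gender_ratio_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"NoiseConfig.{name} must be nonnegative")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-world parameters.

    Defaults emulate the British study conditions: 34 cities, 94%
    panorama availability, a year mix dominated by 2012 and 2011, a
    seasonal image mix with near-zero winter mass, car presence in
    roughly 72% of images and sparse cyclist/bus/motorcycle presence.
    Link counts are lognormal, matched to real network sizes (mean
    ~22,760 links, max ~124,600) and scaled down by ``link_scale`` for
    desk-scale runs; ``plan`` scales the location sample accordingly.
    """

    n_cities: int = 34
    # street networks
    link_log_mean: float = float(np.log(15000.0))
    link_log_sigma: float = 0.9
    link_scale: float = 1.0 / 20.0
    link_floor: int = 1100
    link_cap: int = 124600
    # sampling plan (scaled to match link_scale)
    plan: SamplingPlan = field(
        default_factory=lambda: SamplingPlan(stage2_n=1000, target_locations=500)
    )
    # panorama metadata
    availability: float = 0.94
    year_probs: tuple = ((2011, 0.10), (2012, 0.40), (2010, 0.003), (2009, 0.05), (2008, 0.035))
    recent_years: tuple = (2013, 2014, 2015, 2016, 2017)
    recent_year_prob: float = 0.9
    # latent mode shares
    walk_share_mean: float = 0.127
    walk_share_sd: float = 0.033
    cycle_share_log_mean: float = float(np.log(0.027))
    cycle_share_log_sd: float = 0.7
    cycle_share_min: float = 0.005
    cycle_share_max: float = 0.20
    bus_share_mean: float = 0.106
    bus_share_sd: float = 0.04
    other_pt_share_mean: float = 0.05
    other_pt_share_sd: float = 0.02
    mc_share_mean: float = 0.008
    mc_share_sd: float = 0.003
    population_log_mean: float = float(np.log(340000.0))
    population_log_sd: float = 0.75
    # per-image Poisson rates
    car_presence: float = 0.72
    car_city_sd: float = 0.04  # log-rate city effect SD for cars/vans
    walk_rate_coef: float = 0.9
    cycle_rate_coef: float = 0.26
    pcycle_rate_coef: float = 0.22
    bus_rate: float = 0.0135
    mc_rate: float = 0.0055
    van_rate: float = 0.18
    month_amplitude: float = 0.3  # seasonal log-rate swing for active modes
    # seasonal mix of image months (Dirichlet concentration, Jan..Dec)
    season_concentration: tuple = (
        0.02, 0.02, 1.0, 1.2, 1.2, 1.5, 1.5, 1.5, 1.2, 1.0, 0.8, 0.02
    )
    # outcomes and gender
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    child_fraction: float = 0.19
    gender_a: float = -0.35
    gender_b: float = 0.33  # > 0: male share falls as cycling level rises
    gender_obs_prob: float = 0.55

    def validate(self):
        positive = [
            "n_cities", "link_floor", "link_cap", "link_scale", "link_log_sigma",
            "walk_share_mean", "bus_share_mean", "mc_share_mean",
            "cycle_rate_coef", "walk_rate_coef",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"GeneratorConfig.{name} must be positive")
        probs = [
            "availability", "car_presence", "child_fraction",
            "recent_year_prob", "gender_obs_prob",
        ]
        for name in probs:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"GeneratorConfig.{name} must lie in [0, 1]")
        for year, p in self.year_probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"GeneratorConfig.year_probs[{year}] must lie in [0, 1]")
        if any(c <= 0 for c in self.season_concentration):
            raise ValueError("GeneratorConfig.season_concentration must be positive")
        if len(self.season_concentration) != 12:
            raise ValueError("GeneratorConfig.season_concentration needs 12 entries")
        self.noise.validate()


@dataclass
class LatentCity:
    """Ground truth for one synthetic city."""

    city_id: str
    population: float
    n_links: int
    true_shares: dict  # over SHARE_MODES, sums to 1
    true_aps: dict  # latent prevalence/days/duration measures
    male_cycle_share: float
    season_mix: np.ndarray  # 12 month probabilities
    car_effect: float = 0.0  # log-rate city effect for car/van presence

    def __post_init__(self):
        shares = np.array([self.true_shares[m] for m in SHARE_MODES])
        if np.any(shares < 0):
            raise ValueError(f"{self.city_id}: negative mode share")
        if abs(shares.sum() - 1.0) > 1e-12:
            raise ValueError(f"{self.city_id}: mode shares sum to {shares.sum()!r}, not 1")
        if not 0.0 < self.male_cycle_share < 1.0:
            raise ValueError(f"{self.city_id}: male_cycle_share outside (0, 1)")
        self.season_mix = np.asarray(self.season_mix, dtype=float)
        if abs(self.season_mix.sum() - 1.0) > 1e-9:
            raise ValueError(f"{self.city_id}: season_mix does not sum to 1")
        if self.n_links < 1:
            raise ValueError(f"{self.city_id}: n_links must be >= 1")


@dataclass
class World:
    """A complete synthetic study world."""

    config: GeneratorConfig
    seed: int
    cities: list  # LatentCity
    networks: dict  # city_id -> StreetNetwork
    locations: pd.DataFrame  # stage-1 points + panorama metadata
    selected: pd.DataFrame  # year-selected (location, panorama) pairs
    annotations: pd.DataFrame  # image-level count bins
    outcomes: pd.DataFrame  # city-level Census/APS table (S2 dialect)
    genders: pd.DataFrame  # per-city female/male/child counts

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cities:
            row = {"city_id": c.city_id, "population": c.population,
                   "male_cycle_share": c.male_cycle_share,
                   **{f"true_{m}": c.true_shares[m] for m in SHARE_MODES}}
            rows.append(row)
        return pd.DataFrame(rows).set_index("city_id")

    def to_csv(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.locations.to_csv(directory / "locations.csv", index=False)
        self.selected.to_csv(directory / "selected.csv", index=False)
        self.annotations.to_csv(directory / "annotations.csv", index=False)
        self.outcomes.reset_index().to_csv(directory / "outcomes.csv", index=False)
        self.genders.reset_index().to_csv(directory / "genders.csv", index=False)
        self.truth_frame().reset_index().to_csv(directory / "truth.csv", index=False)


def _substream(seed: int, *labels) -> np.random.Generator:
    """Stable per-purpose RNG: hash the seed and labels into a substream."""
    digest = hashlib.sha256(("/".join(map(str, labels)) + f"#{seed}").encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "big"))


# ---------------------------------------------------------------------------
# Latent cities and networks
# ---------------------------------------------------------------------------

def _draw_latent_city(city_id: str, config: GeneratorConfig, seed: int) -> LatentCity:
    rng = _substream(seed, city_id, "latent")
    walk = float(np.clip(rng.normal(config.walk_share_mean, config.walk_share_sd), 0.05, 0.25))
    cycle = float(np.clip(
        np.exp(rng.normal(config.cycle_share_log_mean, config.cycle_share_log_sd)),
        config.cycle_share_min, config.cycle_share_max,
    ))
    bus = float(np.clip(rng.normal(config.bus_share_mean, config.bus_share_sd), 0.03, 0.30))
    other_pt = float(np.clip(rng.normal(config.other_pt_share_mean, config.other_pt_share_sd), 0.01, 0.15))
    mc = float(np.clip(rng.normal(config.mc_share_mean, config.mc_share_sd), 0.002, 0.02))
    car = max(1.0 - (walk + cycle + bus + other_pt + mc), 0.2)
    shares = np.array([walk, cycle, bus, other_pt, mc, car])
    shares = shares / shares.sum()
    true_shares = dict(zip(["walk", "cycle", "bus", "other_pt", "motorcycle", "car"], shares))
    walk, cycle = true_shares["walk"], true_shares["cycle"]

    def clip01(x):
        return float(np.clip(x, 1e-3, 0.999))

    true_aps = {
        "APS_Prev_All_Cycle": clip01(0.07 + 0.9 * cycle),
        "APS_Prev_Utly_Cycle": clip01(0.015 + 1.1 * cycle),
        "APS_Days_All_Cycle": 0.15 + 4.0 * cycle,
        "APS_Days_Utly_Cycle": 0.04 + 4.5 * cycle,
        "APS_Duration_All_Cycle": 0.20 + 2.5 * cycle,
        "APS_Duration_Utly_Cycle": 0.05 + 2.5 * cycle,
        "APS_Prev_All_Walk": clip01(0.852 + 0.6 * (walk - 0.127)),
        "APS_Prev_Utly_Walk": clip01(0.584 + 1.0 * (walk - 0.127)),
        "APS_Days_All_Walk": 3.56 + 4.0 * (walk - 0.127),
        "APS_Days_Utly_Walk": 2.06 + 5.0 * (walk - 0.127),
        "APS_Duration_All_Walk": 4.14 + 3.0 * (walk - 0.127),
        "APS_Duration_Utly_Walk": 2.65 + 3.0 * (walk - 0.127),
    }
    male_share = float(
        1.0 / (1.0 + np.exp(-(config.gender_a - config.gender_b * np.log(cycle))))
    )
    season_mix = rng.dirichlet(np.asarray(config.season_concentration))
    n_links = int(np.clip(
        np.exp(rng.normal(config.link_log_mean, config.link_log_sigma)),
        None, config.link_cap,
    ) * config.link_scale)
    n_links = max(n_links, config.link_floor)
    population = float(np.exp(rng.normal(config.population_log_mean, config.population_log_sd)))
    car_effect = float(rng.normal(0.0, config.car_city_sd))
    return LatentCity(
        city_id=city_id,
        population=population,
        n_links=n_links,
        true_shares=true_shares,
        true_aps=true_aps,
        male_cycle_share=male_share,
        season_mix=season_mix,
        car_effect=car_effect,
    )


def _build_network(city: LatentCity, seed: int) -> StreetNetwork:
    """Jittered grid street network with exactly ``city.n_links`` links."""
    rng = _substream(seed, city.city_id, "network")
    n = city.n_links
    # an m x m grid graph has 2m(m-1) edges; choose m to overshoot, trim
    m = int(np.ceil((1 + np.sqrt(1 + 2 * n)) / 2)) + 1
    xs = np.arange(m, dtype=float)
    jitter = rng.uniform(-0.35, 0.35, size=(m, m, 2))
    nodes = np.stack(np.meshgrid(xs, xs, indexing="ij"), axis=-1) + jitter
    links: dict[str, np.ndarray] = {}
    k = 0
    for i in range(m):
        for j in range(m):
            for di, dj in ((1, 0), (0, 1)):
                if k >= n:
                    break
                ii, jj = i + di, j + dj
                if ii < m and jj < m:
                    links[f"{city.city_id}_L{k:06d}"] = np.array(
                        [nodes[i, j], nodes[ii, jj]]
                    )
                    k += 1
    return StreetNetwork(city_id=city.city_id, links=links)


def _panorama_metadata(
    city: LatentCity, points: pd.DataFrame, config: GeneratorConfig, seed: int
) -> pd.DataFrame:
    """Per-location availability, years and months of archived panoramas."""
    rng = _substream(seed, city.city_id, "metadata")
    n = len(points)
    available = rng.random(n) < config.availability
    rows = []
    year_probs = list(config.year_probs)
    for idx in range(n):
        loc = points.iloc[idx]
        if not available[idx]:
            continue
        years = [y for y, p in year_probs if rng.random() < p]
        if rng.random() < config.recent_year_prob or not years:
            years.append(int(rng.choice(config.recent_years)))
        for year in sorted(set(years)):
            month = int(rng.choice(12, p=city.season_mix)) + 1
            rows.append(
                (city.city_id, loc["link_id"], loc["x"], loc["y"],
                 f"{loc['link_id']}_{year}", year, month)
            )
    return pd.DataFrame(
        rows,
        columns=["city_id", "location_id", "x", "y", "pano_id", "year", "month"],
    )


# ---------------------------------------------------------------------------
# Annotations, outcomes, genders
# ---------------------------------------------------------------------------

def city_rates(city: LatentCity, config: GeneratorConfig) -> dict:
    """Per-image base Poisson rates per mode, derived from latent shares."""
    s = city.true_shares
    boost = float(np.exp(city.car_effect))
    return {
        "pedestrian": config.walk_rate_coef * s["walk"],
        "cyclist": config.cycle_rate_coef * s["cycle"],
        "parked_cycle": config.pcycle_rate_coef * s["cycle"],
        "car": -np.log1p(-config.car_presence) * boost,
        "motorcycle": config.mc_rate * s["motorcycle"] / 0.008,
        "bus": config.bus_rate * s["bus"] / 0.106,
        "van_truck": config.van_rate * boost,
    }


#: seasonal log-rate amplitude per mode (active modes peak in July)
_MONTH_AMP = {"pedestrian": 0.5, "cyclist": 1.0, "parked_cycle": 0.5}


def _month_factor(mode: str, months: np.ndarray, amplitude: float) -> np.ndarray:
    amp = amplitude * _MONTH_AMP.get(mode, 0.0)
    return np.exp(amp * np.cos(2.0 * np.pi * (months - 7) / 12.0))


def simulate_annotations(
    city: LatentCity,
    panoramas: pd.DataFrame,
    seed: int,
    config: GeneratorConfig | None = None,
    headings: tuple = (0, 180),
) -> pd.DataFrame:
    """Image-level count-bin annotations for the selected panoramas.

    Each panorama yields one image per heading; per-image counts are
    Poisson with rate = mode base rate x month factor, then collapsed
    into the annotation bins.
    """
    config = config or GeneratorConfig()
    rng = _substream(seed, city.city_id, "annotations")
    rates = city_rates(city, config)
    frames = []
    months = panoramas["month"].to_numpy(dtype=float)
    for heading in headings:
        frame = pd.DataFrame(
            {
                "image_id": panoramas["pano_id"].astype(str) + f"@{heading}",
                "city_id": city.city_id,
                "heading": heading,
                "year": panoramas["year"].to_numpy(),
                "month": panoramas["month"].to_numpy(),
            }
        )
        for mode in aggregation.MODES:
            lam = rates[mode] * _month_factor(mode, months, config.month_amplitude)
            counts = rng.poisson(lam)
            frame[mode] = [aggregation.count_to_bin(c) for c in counts]
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def simulate_outcomes(
    city: LatentCity, noise: NoiseConfig, seed: int
) -> dict:
    """One Census/APS outcome row for a city.

    Census shares are a logistic-normal perturbation of the true shares
    (noise 0 returns them exactly); APS measures apply lognormal noise
    to the latent activity values, truncated to valid ranges.
    """
    rng = _substream(seed, city.city_id, "outcomes")
    shares = np.array([city.true_shares[m] for m in SHARE_MODES])
    z = np.log(shares) + rng.normal(0.0, noise.census_sd, size=len(shares))
    s = np.exp(z)
    s = s / s.sum()
    obs = dict(zip(SHARE_MODES, s))
    row = {
        "city_id": city.city_id,
        "Census_Walk": 100.0 * obs["walk"],
        "Census_Cycle": 100.0 * obs["cycle"],
        "Census_MC": 100.0 * obs["motorcycle"],
        "Census_Bus": 100.0 * obs["bus"],
        "Census_PTWalk": 100.0 * (obs["walk"] + obs["bus"] + obs["other_pt"]),
        "Census_Car": 100.0 * obs["car"],
    }
    m = city.male_cycle_share
    base_ratio = m / (1.0 - m)
    row["Census_Cycle_MF"] = base_ratio * float(np.exp(rng.normal(0, noise.gender_ratio_sd)))
    for name, latent in city.true_aps.items():
        noisy = latent * float(np.exp(rng.normal(0.0, noise.aps_sd)))
        if name.startswith("APS_Prev"):
            noisy = float(np.clip(noisy, 1e-3, 0.999))
            row[name] = 100.0 * noisy
        else:
            row[name] = max(noisy, 1e-3)
    row["APS_Prev_All_Cycle_MF"] = base_ratio * float(np.exp(rng.normal(0, noise.gender_ratio_sd)))
    row["APS_Prev_Utly_Cycle_MF"] = base_ratio * float(np.exp(rng.normal(0, noise.gender_ratio_sd)))
    return row


def simulate_genders(
    city: LatentCity,
    n_cyclist_images: int,
    seed: int,
    child_fraction: float = 0.19,
) -> pd.Series:
    """Gender labels for observed cyclists (male/female/child).

    Children occur with the configured fraction; adults are male with
    the city's latent male cycling share.
    """
    rng = _substream(seed, city.city_id, "genders")
    labels = np.where(
        rng.random(n_cyclist_images) < child_fraction,
        "child",
        np.where(rng.random(n_cyclist_images) < city.male_cycle_share, "male", "female"),
    )
    return pd.Series(labels, name="gender")


# ---------------------------------------------------------------------------
# The full world
# ---------------------------------------------------------------------------

def generate_world(config: GeneratorConfig, seed: int) -> World:
    """Generate a complete study world: cities, networks, panorama
    metadata, staged location samples, annotations, outcomes, genders.

    Deterministic given ``(config, seed)``; per-city randomness comes
    from substreams hashed on the city id.
    """
    config.validate()
    cities, networks = [], {}
    loc_frames, sel_frames, ann_frames, out_rows, gender_rows = [], [], [], [], []
    for i in range(config.n_cities):
        city_id = f"C{i:02d}"
        city = _draw_latent_city(city_id, config, seed)
        network = _build_network(city, seed)
        stage1 = sample_link_points(network, seed=_substream(seed, city_id, "points").integers(2**31))
        meta = _panorama_metadata(city, stage1, config, seed)
        # record availability for every stage-1 point
        stage1 = stage1.assign(
            city_id=city_id,
            available=stage1["link_id"].isin(set(meta["location_id"])),
        )
        stage2 = stage2_sample(stage1, config.plan, seed=_substream(seed, city_id, "stage2").integers(2**31))
        meta2 = meta[meta["location_id"].isin(set(stage2["link_id"]))]
        selected, _short = select_by_year(
            meta2, config.plan, seed=_substream(seed, city_id, "select").integers(2**31)
        )
        ann = simulate_annotations(city, selected, seed, config, headings=config.plan.headings)
        outcome = simulate_outcomes(city, config.noise, seed)
        n_cyclist_images = int((ann["cyclist"] != "0").sum())
        rng_g = _substream(seed, city_id, "gender_n")
        n_obs = int(rng_g.binomial(n_cyclist_images, config.gender_obs_prob))
        labels = simulate_genders(city, n_obs, seed, config.child_fraction)
        gender_rows.append(
            {
                "city_id": city_id,
                "females": int((labels == "female").sum()),
                "males": int((labels == "male").sum()),
                "children": int((labels == "child").sum()),
            }
        )
        cities.append(city)
        networks[city_id] = network
        loc_frames.append(stage1)
        sel_frames.append(selected)
        ann_frames.append(ann)
        out_rows.append(outcome)
    locations = pd.concat(loc_frames, ignore_index=True)
    selected = pd.concat(sel_frames, ignore_index=True)
    annotations = pd.concat(ann_frames, ignore_index=True)
    outcomes = pd.DataFrame(out_rows).set_index("city_id")
    genders = pd.DataFrame(gender_rows).set_index("city_id")
    return World(
        config=config,
        seed=seed,
        cities=cities,
        networks=networks,
        locations=locations,
        selected=selected,
        annotations=annotations,
        outcomes=outcomes,
        genders=genders,
    )
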