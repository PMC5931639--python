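"""Census and Active People Survey (APS) outcome tables.

The unit of analysis is the primary urban area (PUA), a city-region
built from one or more local authorities.  Census travel-to-work counts
are pooled across a PUA's local authorities before mode shares are
computed; APS measures, being population-representative rates, are
combined as population-weighted means.

Mode shares are percents of commuters, excluding those who work from
home: car combines driving, passenger and taxi; PT+Walk combines walk,
bus, underground and train.  Gender ratios are male prevalence (or mode
share) over female prevalence.

The module also reads and writes the city-level CSV dialect used for
the deposited study dataset (one row per city carrying Census shares,
APS measures and the street-imagery predictor block), with
case/punctuation-insensitive header matching.
"""

from __future__ import annotations

import logging
import re
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CENSUS_COLUMNS",
    "APS_COLUMNS",
    "GSV_COUNT_COLUMNS",
    "compute_mode_shares",
    "aggregate_to_pua",
    "gender_ratio",
    "read_s2",
    "write_s2",
    "S2Data",
]

CENSUS_COLUMNS = [
    "Census_Walk",
    "Census_Cycle",
    "Census_MC",
    "Census_Bus",
    "Census_PTWalk",
    "Census_Car",
    "Census_Cycle_MF",
]

_APS_MEASURES = ["Prev", "Days", "Duration"]
_APS_GROUPS = ["All", "Utly"]
_APS_MODES = ["Cycle", "Walk"]
APS_COLUMNS = [
    f"APS_{m}_{g}_{md}" for md in _APS_MODES for g in _APS_GROUPS for m in _APS_MEASURES
] + ["APS_Prev_All_Cycle_MF", "APS_Prev_Utly_Cycle_MF"]

GSV_COUNT_COLUMNS = ["GSV_Walk", "GSV_Cycle", "GSV_PCycle", "GSV_Car", "GSV_Bus", "GSV_MC"]

#: Commuter-count keys; ``car`` is accepted as an alias for car_driver.
_MODE_KEYS = [
    "walk", "cycle", "motorcycle", "bus", "underground", "train",
    "car_driver", "car_passenger", "taxi", "other",
]
_ALIASES = {"car": "car_driver", "mc": "motorcycle", "home": "work_from_home"}
_HOME_KEYS = {"work_from_home"}


def _canonical_counts(counts: Mapping[str, float]) -> dict:
    out: dict[str, float] = {}
    for key, value in counts.items():
        k = _ALIASES.get(key.lower(), key.lower())
        if k not in _MODE_KEYS and k not in _HOME_KEYS:
            raise KeyError(f"unknown commute mode {key!r}")
        if value < 0:
            raise ValueError(f"negative count for {key!r}")
        out[k] = out.get(k, 0.0) + float(value)
    return out


def compute_mode_shares(counts: Mapping[str, float]) -> dict:
    """Census commute mode shares (percent) from commuter counts.

    The denominator is all commuters excluding home-workers.  Car is
    driving + passenger + taxi; PT+Walk is walk + bus + underground +
    train.
    """
    c = _canonical_counts(counts)
    denom = sum(v for k, v in c.items() if k not in _HOME_KEYS)
    if denom <= 0:
        raise ValueError("no commuters outside the home-worker category")

    def share(*keys):
        return 100.0 * sum(c.get(k, 0.0) for k in keys) / denom

    return {
        "Census_Walk": share("walk"),
        "Census_Cycle": share("cycle"),
        "Census_MC": share("motorcycle"),
        "Census_Bus": share("bus"),
        "Census_PTWalk": share("walk", "bus", "underground", "train"),
        "Census_Car": share("car_driver", "car_passenger", "taxi"),
    }


def aggregate_to_pua(la_records: pd.DataFrame) -> pd.DataFrame:
    """Pool local-authority records to PUA level.

    Expects one row per local authority with ``la_id``, ``pua_id``, raw
    commuter-count columns named ``count_<mode>`` (plus optional
    ``count_work_from_home``), a ``population`` weight and optional
    APS_* measure columns.  Census counts are summed before shares are
    computed; APS measures become population-weighted means.
    """
    if la_records["pua_id"].isna().any():
        bad = la_records.loc[la_records["pua_id"].isna(), "la_id"].tolist()
        raise ValueError(f"local authorities with unknown PUA: {bad}")
    count_cols = [c for c in la_records.columns if c.startswith("count_")]
    aps_cols = [c for c in la_records.columns if c.startswith("APS_")]
    rows = []
    for pua, grp in la_records.groupby("pua_id", sort=True):
        counts = {c.removeprefix("count_"): grp[c].sum() for c in count_cols}
        row = {"pua_id": pua, **compute_mode_shares(counts)}
        if aps_cols:
            w = grp["population"].to_numpy(dtype=float)
            if w.sum() <= 0:
                raise ValueError(f"PUA {pua!r} has zero total population weight")
            for c in aps_cols:
                v = grp[c].to_numpy(dtype=float)
                mask = ~np.isnan(v)
                row[c] = (
                    float(np.average(v[mask], weights=w[mask])) if mask.any() else np.nan
                )
        rows.append(row)
    return pd.DataFrame(rows).set_index("pua_id")


def gender_ratio(male_measure: float, female_measure: float) -> float:
    """Male-to-female ratio of a prevalence or mode share.

    A zero (or negative) female measure yields NaN — the ratio is
    flagged undefined rather than infinite.
    """
    if female_measure <= 0:
        return float("nan")
    return float(male_measure) / float(female_measure)


# ---------------------------------------------------------------------------
# City-level CSV dialect
# ---------------------------------------------------------------------------

class S2Data(NamedTuple):
    """City-level table split into predictor and outcome blocks."""

    frame: pd.DataFrame  # everything, canonical column names
    gsv: pd.DataFrame  # street-imagery predictor block
    outcomes: pd.DataFrame  # Census + APS block with aps_available flag


def _normalise(name: str) -> str:
    return re.sub(r"[^a-z0-9]", "", name.lower())


_CANONICAL = (
    ["city_id"]
    + CENSUS_COLUMNS
    + APS_COLUMNS
    + GSV_COUNT_COLUMNS
    + [f"GSV_{m}" for m in ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
                            "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]]
    + ["GSV_Spring", "GSV_Summer", "GSV_Autumn", "GSV_Winter"]
)

_MANDATORY = ["city_id"] + CENSUS_COLUMNS[:6] + GSV_COUNT_COLUMNS

#: percent-scale columns used for range warnings
_PERCENT_COLUMNS = CENSUS_COLUMNS[:6] + [
    c for c in APS_COLUMNS if c.startswith("APS_Prev") and not c.endswith("_MF")
]


def read_s2(path, column_map: Mapping[str, str] | None = None) -> S2Data:
    """Read a city-level feature/outcome CSV.

    Header matching is case- and punctuation-insensitive; an optional
    ``column_map`` (raw header -> canonical name) handles anything the
    normalisation cannot.  Cities whose APS block is entirely missing
    (non-English cities) get ``aps_available = False``.
    """
    raw = pd.read_csv(path)
    if raw.empty:
        raise ValueError(f"{path}: no city rows found")
    lookup = {_normalise(c): c for c in _CANONICAL}
    lookup.setdefault("city", "city_id")
    lookup.setdefault("pua", "city_id")
    lookup.setdefault("puaid", "city_id")
    rename = {}
    for col in raw.columns:
        if column_map and col in column_map:
            rename[col] = column_map[col]
        else:
            canon = lookup.get(_normalise(col))
            if canon:
                rename[col] = canon
    df = raw.rename(columns=rename)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    aps_present = [c for c in APS_COLUMNS if c in df.columns]
    if aps_present:
        df["aps_available"] = df[aps_present].notna().any(axis=1)
    else:
        df["aps_available"] = False
    for col in _PERCENT_COLUMNS:
        if col in df.columns:
            v = pd.to_numeric(df[col], errors="coerce")
            bad = v.dropna()[(v.dropna() < 0) | (v.dropna() > 100)]
            if len(bad):
                logger.warning("%s: %d out-of-range values in %s", path, len(bad), col)
    gsv_cols = [c for c in df.columns if c.startswith("GSV_")]
    outcome_cols = [c for c in df.columns if c.startswith(("Census_", "APS_"))]
    gsv = df[["city_id"] + gsv_cols].set_index("city_id")
    outcomes = df[["city_id"] + outcome_cols + ["aps_available"]].set_index("city_id")
    return S2Data(df.set_index("city_id"), gsv, outcomes)


def write_s2(frame: pd.DataFrame, path) -> None:
    """Write a city-level table in the same dialect ``read_s2`` accepts."""
    out = frame.reset_index() if frame.index.name == "city_id" else frame
    out.to_csv(path, index=False)
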