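"""Cyclist gender-split analysis.

City-level gender observations of cyclists are sparse, so cities are
pooled: sorted in ascending order of the Census male/female commuter
cycling ratio, then partitioned into a small number of contiguous
groups chosen so that gender ratios within a group are similar and the
observation totals across groups are as balanced as possible.  Each
group's image-observed ratio (pooled males over pooled females) is then
compared with observation-weighted averages of the survey-reported
ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "GenderObservations",
    "partition_cities",
    "group_ratios",
    "weighted_average_ratio",
    "gender_split_table",
]


@dataclass(frozen=True)
class GenderObservations:
    """Per-city cyclist gender counts (children already excluded)."""

    city_id: str
    females: int
    males: int
    children_excluded: int = 0

    def __post_init__(self):
        for name in ("females", "males", "children_excluded"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a nonnegative integer")

    @property
    def total(self) -> int:
        return self.females + self.males


def partition_cities(observations: pd.DataFrame, k: int = 4) -> pd.DataFrame:
    """Optimal contiguous partition of ratio-sorted cities into ``k`` groups.

    ``observations`` must carry one row per city with ``females``,
    ``males`` and a ``census_ratio`` column, already sorted ascending by
    that ratio (the function sorts defensively).  All contiguous
    partitions are enumerated; the one minimising the variance of group
    observation totals wins, with the summed within-group ratio range as
    tie-breaker.  Returns the frame with a ``group`` column (1-based).
    """
    obs = observations.sort_values("census_ratio", kind="stable").copy()
    n = len(obs)
    if k > n:
        raise ValueError(f"cannot split {n} cities into {k} groups")
    totals = (obs["females"] + obs["males"]).to_numpy(dtype=float)
    ratios = obs["census_ratio"].to_numpy(dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(totals)])
    best = None
    for cuts in combinations(range(1, n), k - 1):
        bounds = (0, *cuts, n)
        group_totals = np.diff(cum[list(bounds)])
        var = float(np.var(group_totals))
        spread = float(
            sum(ratios[b - 1] - ratios[a] for a, b in zip(bounds[:-1], bounds[1:]))
        )
        key = (var, spread, cuts)
        if best is None or key < best[0]:
            best = (key, bounds)
    bounds = best[1]
    group = np.empty(n, dtype=int)
    for g, (a, b) in enumerate(zip(bounds[:-1], bounds[1:]), start=1):
        group[a:b] = g
    obs["group"] = group
    return obs


def group_ratios(groups: pd.DataFrame) -> pd.Series:
    """Pooled male/female ratio per group: sum(males) / sum(females).

    Groups with zero females get NaN (undefined, not infinite).
    """
    agg = groups.groupby("group")[["females", "males"]].sum()
    ratio = agg["males"] / agg["females"].replace(0, np.nan)
    return ratio.rename("gsv_ratio")


def weighted_average_ratio(ratios, weights) -> float:
    """Observation-weighted mean of per-city survey ratios."""
    r = np.asarray(ratios, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if w.sum() <= 0:
        raise ValueError("weights must not all be zero")
    return float(np.sum(w * r) / np.sum(w))


def gender_split_table(
    observations: pd.DataFrame,
    survey_ratios: pd.DataFrame | None = None,
    k: int = 4,
) -> pd.DataFrame:
    """Full gender-split comparison table.

    ``observations``: per-city females/males/census_ratio (sorted or
    not).  ``survey_ratios`` optionally adds per-city survey ratio
    columns (any column ending in ``_MF``) to be observation-weighted
    into group averages.  Returns one row per group plus an ``All`` row.
    """
    parts = partition_cities(observations, k=k)
    if survey_ratios is not None:
        parts = parts.join(survey_ratios, how="left")
    ratio_cols = [c for c in parts.columns if c.endswith("_MF")] + ["census_ratio"]
    rows = []
    weights = parts["females"] + parts["males"]
    for label, grp in [("All", parts)] + [
        (f"Group {g}", parts[parts["group"] == g]) for g in sorted(parts["group"].unique())
    ]:
        row = {
            "group": label,
            "females": int(grp["females"].sum()),
            "males": int(grp["males"].sum()),
        }
        f = row["females"]
        row["gsv_ratio"] = row["males"] / f if f > 0 else np.nan
        w = weights.loc[grp.index]
        for col in ratio_cols:
            vals = grp[col]
            mask = vals.notna() & (w > 0)
            row[f"weighted_{col}"] = (
                weighted_average_ratio(vals[mask], w[mask]) if mask.any() else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")
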