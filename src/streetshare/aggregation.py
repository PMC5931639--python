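"""City-level feature construction from image-level annotations.

Annotators record, for every image, a count bin per road-user category
(0, 1-3, 4-6, >6 for pedestrians, cyclists, parked cycles, cars,
motorcycles, buses and vans/trucks).  Because the non-zero bins are
sparse for most categories, modelling uses only the number of images
per city with at least one observation of each mode — the "presence
counts" GSV_Walk, GSV_Cycle, GSV_PCycle, GSV_Car, GSV_Bus and GSV_MC
(vans/trucks are tallied but excluded from the predictor block).

Alongside the counts, this module computes the monthly distribution of
each city's images (GSV_Jan ... GSV_Dec, in percent), seasonal shares,
bootstrap standard deviations of the presence counts, and cross-city
coefficients of variation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "MODES",
    "BIN_LABELS",
    "FEATURE_NAMES",
    "MONTH_COLUMNS",
    "SEASONS",
    "collapse_counts",
    "monthly_proportions",
    "bootstrap_sd",
    "coefficient_of_variation",
    "car_bin_diagnostic",
    "build_feature_table",
    "count_to_bin",
]

MODES = ["pedestrian", "cyclist", "parked_cycle", "car", "motorcycle", "bus", "van_truck"]
BIN_LABELS = ["0", "1-3", "4-6", ">6"]

#: Predictor-block feature name per mode; vans/trucks deliberately absent.
FEATURE_NAMES = {
    "pedestrian": "GSV_Walk",
    "cyclist": "GSV_Cycle",
    "parked_cycle": "GSV_PCycle",
    "car": "GSV_Car",
    "motorcycle": "GSV_MC",
    "bus": "GSV_Bus",
}

_MONTHS = ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
           "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]
MONTH_COLUMNS = [f"GSV_{m}" for m in _MONTHS]

SEASONS = {
    "GSV_Spring": (3, 4, 5),
    "GSV_Summer": (6, 7, 8),
    "GSV_Autumn": (9, 10, 11),
    "GSV_Winter": (12, 1, 2),
}


def count_to_bin(count: int) -> str:
    """Collapse a raw per-image count into its annotation bin."""
    if count <= 0:
        return "0"
    if count <= 3:
        return "1-3"
    if count <= 6:
        return "4-6"
    return ">6"


def _presence(annotations: pd.DataFrame, modes=MODES) -> pd.DataFrame:
    """Boolean presence (bin != "0") per image and mode, validating bins."""
    out = {}
    for mode in modes:
        col = annotations[mode]
        bad = ~col.isin(BIN_LABELS)
        if bad.any():
            image = annotations.loc[bad, "image_id"].iloc[0]
            raise ValueError(
                f"unknown bin label {col[bad].iloc[0]!r} for mode {mode!r} "
                f"in image {image!r}"
            )
        out[mode] = col != "0"
    return pd.DataFrame(out, index=annotations.index)


def collapse_counts(annotations: pd.DataFrame) -> pd.DataFrame:
    """Per-city presence counts: number of images with >= 1 observation.

    ``annotations`` carries one row per image with a bin-label column
    per mode plus ``image_id`` and ``city_id``.  Returns a frame indexed
    by city with the GSV_* predictor columns, a ``van_truck_images``
    tally and the total image count ``n_images``.
    """
    pres = _presence(annotations)
    pres["city_id"] = annotations["city_id"].to_numpy()
    grouped = pres.groupby("city_id", sort=True).sum()
    out = pd.DataFrame(index=grouped.index)
    for mode, feat in FEATURE_NAMES.items():
        out[feat] = grouped[mode].astype(int)
    out["van_truck_images"] = grouped["van_truck"].astype(int)
    out["n_images"] = annotations.groupby("city_id", sort=True).size()
    return out


def monthly_proportions(annotations: pd.DataFrame) -> pd.DataFrame:
    """Monthly percents of each city's images, plus seasonal shares.

    Images with a missing month are excluded here (they still count in
    the presence tallies).  Monthly percents sum to 100 per city.
    """
    ann = annotations.dropna(subset=["month"])
    month = ann["month"].astype(int)
    if ((month < 1) | (month > 12)).any():
        raise ValueError("month values must lie in 1..12")
    counts = (
        pd.crosstab(ann["city_id"], month)
        .reindex(columns=range(1, 13), fill_value=0)
    )
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    pct.columns = MONTH_COLUMNS
    for season, months in SEASONS.items():
        pct[season] = sum(pct[MONTH_COLUMNS[m - 1]] for m in months)
    return pct


def bootstrap_sd(
    city_annotations: pd.DataFrame,
    B: int = 5000,
    n: int = 2000,
    seed: int = 0,
    modes=tuple(FEATURE_NAMES),
    chunk: int = 1000,
) -> pd.Series:
    """Bootstrap SD of per-mode presence counts for one city.

    Resamples ``n`` images with replacement ``B`` times and returns the
    standard deviation (across replicates, population convention) of the
    presence count for each mode, indexed by feature name.
    """
    if len(city_annotations) == 0:
        raise ValueError("cannot bootstrap an empty city")
    pres = _presence(city_annotations, modes=list(modes)).to_numpy()
    N = pres.shape[0]
    rng = np.random.default_rng(seed)
    sums = np.zeros((B, pres.shape[1]), dtype=np.int64)
    done = 0
    while done < B:
        b = min(chunk, B - done)
        idx = rng.integers(0, N, size=(b, n))
        sums[done : done + b] = pres[idx].sum(axis=1)
        done += b
    sd = sums.std(axis=0, ddof=0)
    return pd.Series(sd, index=[FEATURE_NAMES[m] for m in modes])


def coefficient_of_variation(values) -> float:
    """Cross-city coefficient of variation: sample SD (n-1) over mean."""
    x = np.asarray(values, dtype=float)
    mean = x.mean()
    if mean == 0:
        raise ValueError("coefficient of variation undefined for zero mean")
    return float(x.std(ddof=1) / mean)


def car_bin_diagnostic(annotations: pd.DataFrame) -> pd.DataFrame:
    """Cross-city variability of the car count-bin distribution.

    For each non-zero car bin, reports the per-city proportion of images
    in that bin and its cross-city CV.  A diagnostic report only — the
    bin magnitudes are deliberately not used in modelling.
    """
    shares = (
        pd.crosstab(annotations["city_id"], annotations["car"], normalize="index")
        .reindex(columns=BIN_LABELS, fill_value=0.0)
    )
    rows = []
    for b in BIN_LABELS[1:]:
        col = shares[b]
        cv = coefficient_of_variation(col) if col.mean() > 0 else np.nan
        rows.append({"bin": b, "mean_share": col.mean(), "cv": cv})
    return pd.DataFrame(rows).set_index("bin")


def build_feature_table(
    annotations: pd.DataFrame,
    *,
    bootstrap: bool = False,
    B: int = 5000,
    n: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Full per-city predictor block: presence counts, monthly percents,
    seasonal shares and (optionally) bootstrap SDs."""
    counts = collapse_counts(annotations)
    months = monthly_proportions(annotations)
    table = counts.join(months, how="left")
    if bootstrap:
        sds = {}
        for city, grp in annotations.groupby("city_id", sort=True):
            sds[city] = bootstrap_sd(grp, B=B, n=n, seed=seed)
        sd_frame = pd.DataFrame(sds).T
        sd_frame.columns = [f"{c}_sd" for c in sd_frame.columns]
        table = table.join(sd_frame)
    return table
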