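"""End-to-end pipeline orchestration and descriptive reporting.

Two run modes:

* ``synthetic`` — generate a seeded synthetic world, aggregate its image
  annotations into the city-level predictor block, join the simulated
  surveillance outcomes, and run the correlation matrix, the final model
  set and the gender-split analysis.

* ``s2`` — load a deposited city-level CSV (real study data) and run the
  same analysis stages on it, with gender observations supplied as a
  fixture CSV.

Every bundle is written with a run manifest (seed, config hash, file
list) so a run can be reproduced exactly; stage failures abort the run
and remove partial outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import aggregation, gender, outcomes, selection, synthetic

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "summarise_descriptives"]


@dataclass
class PipelineConfig:
    mode: str = "synthetic"  # or "s2"
    out_dir: str | Path = "streetshare_run"
    seed: int = 0
    generator: synthetic.GeneratorConfig = field(default_factory=synthetic.GeneratorConfig)
    data_path: str | Path | None = None  # s2 mode
    gender_path: str | Path | None = None  # optional gender fixture CSV
    bootstrap: bool = False  # per-city bootstrap SDs (slower)

    def validate(self):
        if self.mode not in ("synthetic", "s2"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "s2" and self.data_path is None:
            raise ValueError("s2 mode requires data_path")

    def digest(self) -> str:
        payload = repr(dataclasses.asdict(self)).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def summarise_descriptives(table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Descriptive statistics per variable: mean, SD (sample), min,
    quartiles by linear interpolation, median, max."""
    if len(table) < 2:
        raise ValueError("need at least 2 cities to summarise")
    cols = columns or [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    rows = {}
    for c in cols:
        v = table[c].dropna().astype(float)
        rows[c] = {
            "mean": v.mean(),
            "sd": v.std(ddof=1),
            "min": v.min(),
            "p25": v.quantile(0.25, interpolation="linear"),
            "median": v.quantile(0.50, interpolation="linear"),
            "p75": v.quantile(0.75, interpolation="linear"),
            "max": v.max(),
        }
    return pd.DataFrame(rows).T


def _stage(name, fn, *args, **kwargs):
    logger.info("stage %s: starting", name)
    try:
        result = fn(*args, **kwargs)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    try:
        n = len(result)
        logger.info("stage %s: done (%d rows)", name, n)
    except TypeError:
        logger.info("stage %s: done", name)
    return result


def _city_table_synthetic(config: PipelineConfig):
    world = _stage("generate", synthetic.generate_world, config.generator, config.seed)
    features = _stage(
        "aggregate",
        aggregation.build_feature_table,
        world.annotations,
        bootstrap=config.bootstrap,
        seed=config.seed,
    )
    table = features.join(world.outcomes, how="inner")
    table.index.name = "city_id"
    gender_obs = world.genders.join(
        world.outcomes["Census_Cycle_MF"].rename("census_ratio")
    )
    survey = world.outcomes[[c for c in world.outcomes.columns if c.endswith("_MF")]]
    return world, table, gender_obs, survey


def _city_table_s2(config: PipelineConfig):
    path = Path(config.data_path)
    if not path.exists():
        raise FileNotFoundError(f"city-level data file not found: {path}")
    s2 = _stage("read", outcomes.read_s2, path)
    table = s2.frame
    gender_obs = None
    if config.gender_path:
        gpath = Path(config.gender_path)
        if not gpath.exists():
            raise FileNotFoundError(f"gender fixture not found: {gpath}")
        gender_obs = pd.read_csv(gpath).set_index("city_id")
        gender_obs = gender_obs.join(table["Census_Cycle_MF"].rename("census_ratio"))
    survey = table[[c for c in table.columns if c.endswith("_MF")]]
    return None, table, gender_obs, survey


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured pipeline and write the report bundle.

    Returns the in-memory artefacts; writes CSV/JSON outputs plus a
    ``manifest.json`` carrying the seed and config hash.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    try:
        if config.mode == "synthetic":
            world, table, gender_obs, survey = _city_table_synthetic(config)
        else:
            world, table, gender_obs, survey = _city_table_s2(config)

        artefacts: dict = {"city_table": table}
        gsv_cols = [c for c in outcomes.GSV_COUNT_COLUMNS if c in table.columns]
        out_cols = [c for c in table.columns if c.startswith(("Census_", "APS_"))
                    and not c.endswith("_MF")]
        corr = _stage("correlate", selection.correlation_matrix, table, gsv_cols + out_cols)
        table2 = _stage("fit", selection.fit_final_models, table)
        artefacts["correlations"] = corr
        artefacts["table2"] = table2
        descr = _stage("describe", summarise_descriptives, table)
        artefacts["descriptives"] = descr
        if gender_obs is not None:
            gtab = _stage("gender", gender.gender_split_table, gender_obs, survey)
            artefacts["gender"] = gtab

        table.to_csv(out / "city_table.csv")
        corr.to_csv(out / "correlations.csv")
        table2.to_csv(out / "table2.csv")
        descr.to_csv(out / "descriptives.csv")
        written += ["city_table.csv", "correlations.csv", "table2.csv", "descriptives.csv"]
        if gender_obs is not None:
            artefacts["gender"].to_csv(out / "gender_split.csv")
            written.append("gender_split.csv")
        if world is not None:
            world.to_csv(out / "world")
            written.append("world/")
            artefacts["world"] = world
        manifest = {
            "mode": config.mode,
            "seed": config.seed,
            "config_hash": config.digest(),
            "artifacts": written,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        artefacts["manifest"] = manifest
        return artefacts
    except Exception:
        # remove partial outputs so a failed run leaves nothing behind
        for name in written:
            target = out / name
            if target.is_dir():
                shutil.rmtree(target, ignore_errors=True)
            elif target.exists():
                target.unlink()
        raise
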