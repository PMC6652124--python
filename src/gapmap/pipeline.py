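"""End-to-end orchestration: clean → simulate → distances → loads → report.

A single :class:`RunConfig` drives the whole analysis and a run manifest
(input checksums, parameters, seed, library versions) is written next to
the outputs, so a report bundle is reproducible byte-for-byte from its
manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .access_metrics import (
    aggregate_to_state,
    county_mean_distances,
    density_grid,
    plot_density_grid,
    rank_regions,
)
from .io import (
    frame_from_records,
    read_counties_csv,
    read_resources_csv,
    records_from_frame,
    resources_to_geojson,
)
from .keywords import CATEGORIES, DEFAULT_KEYWORD_MAP, KeywordMap
from .population_sim import DEFAULT_PREVALENCE_DENOMINATOR, simulate_national
from .resource_db import DEFAULT_DEDUP_PRECISION, category_breakdown, process_resources
from .resource_load import count_counties_without_category, resource_load_table
from .synthetic_data import SyntheticConfig, generate_world, strip_truth


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Exactly one input source: either ``resources_csv`` + ``counties_csv``,
    or ``synth`` (a SyntheticConfig) to generate both.
    """

    out_dir: str | Path
    resources_csv: str | Path | None = None
    counties_csv: str | Path | None = None
    synth: SyntheticConfig | None = None
    keywords_yaml: str | Path | None = None
    prevalence_denominator: int = DEFAULT_PREVALENCE_DENOMINATOR
    dedup_precision: int = DEFAULT_DEDUP_PRECISION
    metric: str = "haversine"
    categories: tuple[str, ...] = ("All",) + CATEGORIES
    load_mode: str = "pooled"
    load_category: str = "Diagnosis"
    state_weighting: str = "individual"  # or "county"
    top_n: int = 10
    grid_bins: tuple[int, int] = (40, 80)
    seed: int = 0
    write_geojson: bool = False
    write_plot: bool = False

    def __post_init__(self) -> None:
        have_files = self.resources_csv is not None and self.counties_csv is not None
        if have_files == (self.synth is not None):
            raise ValueError(
                "provide either resources_csv+counties_csv or a synth config, not both"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if "synth" in doc and doc["synth"] is not None:
            doc["synth"] = SyntheticConfig(**doc["synth"])
        for key in ("categories", "grid_bins"):
            if key in doc and doc[key] is not None:
                doc[key] = tuple(doc[key])
        return cls(**doc)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a dict of output paths and key
    tables.  Any stage failure raises :class:`PipelineError` naming the
    stage."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    keyword_map = (
        KeywordMap.from_yaml(config.keywords_yaml)
        if config.keywords_yaml
        else DEFAULT_KEYWORD_MAP
    )

    # --- inputs -----------------------------------------------------------
    input_files: dict[str, str] = {}
    if config.synth is not None:
        counties, raw_with_truth = generate_world(config.synth, seed=config.seed)
        raw_resources = strip_truth(raw_with_truth)
        _write_csv(counties, out / "counties.csv")
        _write_csv(raw_resources, out / "raw_resources.csv")
    else:
        counties = read_counties_csv(config.counties_csv)
        raw_resources = read_resources_csv(config.resources_csv)
        input_files = {
            "resources_csv": _sha256(Path(config.resources_csv)),
            "counties_csv": _sha256(Path(config.counties_csv)),
        }

    # --- validate / dedup / categorize ------------------------------------
    @_stage("validate")
    def _clean():
        records = records_from_frame(raw_resources)
        return process_resources(records, keyword_map, config.dedup_precision)

    kept, discarded = _clean()
    validated = frame_from_records(kept + discarded)
    _write_csv(validated, out / "validated_resources.csv")
    breakdown = category_breakdown(kept)
    _write_csv(breakdown, out / "category_breakdown.csv")
    if config.write_geojson:
        resources_to_geojson(kept, out / "resources.geojson")

    resources = frame_from_records(kept)

    # --- population simulation --------------------------------------------
    @_stage("simulate")
    def _simulate():
        return simulate_national(
            counties, config.prevalence_denominator, rng_seed=config.seed
        )

    individuals = _simulate()
    _write_csv(individuals, out / "individuals.csv")

    # --- distances ---------------------------------------------------------
    @_stage("distances")
    def _distances():
        county_parts, state_parts = [], []
        for category in config.categories:
            cs = county_mean_distances(
                individuals, resources, category, metric=config.metric
            )
            county_parts.append(cs)
            state_parts.append(
                aggregate_to_state(
                    cs, counties, weighted=config.state_weighting == "individual"
                )
            )
        return pd.concat(county_parts, ignore_index=True), pd.concat(
            state_parts, ignore_index=True
        )

    county_summaries, state_summaries = _distances()
    _write_csv(county_summaries, out / "county_distances.csv")
    _write_csv(state_summaries, out / "state_distances.csv")

    overall = state_summaries[state_summaries["category"] == config.categories[0]]
    ranked = rank_regions(overall, "descending")
    _write_csv(ranked.head(config.top_n), out / "states_largest_distance.csv")
    _write_csv(
        rank_regions(overall, "ascending").head(config.top_n),
        out / "states_smallest_distance.csv",
    )

    # --- resource load -----------------------------------------------------
    @_stage("load")
    def _load():
        return resource_load_table(
            counties,
            resources,
            category=config.load_category,
            prevalence_denominator=config.prevalence_denominator,
            mode=config.load_mode,
        )

    loads = _load()
    _write_csv(loads, out / "state_resource_load.csv")
    defined = loads[loads["defined"]]
    _write_csv(
        defined.sort_values(
            ["normalized_load", "region_id"], ascending=[False, True]
        ).head(config.top_n),
        out / "states_highest_load.csv",
    )
    _write_csv(
        defined.sort_values(
            ["normalized_load", "region_id"], ascending=[True, True]
        ).head(config.top_n),
        out / "states_lowest_load.csv",
    )
    n_lacking, pct_lacking = count_counties_without_category(
        counties, resources, config.load_category
    )

    # --- density grid ------------------------------------------------------
    @_stage("density")
    def _density():
        return density_grid(
            resources["latitude"].to_numpy(),
            resources["longitude"].to_numpy(),
            *config.grid_bins,
        )

    grid = _density()
    grid.to_frame().to_csv(out / "density_grid.csv")
    if config.write_plot:
        plot_density_grid(grid, out / "density_grid.png")

    # --- manifest ----------------------------------------------------------
    params = dataclasses.asdict(config)
    params["out_dir"] = str(params["out_dir"])
    for key in ("resources_csv", "counties_csv", "keywords_yaml"):
        if params[key] is not None:
            params[key] = str(params[key])
    summary = {
        "n_raw_records": int(len(raw_resources)),
        "n_kept": len(kept),
        "n_discarded": len(discarded),
        "n_individuals": int(len(individuals)),
        "counties_without_load_category": [n_lacking, pct_lacking],
        "overall_mean_distance_km": float(
            np.average(
                overall["mean_distance_km"], weights=overall["n_individuals"]
            )
        ),
    }
    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "parameters": params,
        "input_checksums": input_files,
        "summary": summary,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return {
        "out_dir": out,
        "breakdown": breakdown,
        "county_summaries": county_summaries,
        "state_summaries": state_summaries,
        "loads": loads,
        "grid": grid,
        "manifest": manifest,
    }
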