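"""Diagnostic resource load: a comparative demand-over-supply index.

For a region with population ``N`` and ``R`` diagnostic resources, the raw
load is ``N / (denominator × R)`` — the simulated affected population per
diagnostic resource.  The index has no meaning as a stand-alone value (no
throughput data enters it); it is normalized by the minimum defined state
load so the least-loaded state scores exactly 1 and every other value reads
as a multiple of it.

Because most counties have no diagnostic resource at all, the default state
load pools counties first: state load = (Σ N_c) / (denominator × Σ R_c), so
zero-resource counties contribute demand but no supply.  States with no
diagnostic resources are reported as undefined and excluded from
normalization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .population_sim import DEFAULT_PREVALENCE_DENOMINATOR, as_county_frame
from .resource_db import percent_2dp


def raw_load(
    N: float, R: int, prevalence_denominator: int = DEFAULT_PREVALENCE_DENOMINATOR
) -> float:
    """N / (denominator × R); linear in N, inversely proportional to R.

    Undefined for R = 0: callers must pool regions before dividing, so the
    error is raised rather than returning 0 or infinity.
    """
    if R < 1:
        raise ValueError("resource load is undefined for R = 0; pool regions first")
    if N < 0:
        raise ValueError("population must be non-negative")
    if prevalence_denominator < 1:
        raise ValueError("prevalence denominator must be >= 1")
    return N / (prevalence_denominator * R)


def assign_resources_to_counties(
    counties, latitudes, longitudes
) -> np.ndarray:
    """County id containing each resource point, by bbox membership.

    Counties are scanned in ascending county_id order and each resource goes
    to the first bounding box that contains it, which resolves overlapping
    boxes deterministically.  Resources outside every box get ``None``.
    """
    frame = as_county_frame(counties).sort_values("county_id")
    lat = np.asarray(latitudes, dtype=float)
    lon = np.asarray(longitudes, dtype=float)
    assigned = np.full(lat.shape, None, dtype=object)
    unclaimed = np.ones(lat.shape, dtype=bool)
    for row in frame.itertuples(index=False):
        if not unclaimed.any():
            break
        inside = (
            unclaimed
            & (lat >= row.min_lat)
            & (lat <= row.max_lat)
            & (lon >= row.min_lon)
            & (lon <= row.max_lon)
        )
        assigned[inside] = row.county_id
        unclaimed &= ~inside
    return assigned


def county_resource_counts(
    counties, resources: pd.DataFrame, category: str = "Diagnosis"
) -> pd.DataFrame:
    """Counties table with an ``R`` column: resources of ``category`` whose
    point falls in the county bbox."""
    from .access_metrics import normalize_categories_column

    frame = as_county_frame(counties)
    resources = normalize_categories_column(resources)
    in_cat = resources[[category in cats for cats in resources["categories"]]]
    assigned = assign_resources_to_counties(
        frame, in_cat["latitude"].to_numpy(), in_cat["longitude"].to_numpy()
    )
    counts = pd.Series(assigned[assigned != None]).value_counts()  # noqa: E711
    out = frame.copy()
    out["R"] = out["county_id"].map(counts).fillna(0).astype(int)
    return out


def state_loads(
    county_table: pd.DataFrame,
    prevalence_denominator: int = DEFAULT_PREVALENCE_DENOMINATOR,
    mode: str = "pooled",
) -> pd.DataFrame:
    """Per-state raw loads from a county table with columns
    county_id, state, population, R.

    ``pooled`` (default): (Σ N_c)/(denominator × Σ R_c).  ``county_average``:
    unweighted mean of the defined county loads.  States with no defined
    value get raw_load = NaN and defined = False.
    """
    if county_table.empty:
        raise ValueError("county table is empty")
    if mode not in ("pooled", "county_average"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for state, grp in county_table.groupby("state", sort=True):
        N = int(grp["population"].sum())
        R = int(grp["R"].sum())
        if mode == "pooled":
            load = raw_load(N, R, prevalence_denominator) if R >= 1 else np.nan
        else:
            defined = grp[grp["R"] >= 1]
            load = (
                float(
                    np.mean(
                        [
                            raw_load(n, r, prevalence_denominator)
                            for n, r in zip(defined["population"], defined["R"])
                        ]
                    )
                )
                if len(defined)
                else np.nan
            )
        rows.append((state, "state", N, R, load, not np.isnan(load)))
    return pd.DataFrame(
        rows, columns=["region_id", "region_kind", "N", "R", "raw_load", "defined"]
    )


def normalize_loads(loads) -> np.ndarray:
    """Divide each defined (non-NaN) load by the minimum defined load.

    The minimum of the output is exactly 1 (x/x == 1.0 in floating point);
    undefined entries stay NaN.
    """
    arr = np.asarray(loads, dtype=float)
    defined = ~np.isnan(arr)
    if not defined.any():
        raise ValueError("no defined loads to normalize")
    floor_value = arr[defined].min()
    if floor_value <= 0:
        raise ValueError("defined loads must be positive to normalize")
    return arr / floor_value


def resource_load_table(
    counties,
    resources: pd.DataFrame,
    category: str = "Diagnosis",
    prevalence_denominator: int = DEFAULT_PREVALENCE_DENOMINATOR,
    mode: str = "pooled",
) -> pd.DataFrame:
    """End-to-end state resource-load table with normalized values."""
    county_table = county_resource_counts(counties, resources, category)
    states = state_loads(county_table, prevalence_denominator, mode)
    states["normalized_load"] = normalize_loads(states["raw_load"].to_numpy())
    states["prevalence_denominator"] = prevalence_denominator
    return states


def count_counties_without_category(
    counties, resources: pd.DataFrame, category: str = "Diagnosis"
) -> tuple[int, float]:
    """(count, percent) of counties with no resource of ``category``.

    Percent is of all counties, half-up rounded to 2 decimals.
    """
    county_table = county_resource_counts(counties, resources, category)
    lacking = int((county_table["R"] == 0).sum())
    return lacking, percent_2dp(lacking, len(county_table))
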