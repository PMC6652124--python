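"""Simulation of the affected population from county population counts.

In the absence of individual-level location data, the population of
individuals with autism is emulated by placing points uniformly at random
inside each county's rectangular bounding box.  The number of points per
county is the county population divided by a prevalence denominator
(default 59, i.e. a 1-in-59 prevalence), rounded half-up.

Counties are modelled as axis-aligned lat/lon rectangles, a deliberate
simplification of true county polygons; sampling is uniform in degrees by
default, with an optional equal-area mode that corrects latitude sampling
by cos(latitude).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_PREVALENCE_DENOMINATOR = 59

COUNTY_COLUMNS = (
    "county_id",
    "state",
    "min_lat",
    "min_lon",
    "max_lat",
    "max_lon",
    "population",
)

INDIVIDUAL_COLUMNS = ("county_id", "latitude", "longitude")


@dataclass(frozen=True)
class CountyRecord:
    """Administrative unit: FIPS-style id, state, bounding box, population."""

    county_id: str
    state: str
    min_lat: float
    min_lon: float
    max_lat: float
    max_lon: float
    population: int

    def __post_init__(self) -> None:
        if not (-90.0 <= self.min_lat <= self.max_lat <= 90.0):
            raise ValueError(f"invalid latitude bounds for county {self.county_id}")
        if not (-180.0 <= self.min_lon <= self.max_lon <= 180.0):
            raise ValueError(f"invalid longitude bounds for county {self.county_id}")
        if self.population < 0:
            raise ValueError(f"negative population for county {self.county_id}")

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        return (self.min_lat, self.min_lon, self.max_lat, self.max_lon)


def as_county_frame(counties) -> pd.DataFrame:
    """Coerce a counties table (DataFrame or iterable of CountyRecord)."""
    if isinstance(counties, pd.DataFrame):
        missing = set(COUNTY_COLUMNS) - set(counties.columns)
        if missing:
            raise ValueError(f"counties table missing columns: {sorted(missing)}")
        return counties
    return pd.DataFrame(
        [
            (c.county_id, c.state, c.min_lat, c.min_lon, c.max_lat, c.max_lon, c.population)
            for c in counties
        ],
        columns=list(COUNTY_COLUMNS),
    )


def county_case_count(
    population: int,
    prevalence_denominator: int = DEFAULT_PREVALENCE_DENOMINATOR,
    rounding: str = "half_up",
) -> int:
    """Expected affected count: population / denominator, rounded.

    Default rounding is half-up to the nearest integer, computed exactly in
    integer arithmetic; ``floor`` and ``ceil`` modes are available.
    """
    if prevalence_denominator < 1:
        raise ValueError("prevalence denominator must be >= 1")
    if population < 0:
        raise ValueError("population must be non-negative")
    population = int(population)
    d = int(prevalence_denominator)
    if rounding == "half_up":
        return (2 * population + d) // (2 * d)
    if rounding == "floor":
        return population // d
    if rounding == "ceil":
        return -((-population) // d)
    raise ValueError(f"unknown rounding mode {rounding!r}")


def _county_seed_sequence(rng_seed: int, county_id: str) -> np.random.SeedSequence:
    # sub-seed keyed on county_id so the national simulation is independent
    # of county ordering
    digest = hashlib.sha256(county_id.encode("utf-8")).digest()
    return np.random.SeedSequence([int(rng_seed), int.from_bytes(digest[:4], "big")])


def simulate_county(
    county: CountyRecord,
    prevalence_denominator: int = DEFAULT_PREVALENCE_DENOMINATOR,
    rng_seed: int = 0,
    rounding: str = "half_up",
    equal_area: bool = False,
) -> pd.DataFrame:
    """Uniform random points in the county bbox, one per simulated case.

    Fully reproducible: the generator is seeded from ``(rng_seed,
    county_id)``.  A degenerate (zero-width or zero-height) bbox yields all
    points on the degenerate coordinate.
    """
    n = county_case_count(county.population, prevalence_denominator, rounding)
    rng = np.random.default_rng(_county_seed_sequence(rng_seed, county.county_id))
    if equal_area:
        # inverse-CDF sampling with density proportional to cos(latitude)
        s0, s1 = np.sin(np.radians([county.min_lat, county.max_lat]))
        if s0 == s1:
            lat = np.full(n, county.min_lat)
        else:
            lat = np.degrees(np.arcsin(rng.uniform(s0, s1, size=n)))
    else:
        lat = rng.uniform(county.min_lat, county.max_lat, size=n)
    lon = rng.uniform(county.min_lon, county.max_lon, size=n)
    return pd.DataFrame(
        {"county_id": county.county_id, "latitude": lat, "longitude": lon},
        columns=list(INDIVIDUAL_COLUMNS),
    )


def simulate_national(
    counties,
    prevalence_denominator: int = DEFAULT_PREVALENCE_DENOMINATOR,
    rng_seed: int = 0,
    rounding: str = "half_up",
    equal_area: bool = False,
) -> pd.DataFrame:
    """Concatenated per-county simulations with per-county sub-seeds.

    The total point count equals the sum of the per-county case counts; the
    multiset of points is invariant to county ordering.
    """
    frame = as_county_frame(counties)
    if frame.empty:
        raise ValueError("counties table is empty")
    if frame["county_id"].duplicated().any():
        dupes = frame.loc[frame["county_id"].duplicated(), "county_id"].tolist()
        raise ValueError(f"duplicate county_id(s): {dupes}")
    parts = [
        simulate_county(
            CountyRecord(**row),
            prevalence_denominator,
            rng_seed,
            rounding,
            equal_area,
        )
        for row in frame[list(COUNTY_COLUMNS)].to_dict("records")
    ]
    return pd.concat(parts, ignore_index=True)
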