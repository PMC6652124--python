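"""Synthetic county tables and resource databases for pipeline testing.

No public accession backs the analysis inputs (county bounding boxes with
population estimates, and a merged directory of geocoded service listings),
so this module generates both with the statistical structure the pipeline
assumes:

* counties tile each synthetic state's rectangle with disjoint axis-aligned
  boxes and draw populations from a log-normal (heavy right tail, like real
  county sizes);
* resources are placed either population-proportionally per county or as a
  homogeneous Poisson process, given plausible names/addresses/contacts, and
  labelled with service-type phrases drawn verbatim from the keyword
  taxonomy so the generating category is recoverable;
* known dirt is injected — near-duplicates (coordinates perturbed below the
  deduplication precision, names case/punctuation-mangled) and invalid
  records for each discard reason — with ground truth retained in hidden
  ``truth_*`` columns that the validation code never reads.

Valid coordinates are snapped to the 1e-4 degree deduplication lattice so
that an injected duplicate is guaranteed to land in its base record's
deduplication cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .keywords import CATEGORIES, KEYWORD_CATEGORIES, DEFAULT_KEYWORD_MAP
from .population_sim import COUNTY_COLUMNS

#: Category mix of a realistic resource directory (multi-label marginals).
DEFAULT_CATEGORY_WEIGHTS: dict[str, float] = {
    "Therapy": 0.4143,
    "Support": 0.2911,
    "Health": 0.2584,
    "Education": 0.1998,
    "Recreation": 0.0997,
    "Diagnosis": 0.0883,
    "Other": 0.1853,
}

DEFAULT_INVALID_RATES: dict[str, float] = {
    "po_box": 0.03,
    "invalid_address": 0.02,
    "irrelevant_website": 0.02,
    "no_contact": 0.02,
    "unmappable": 0.01,
}

TRUTH_COLUMNS = ("truth_kind", "truth_categories", "truth_duplicate_of")

RESOURCE_COLUMNS = (
    "program_name",
    "program_description",
    "full_address",
    "phone",
    "email",
    "url",
    "latitude",
    "longitude",
    "service_types",
    "website_text",
    "broken_url",
)

_NOUNS = (
    "Center", "Clinic", "Services", "Network", "Institute",
    "Alliance", "Foundation", "Program", "Associates", "Cooperative",
)
_STREETS = (
    "Main", "Oak", "Cedar", "Maple", "Washington",
    "Lake", "Hill", "Park", "River", "Sunset",
)

# generic text with no taxonomy keyword, so fallback categorization → Other
_OTHER_WEBSITE_TEXT = "We assist autism families in our local community."
_IRRELEVANT_WEBSITE_TEXT = "General accounting and tax preparation for small businesses."


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic world; defaults emulate the study conditions
    at desk scale (10 states, heavy-tailed county populations around a
    26,000 median, resource counts proportional to population at roughly
    one listing per 11,500 residents, directory-like category mix, ~5%
    injected duplicates, ~10% injected invalid records)."""

    n_states: int = 10
    counties_per_state: int | tuple[int, int] = 6
    extent: tuple[float, float, float, float] = (30.0, -120.0, 45.0, -80.0)
    population_median: float = 26000.0
    population_sigma: float = 1.2
    resource_model: str = "population"  # or "poisson"
    resources_per_capita: float = 8.7e-5
    poisson_intensity_per_km2: float = 1e-3
    category_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_WEIGHTS)
    )
    multi_label_probability: float = 0.15
    duplicate_rate: float = 0.05
    invalid_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INVALID_RATES)
    )
    pending_email_rate: float = 0.02
    county_overlap_fraction: float = 0.0
    min_county_deg: float = 0.01
    rng_seed: int = 0

    def __post_init__(self) -> None:
        min_lat, min_lon, max_lat, max_lon = self.extent
        if not (min_lat < max_lat and min_lon < max_lon):
            raise ValueError("invalid extent")
        for name, rate in [
            ("duplicate_rate", self.duplicate_rate),
            ("multi_label_probability", self.multi_label_probability),
            ("pending_email_rate", self.pending_email_rate),
            *[(f"invalid_rates[{k}]", v) for k, v in self.invalid_rates.items()],
        ]:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        weights = dict(self.category_weights)
        if any(w < 0 for w in weights.values()) or not any(w > 0 for w in weights.values()):
            raise ValueError("category weights must be >= 0 with at least one > 0")
        unknown = set(weights) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories in weights: {sorted(unknown)}")


def _state_codes(n: int) -> list[str]:
    import itertools, string

    codes = ["".join(p) for p in itertools.product(string.ascii_uppercase, repeat=2)]
    if n > len(codes):
        raise ValueError("too many states requested")
    return codes[:n]


def generate_counties(config: SyntheticConfig, seed: int | None = None) -> pd.DataFrame:
    """Tile each state rectangle into disjoint county boxes with log-normal
    populations.  Deterministic under seed."""
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    min_lat, min_lon, max_lat, max_lon = config.extent
    states = _state_codes(config.n_states)
    lon_step = (max_lon - min_lon) / config.n_states
    rows = []
    for si, state in enumerate(states):
        s_min_lon = min_lon + si * lon_step
        s_max_lon = min_lon + (si + 1) * lon_step
        if isinstance(config.counties_per_state, tuple):
            lo, hi = config.counties_per_state
            n_counties = int(rng.integers(lo, hi + 1))
        else:
            n_counties = int(config.counties_per_state)
        if n_counties < 1:
            raise ValueError("need at least one county per state")
        n_rows = max(1, int(np.floor(np.sqrt(n_counties))))
        base, extra = divmod(n_counties, n_rows)
        per_row = [base + (1 if r < extra else 0) for r in range(n_rows)]
        lat_step = (max_lat - min_lat) / n_rows
        if lat_step < config.min_county_deg or (s_max_lon - s_min_lon) / max(per_row) < config.min_county_deg:
            raise ValueError("too many counties for the extent (tiling infeasible)")
        serial = 0
        for r, n_cols in enumerate(per_row):
            c_min_lat = min_lat + r * lat_step
            c_max_lat = min_lat + (r + 1) * lat_step
            col_step = (s_max_lon - s_min_lon) / n_cols
            for c in range(n_cols):
                serial += 1
                b = (
                    c_min_lat,
                    s_min_lon + c * col_step,
                    c_max_lat,
                    s_min_lon + (c + 1) * col_step,
                )
                if config.county_overlap_fraction > 0:
                    dlat = (b[2] - b[0]) * config.county_overlap_fraction / 2
                    dlon = (b[3] - b[1]) * config.county_overlap_fraction / 2
                    b = (
                        max(min_lat, b[0] - dlat),
                        max(min_lon, b[1] - dlon),
                        min(max_lat, b[2] + dlat),
                        min(max_lon, b[3] + dlon),
                    )
                population = int(round(
                    rng.lognormal(np.log(config.population_median), config.population_sigma)
                ))
                rows.append(
                    (f"{si + 1:02d}{serial:03d}", state, b[0], b[1], b[2], b[3], population)
                )
    return pd.DataFrame(rows, columns=list(COUNTY_COLUMNS))


def _lattice_coord(rng: np.random.Generator, low: float, high: float) -> float:
    """Uniform coordinate snapped to the 1e-4 degree dedup lattice."""
    lo = int(np.ceil(low * 1e4))
    hi = int(np.floor(high * 1e4))
    if hi < lo:
        return round((low + high) / 2, 4)
    return int(rng.integers(lo, hi + 1)) / 1e4


def _draw_categories(rng: np.random.Generator, config: SyntheticConfig) -> list[str]:
    cats = [c for c in CATEGORIES if config.category_weights.get(c, 0.0) > 0]
    w = np.array([config.category_weights[c] for c in cats], dtype=float)
    primary = str(rng.choice(cats, p=w / w.sum()))
    chosen = [primary]
    if primary != "Other" and rng.random() < config.multi_label_probability:
        others = [c for c in KEYWORD_CATEGORIES if c != primary
                  and config.category_weights.get(c, 0.0) > 0]
        if others:
            w2 = np.array([config.category_weights[c] for c in others], dtype=float)
            chosen.append(str(rng.choice(others, p=w2 / w2.sum())))
    return chosen


def _base_row(serial: int, rng: np.random.Generator, lat: float, lon: float,
              state: str) -> dict:
    noun = _NOUNS[serial % len(_NOUNS)]
    street = _STREETS[int(rng.integers(len(_STREETS)))]
    return {
        "program_name": f"{street} Autism {noun} {serial:06d}",
        "program_description": f"Community autism {noun.lower()}.",
        "full_address": f"{int(rng.integers(100, 9999))} {street} St, Springfield, {state}",
        "phone": f"555-{int(rng.integers(0, 10000)):04d}",
        "email": f"info{serial:06d}@example.org" if rng.random() < 0.7 else "",
        "url": f"https://resource{serial:06d}.example.org",
        "latitude": lat,
        "longitude": lon,
        "service_types": "",
        "website_text": "",
        "broken_url": False,
        "truth_kind": "valid",
        "truth_categories": "",
        "truth_duplicate_of": "",
    }


def _valid_row(serial: int, rng: np.random.Generator, lat: float, lon: float,
               state: str, config: SyntheticConfig) -> dict:
    row = _base_row(serial, rng, lat, lon, state)
    cats = _draw_categories(rng, config)
    if cats == ["Other"]:
        row["website_text"] = _OTHER_WEBSITE_TEXT
    else:
        phrases = [
            str(rng.choice(DEFAULT_KEYWORD_MAP.phrases_for_category(c)))
            for c in cats
            if c != "Other"
        ]
        row["service_types"] = "|".join(phrases)
        cats = [c for c in cats if c != "Other"]
        if rng.random() < 0.5:
            row["website_text"] = f"Autism services: {phrases[0]} for families."
    row["truth_categories"] = "|".join(sorted(set(cats)))
    return row


def _mangle_name(name: str, rng: np.random.Generator) -> str:
    variants = (name.upper(), name.lower(), name.swapcase(), name + ",", f"  {name}. ")
    return str(variants[int(rng.integers(len(variants)))])


def _duplicate_row(base: dict, serial: int, rng: np.random.Generator) -> dict:
    dup = dict(base)
    dup["program_name"] = _mangle_name(base["program_name"], rng)
    dup["latitude"] = base["latitude"] + float(rng.uniform(-4.9e-5, 4.9e-5))
    dup["longitude"] = base["longitude"] + float(rng.uniform(-4.9e-5, 4.9e-5))
    dup["program_description"] = ""  # duplicates are sparser copies
    dup["phone"] = ""
    dup["truth_kind"] = "duplicate"
    dup["truth_duplicate_of"] = base["program_name"]
    return dup


def _invalid_row(kind: str, serial: int, rng: np.random.Generator, lat: float,
                 lon: float, state: str, config: SyntheticConfig) -> dict:
    row = _valid_row(serial, rng, lat, lon, state, config)
    row["truth_kind"] = kind
    row["truth_categories"] = ""
    if kind == "po_box":
        row["full_address"] = f"P.O. Box {int(rng.integers(1, 9999))}, Springfield, {state}"
    elif kind == "invalid_address":
        row["full_address"] = f"{_STREETS[int(rng.integers(len(_STREETS)))]} Street"
    elif kind == "irrelevant_website":
        row["website_text"] = _IRRELEVANT_WEBSITE_TEXT
    elif kind == "no_contact":
        row["url"] = ""
        row["email"] = ""
        row["website_text"] = ""
        row["broken_url"] = False
    elif kind == "unmappable":
        row["latitude"] = np.nan
        row["longitude"] = np.nan
    else:
        raise ValueError(f"unknown invalid kind {kind!r}")
    return row


def _pending_row(serial: int, rng: np.random.Generator, lat: float, lon: float,
                 state: str, config: SyntheticConfig) -> dict:
    row = _valid_row(serial, rng, lat, lon, state, config)
    row["broken_url"] = True
    row["website_text"] = ""
    row["email"] = f"info{serial:06d}@example.org"
    row["truth_kind"] = "pending"
    return row


def generate_resources(
    counties: pd.DataFrame, config: SyntheticConfig, seed: int | None = None
) -> pd.DataFrame:
    """Raw resource table for a county map, with hidden ``truth_*`` columns.

    Valid records are placed in counties per the configured intensity model;
    duplicates and invalid records are injected at the configured rates
    (counts are rounded per batch so recovery tests can be exact).  Rows are
    deterministically shuffled.
    """
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    rows: list[dict] = []
    serial = 0
    for county in counties.itertuples(index=False):
        if config.resource_model == "population":
            lam = config.resources_per_capita * county.population
        elif config.resource_model == "poisson":
            from .access_metrics import EARTH_RADIUS_KM

            mid = np.radians((county.min_lat + county.max_lat) / 2)
            area = (
                np.radians(county.max_lat - county.min_lat) * EARTH_RADIUS_KM
                * np.radians(county.max_lon - county.min_lon) * EARTH_RADIUS_KM
                * np.cos(mid)
            )
            lam = config.poisson_intensity_per_km2 * area
        else:
            raise ValueError(f"unknown resource model {config.resource_model!r}")
        n = int(rng.poisson(lam))
        for _ in range(n):
            serial += 1
            lat = _lattice_coord(rng, county.min_lat, county.max_lat)
            lon = _lattice_coord(rng, county.min_lon, county.max_lon)
            rows.append(_valid_row(serial, rng, lat, lon, county.state, config))
    if not rows:
        raise ValueError("intensity model produced no resources anywhere")

    min_lat, min_lon, max_lat, max_lon = config.extent
    state0 = str(counties["state"].iloc[0])
    n_valid = len(rows)

    n_pending = round(config.pending_email_rate * n_valid)
    for _ in range(n_pending):
        serial += 1
        lat = _lattice_coord(rng, min_lat, max_lat)
        lon = _lattice_coord(rng, min_lon, max_lon)
        rows.append(_pending_row(serial, rng, lat, lon, state0, config))

    n_dup = round(config.duplicate_rate * n_valid)
    base_idx = rng.choice(n_valid, size=n_dup, replace=False)
    for bi in base_idx:
        serial += 1
        rows.append(_duplicate_row(rows[int(bi)], serial, rng))

    for kind, rate in config.invalid_rates.items():
        for _ in range(round(rate * n_valid)):
            serial += 1
            lat = _lattice_coord(rng, min_lat, max_lat)
            lon = _lattice_coord(rng, min_lon, max_lon)
            rows.append(_invalid_row(kind, serial, rng, lat, lon, state0, config))

    frame = pd.DataFrame(rows, columns=list(RESOURCE_COLUMNS + TRUTH_COLUMNS))
    return frame.iloc[rng.permutation(len(frame))].reset_index(drop=True)


def strip_truth(resources: pd.DataFrame) -> pd.DataFrame:
    """Public view of a synthetic resource table (hidden columns removed)."""
    return resources.drop(columns=[c for c in TRUTH_COLUMNS if c in resources.columns])


def generate_world(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(counties, raw resources with truth columns) from one seed."""
    base = config.rng_seed if seed is None else seed
    counties = generate_counties(config, seed=base)
    resources = generate_resources(counties, config, seed=base + 1)
    return counties, resources


def worked_fixture() -> dict:
    """Tiny hand-checkable dataset: 3 counties, 5 resources, 6 individuals.

    Every coordinate is printed below and every expected output was derived
    independently of the pipeline (nearest-resource distances via the
    arctangent form of the great-circle formula on the same 6371.0088 km
    sphere, aggregates and loads by hand arithmetic), so each pipeline stage
    can be checked against ``expected`` to tight tolerances.
    """
    counties = pd.DataFrame(
        [
            ("01001", "AA", 37.0, -123.0, 38.0, -122.0, 118),
            ("01002", "AA", 37.0, -122.0, 38.0, -121.0, 177),
            ("02001", "BB", 36.0, -123.0, 36.9, -122.0, 59),
        ],
        columns=list(COUNTY_COLUMNS),
    )
    resources = pd.DataFrame(
        [
            # program_name, address, email, url, lat, lon, service_types
            ("Bayside Autism Diagnostics", "12 Shore Rd, Bayside, AA",
             "contact@bayside.example.org", "https://bayside.example.org",
             37.2, -122.8, "Assessments and Diagnosis|Occupational Therapy"),
            ("Valley Speech Partners", "480 Valley Ave, Midtown, AA",
             "", "https://valley.example.org", 37.5, -122.1, "Speech"),
            ("Eastside Family Circle", "77 East St, Eastside, AA",
             "hello@eastside.example.org", "https://eastside.example.org",
             37.9, -121.2, "Support Groups"),
            ("Southport Assessment Clinic", "9 Harbor Way, Southport, BB",
             "", "https://southport.example.org", 36.3, -122.5, "Diagnostic"),
            ("Coastal Pediatric Health", "310 Coast Hwy, Seabrook, BB",
             "", "https://coastal.example.org", 36.7, -122.2, "Health Services"),
        ],
        columns=["program_name", "full_address", "email", "url",
                 "latitude", "longitude", "service_types"],
    )
    for col, value in [("program_description", ""), ("phone", ""),
                       ("website_text", ""), ("broken_url", False)]:
        resources[col] = value
    resources = resources[list(RESOURCE_COLUMNS)]
    individuals = pd.DataFrame(
        [
            ("01001", 37.25, -122.75),
            ("01001", 37.60, -122.90),
            ("01002", 37.45, -121.90),
            ("01002", 37.80, -121.40),
            ("01002", 37.10, -121.10),
            ("02001", 36.50, -122.40),
        ],
        columns=["county_id", "latitude", "longitude"],
    )
    expected = {
        # per-individual nearest resource (row index) and distance, all categories
        "nearest_index": [0, 0, 1, 2, 2, 3],
        "nearest_distance_km": [
            7.107008730508951,
            45.346721785233186,
            18.504285858622378,
            20.784842133675234,
            89.3923946483006,
            23.972411767935746,
        ],
        "county_mean_km": {
            "01001": 26.22686525787107,
            "01002": 42.8938408801994,
            "02001": 23.972411767935746,
        },
        "state_mean_km": {"AA": 36.227050631268064, "BB": 23.972411767935746},
        "diagnosis_county_mean_km": {
            "01001": 26.22686525787107,
            "01002": 125.24754114697089,
            "02001": 23.972411767935746,
        },
        "categories": [
            {"Diagnosis", "Therapy"},
            {"Therapy"},
            {"Support"},
            {"Diagnosis"},
            {"Health"},
        ],
        # 5 resources; counts and half-up percents per category
        "breakdown": {
            "All resources": (5, 100.0),
            "Diagnosis": (2, 40.0),
            "Therapy": (2, 40.0),
            "Health": (1, 20.0),
            "Education": (0, 0.0),
            "Recreation": (0, 0.0),
            "Support": (1, 20.0),
            "Other": (0, 0.0),
        },
        # pooled loads: AA N=295 R=1 -> 295/59=5; BB N=59 R=1 -> 1
        "state_raw_load": {"AA": 5.0, "BB": 1.0},
        "state_normalized_load": {"AA": 5.0, "BB": 1.0},
    }
    return {
        "counties": counties,
        "resources": resources,
        "individuals": individuals,
        "expected": expected,
    }


def bookkeeping_scenario(
    seed: int = 0,
    n_initial: int = 29935,
    n_removed: int = 8402,
    n_added: int = 6470,
    extent: tuple[float, float, float, float] = (25.0, -124.0, 49.0, -67.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two raw resource batches with exactly controlled cleaning arithmetic.

    The initial batch holds ``n_initial`` records of which exactly
    ``n_removed`` are removed by validation + deduplication (an even split
    between injected invalid records and injected duplicates); the second
    batch holds ``n_added`` new unique valid records.  Cleaning the initial
    batch and merging the second therefore yields
    ``n_initial - n_removed + n_added`` records.
    """
    if n_removed >= n_initial:
        raise ValueError("cannot remove more records than exist")
    rng = np.random.default_rng(seed)
    config = SyntheticConfig(rng_seed=seed, extent=extent)
    min_lat, min_lon, max_lat, max_lon = extent
    n_invalid = n_removed // 2
    n_dup = n_removed - n_invalid
    n_unique_valid = n_initial - n_removed

    def valid_rows(count: int, start_serial: int) -> list[dict]:
        out = []
        for i in range(count):
            lat = _lattice_coord(rng, min_lat, max_lat)
            lon = _lattice_coord(rng, min_lon, max_lon)
            out.append(_valid_row(start_serial + i, rng, lat, lon, "US", config))
        return out

    initial = valid_rows(n_unique_valid, 0)
    serial = n_unique_valid
    base_idx = rng.choice(n_unique_valid, size=n_dup, replace=False)
    for bi in base_idx:
        initial.append(_duplicate_row(initial[int(bi)], serial, rng))
        serial += 1
    kinds = list(DEFAULT_INVALID_RATES)
    for i in range(n_invalid):
        lat = _lattice_coord(rng, min_lat, max_lat)
        lon = _lattice_coord(rng, min_lon, max_lon)
        initial.append(
            _invalid_row(kinds[i % len(kinds)], serial, rng, lat, lon, "US", config)
        )
        serial += 1
    added = valid_rows(n_added, serial)
    columns = list(RESOURCE_COLUMNS + TRUTH_COLUMNS)
    initial_df = pd.DataFrame(initial, columns=columns)
    added_df = pd.DataFrame(added, columns=columns)
    return (
        initial_df.iloc[rng.permutation(len(initial_df))].reset_index(drop=True),
        added_df.iloc[rng.permutation(len(added_df))].reset_index(drop=True),
    )
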