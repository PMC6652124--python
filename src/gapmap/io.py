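"""CSV and GeoJSON readers/writers for the pipeline's table dialects.

All tables are plain CSV.  The resources dialect stores multi-valued fields
pipe-delimited (``service_types``, ``categories``); missing website text is
an empty field and is mapped to ``None`` in memory so "website absent" and
"website fetched but empty" are not conflated.
"""

from __future__ import annotations

import json
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .population_sim import COUNTY_COLUMNS
from .resource_db import ResourceRecord


def _opt_str(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ""
    return str(value)


def _opt_float(value) -> float | None:
    if value is None or value == "":
        return None
    value = float(value)
    return None if np.isnan(value) else value


def records_from_frame(frame: pd.DataFrame) -> list[ResourceRecord]:
    """Convert a raw resources table into ResourceRecord objects."""
    records = []
    for row in frame.to_dict("records"):
        service_types = tuple(
            s for s in _opt_str(row.get("service_types")).split("|") if s
        )
        website_text = _opt_str(row.get("website_text"))
        categories = frozenset(
            c for c in _opt_str(row.get("categories")).split("|") if c
        )
        records.append(
            ResourceRecord(
                program_name=_opt_str(row.get("program_name")),
                program_description=_opt_str(row.get("program_description")),
                full_address=_opt_str(row.get("full_address")),
                phone=_opt_str(row.get("phone")),
                email=_opt_str(row.get("email")),
                url=_opt_str(row.get("url")),
                latitude=_opt_float(row.get("latitude")),
                longitude=_opt_float(row.get("longitude")),
                service_types=service_types,
                website_text=website_text or None,
                broken_url=bool(row.get("broken_url", False)),
                categories=categories,
                status=_opt_str(row.get("status")),
                discard_reason=_opt_str(row.get("discard_reason")),
            )
        )
    return records


def frame_from_records(records: Iterable[ResourceRecord]) -> pd.DataFrame:
    """Inverse of :func:`records_from_frame` (categories sorted for
    determinism)."""
    rows = []
    for r in records:
        rows.append(
            {
                "program_name": r.program_name,
                "program_description": r.program_description,
                "full_address": r.full_address,
                "phone": r.phone,
                "email": r.email,
                "url": r.url,
                "latitude": r.latitude,
                "longitude": r.longitude,
                "service_types": "|".join(r.service_types),
                "website_text": r.website_text or "",
                "broken_url": r.broken_url,
                "categories": "|".join(sorted(r.categories)),
                "status": r.status,
                "discard_reason": r.discard_reason,
            }
        )
    return pd.DataFrame(rows)


def read_resources_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"service_types": str, "website_text": str}, keep_default_na=True)
    if "broken_url" not in df.columns:
        df["broken_url"] = False
    df["broken_url"] = df["broken_url"].fillna(False).astype(bool)
    return df


def read_counties_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"county_id": str, "state": str})
    missing = set(COUNTY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"counties CSV missing columns: {sorted(missing)}")
    return df


def read_individuals_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"county_id": str})


def resources_to_geojson(records: Sequence[ResourceRecord], path) -> None:
    """Write valid/pending records as a GeoJSON FeatureCollection of Points."""
    features = []
    for r in records:
        if not r.has_coordinates:
            continue
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [r.longitude, r.latitude],
                },
                "properties": {
                    "program_name": r.program_name,
                    "full_address": r.full_address,
                    "url": r.url,
                    "categories": sorted(r.categories),
                    "status": r.status,
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


def individuals_to_geojson(individuals: pd.DataFrame, path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [row.longitude, row.latitude]},
            "properties": {"county_id": row.county_id},
        }
        for row in individuals.itertuples(index=False)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
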