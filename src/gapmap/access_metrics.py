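"""Nearest-resource distance statistics and regional aggregation.

Each simulated individual is matched to the closest resource of a given
category — anywhere in the dataset, not just within the individual's own
county — and the per-individual nearest distances are averaged to county
and state level.  Two distance metrics are supported:

``haversine``
    Great-circle distance on a sphere of radius 6371.0088 km (the IUGG mean
    Earth radius).  Default, and geodetically meaningful at continental
    scale.
``equirectangular``
    Euclidean distance on a locally flat (equirectangular) projection,
    where one degree of longitude is scaled by cos(reference latitude).
    Appropriate for small patches and used by the analytic Poisson
    benchmarks.

The accelerated nearest-neighbour index is exact, not approximate: for the
haversine metric points are embedded on the unit sphere, where chord length
is monotone in central angle, so a 3-D KD-tree returns the true
great-circle nearest neighbour; for the equirectangular metric the KD-tree
operates directly on the projected plane.  Exact ties are broken toward the
smallest resource index, and a brute-force scan with the identical distance
computation is provided as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .keywords import CATEGORIES

EARTH_RADIUS_KM = 6371.0088

SUMMARY_COLUMNS = (
    "region_id",
    "region_kind",
    "category",
    "n_individuals",
    "mean_distance_km",
)


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between coordinate arrays (broadcasting)."""
    phi1, lam1, phi2, lam2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dphi = phi2 - phi1
    dlam = lam2 - lam1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def equirectangular_km(lat1, lon1, lat2, lon2, ref_lat=None) -> np.ndarray:
    """Euclidean distance on a flat projection scaled at ``ref_lat``.

    With ``ref_lat=None`` the per-pair mean latitude is used, which is the
    usual symmetric small-patch approximation.
    """
    lat1, lon1, lat2, lon2 = map(np.asarray, (lat1, lon1, lat2, lon2))
    if ref_lat is None:
        ref = np.radians((lat1 + lat2) / 2.0)
    else:
        ref = np.radians(ref_lat)
    x = np.radians(lon2 - lon1) * np.cos(ref)
    y = np.radians(lat2 - lat1)
    return EARTH_RADIUS_KM * np.hypot(x, y)


def point_distance_km(a, b, metric: str = "haversine") -> float:
    """Distance between two (lat, lon) points in km under ``metric``."""
    if metric == "haversine":
        return float(haversine_km(a[0], a[1], b[0], b[1]))
    if metric == "equirectangular":
        return float(equirectangular_km(a[0], a[1], b[0], b[1]))
    raise ValueError(f"unknown metric {metric!r}")


def _unit_vectors(lat, lon) -> np.ndarray:
    phi = np.radians(np.asarray(lat, dtype=float))
    lam = np.radians(np.asarray(lon, dtype=float))
    cos_phi = np.cos(phi)
    return np.column_stack(
        (cos_phi * np.cos(lam), cos_phi * np.sin(lam), np.sin(phi))
    )


def _chord_to_km(chord: np.ndarray) -> np.ndarray:
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0))


class ResourceIndex:
    """Exact nearest-resource index over a fixed point set.

    For the equirectangular metric all points are projected at a single
    reference latitude (default: mean resource latitude) so that distances
    form a true metric and the KD-tree search is exact.
    """

    def __init__(self, latitudes, longitudes, metric: str = "haversine", ref_lat=None):
        self.latitudes = np.atleast_1d(np.asarray(latitudes, dtype=float))
        self.longitudes = np.atleast_1d(np.asarray(longitudes, dtype=float))
        if self.latitudes.size == 0:
            raise ValueError("resource set is empty")
        if self.latitudes.shape != self.longitudes.shape:
            raise ValueError("latitude/longitude arrays differ in length")
        self.metric = metric
        if metric == "haversine":
            self._points = _unit_vectors(self.latitudes, self.longitudes)
            self.ref_lat = None
        elif metric == "equirectangular":
            self.ref_lat = (
                float(np.mean(self.latitudes)) if ref_lat is None else float(ref_lat)
            )
            self._points = self._project(self.latitudes, self.longitudes)
        else:
            raise ValueError(f"unknown metric {metric!r}")
        self._tree = cKDTree(self._points)

    def __len__(self) -> int:
        return self.latitudes.size

    def _project(self, lat, lon) -> np.ndarray:
        x = EARTH_RADIUS_KM * np.radians(np.asarray(lon, dtype=float)) * np.cos(
            np.radians(self.ref_lat)
        )
        y = EARTH_RADIUS_KM * np.radians(np.asarray(lat, dtype=float))
        return np.column_stack((x, y))

    def _embed(self, lat, lon) -> np.ndarray:
        if self.metric == "haversine":
            return _unit_vectors(lat, lon)
        return self._project(lat, lon)

    def _to_km(self, raw: np.ndarray) -> np.ndarray:
        if self.metric == "haversine":
            return _chord_to_km(raw)
        return raw

    def query(self, lat, lon) -> tuple[np.ndarray, np.ndarray]:
        """Nearest resource index and distance (km) for each query point.

        Ties (e.g. coincident resources) resolve to the smallest resource
        index, matching :meth:`query_bruteforce`.
        """
        pts = self._embed(np.atleast_1d(lat), np.atleast_1d(lon))
        k = min(2, len(self))
        raw, idx = self._tree.query(pts, k=k)
        if k == 1:
            return idx.astype(np.intp), self._to_km(raw)
        best_raw = raw[:, 0]
        best_idx = idx[:, 0].astype(np.intp)
        # resolve exact/near ties toward the smallest resource index
        ambiguous = np.nonzero(raw[:, 1] - best_raw <= 1e-12 * (best_raw + 1e-9))[0]
        for i in ambiguous:
            radius = best_raw[i] * (1.0 + 1e-9) + 1e-12
            members = np.array(self._tree.query_ball_point(pts[i], radius), dtype=np.intp)
            dists = np.linalg.norm(self._points[members] - pts[i], axis=1)
            dmin = dists.min()
            best_idx[i] = members[dists <= dmin].min()
            best_raw[i] = dmin
        return best_idx, self._to_km(best_raw)

    def query_bruteforce(self, lat, lon) -> tuple[np.ndarray, np.ndarray]:
        """Exhaustive O(n·m) scan with the same distance computation.

        ``argmin`` keeps the first (smallest-index) minimum, the documented
        tie-break.
        """
        pts = self._embed(np.atleast_1d(lat), np.atleast_1d(lon))
        idx = np.empty(pts.shape[0], dtype=np.intp)
        raw = np.empty(pts.shape[0], dtype=float)
        for i, p in enumerate(pts):  # chunked by query point to bound memory
            d = np.linalg.norm(self._points - p, axis=1)
            idx[i] = np.argmin(d)
            raw[i] = d[idx[i]]
        return idx, self._to_km(raw)


def nearest_resource(individual, index: ResourceIndex) -> tuple[int, float]:
    """Nearest resource for a single (lat, lon) point: (index, distance km)."""
    idx, dist = index.query([individual[0]], [individual[1]])
    return int(idx[0]), float(dist[0])


def _category_mask(resources: pd.DataFrame, category: str) -> np.ndarray:
    if category == "All":
        return np.ones(len(resources), dtype=bool)
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    return np.fromiter(
        (category in cats for cats in resources["categories"]),
        dtype=bool,
        count=len(resources),
    )


def normalize_categories_column(resources: pd.DataFrame) -> pd.DataFrame:
    """Return a copy whose ``categories`` column holds frozensets.

    Accepts pipe-delimited strings (the CSV dialect) or any iterable of
    category names per row.
    """
    out = resources.copy()

    def _coerce(value) -> frozenset:
        if isinstance(value, str):
            return frozenset(v for v in value.split("|") if v)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return frozenset()
        return frozenset(value)

    out["categories"] = [_coerce(v) for v in out["categories"]]
    return out


def county_mean_distances(
    individuals: pd.DataFrame,
    resources: pd.DataFrame,
    category: str = "All",
    metric: str = "haversine",
) -> pd.DataFrame:
    """Mean nearest-resource distance per county for one category.

    ``individuals`` carries columns county_id, latitude, longitude;
    ``resources`` carries latitude, longitude, categories.  The nearest
    resource may lie outside the individual's county.  A category with no
    resources anywhere raises a ValueError naming the category.
    """
    resources = normalize_categories_column(resources)
    mask = _category_mask(resources, category)
    if not mask.any():
        raise ValueError(f"no resources in category {category!r}")
    subset = resources.loc[mask]
    index = ResourceIndex(
        subset["latitude"].to_numpy(), subset["longitude"].to_numpy(), metric=metric
    )
    _, dist = index.query(
        individuals["latitude"].to_numpy(), individuals["longitude"].to_numpy()
    )
    per_county = (
        pd.DataFrame(
            {"region_id": individuals["county_id"].to_numpy(), "distance": dist}
        )
        .groupby("region_id", sort=True)["distance"]
        .agg(n_individuals="size", mean_distance_km="mean")
        .reset_index()
    )
    per_county.insert(1, "region_kind", "county")
    per_county.insert(2, "category", category)
    return per_county[list(SUMMARY_COLUMNS)]


def aggregate_to_state(
    county_summaries: pd.DataFrame,
    county_to_state: pd.DataFrame | dict,
    weighted: bool = True,
) -> pd.DataFrame:
    """Roll county summaries up to states.

    Default is the individual-weighted mean (equivalent to averaging over
    all of a state's simulated individuals); ``weighted=False`` averages the
    county means without weights.
    """
    if isinstance(county_to_state, pd.DataFrame):
        mapping = dict(zip(county_to_state["county_id"], county_to_state["state"]))
    else:
        mapping = dict(county_to_state)
    df = county_summaries.copy()
    unmapped = set(df["region_id"]) - set(mapping)
    if unmapped:
        raise ValueError(f"counties with no state mapping: {sorted(unmapped)}")
    df["state"] = df["region_id"].map(mapping)
    rows = []
    for (state, category), grp in df.groupby(["state", "category"], sort=True):
        n = int(grp["n_individuals"].sum())
        if weighted:
            mean = float(
                np.average(grp["mean_distance_km"], weights=grp["n_individuals"])
            )
        else:
            mean = float(grp["mean_distance_km"].mean())
        rows.append((state, "state", category, n, mean))
    return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))


def rank_regions(summaries: pd.DataFrame, direction: str = "descending") -> pd.DataFrame:
    """Stable sort by mean distance; ties break by region_id lexicographic."""
    if direction not in ("descending", "ascending"):
        raise ValueError(f"unknown direction {direction!r}")
    return summaries.sort_values(
        ["mean_distance_km", "region_id"],
        ascending=[direction == "ascending", True],
        kind="mergesort",
    ).reset_index(drop=True)


@dataclass(frozen=True)
class DensityGrid:
    """2-D histogram of resource coordinates."""

    lat_edges: np.ndarray
    lon_edges: np.ndarray
    counts: np.ndarray  # shape (n_lat_bins, n_lon_bins)
    n_outside: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.lat_edges[:-1], name="lat_edge"),
            columns=pd.Index(self.lon_edges[:-1], name="lon_edge"),
        )


def density_grid(
    latitudes: Sequence[float],
    longitudes: Sequence[float],
    n_lat_bins: int,
    n_lon_bins: int,
    extent: tuple[float, float, float, float] | None = None,
) -> DensityGrid:
    """Bin resource points into an ``n_lat_bins × n_lon_bins`` grid.

    ``extent`` is (min_lat, min_lon, max_lat, max_lon); by default it is the
    data range.  Points outside the extent are counted in ``n_outside`` so
    that total points = grid sum + outside.
    """
    if n_lat_bins < 1 or n_lon_bins < 1:
        raise ValueError("need at least one bin per axis")
    lat = np.asarray(latitudes, dtype=float)
    lon = np.asarray(longitudes, dtype=float)
    if extent is None:
        extent = (lat.min(), lon.min(), lat.max(), lon.max())
    min_lat, min_lon, max_lat, max_lon = extent
    if not (min_lat < max_lat and min_lon < max_lon):
        raise ValueError("extent has zero area")
    counts, lat_edges, lon_edges = np.histogram2d(
        lat, lon, bins=[n_lat_bins, n_lon_bins],
        range=[[min_lat, max_lat], [min_lon, max_lon]],
    )
    inside = int(counts.sum())
    return DensityGrid(lat_edges, lon_edges, counts.astype(int), lat.size - inside)


def plot_density_grid(grid: DensityGrid, path) -> None:
    """Write a heat-map PNG of a density grid (non-contractual output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 5))
    mesh = ax.pcolormesh(grid.lon_edges, grid.lat_edges, grid.counts, cmap="hot_r")
    fig.colorbar(mesh, ax=ax, label="resources per cell")
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
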