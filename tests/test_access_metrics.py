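"""Distances, nearest-resource search, regional aggregation, density grid."""

import numpy as np
import pandas as pd
import pytest

from gapmap.access_metrics import (
    EARTH_RADIUS_KM,
    DensityGrid,
    ResourceIndex,
    aggregate_to_state,
    county_mean_distances,
    density_grid,
    equirectangular_km,
    haversine_km,
    nearest_resource,
    point_distance_km,
    rank_regions,
)


def resources_frame(points, categories=None):
    lat, lon = zip(*points)
    cats = categories or [{"Therapy"}] * len(points)
    return pd.DataFrame({"latitude": lat, "longitude": lon, "categories": cats})


class TestPointDistance:
    def test_identity(self):
        assert point_distance_km((37.4, -122.1), (37.4, -122.1)) == 0.0
        assert point_distance_km((37.4, -122.1), (37.4, -122.1), "equirectangular") == 0.0

    def test_one_degree_meridian_arc(self):
        # closed form: R * pi / 180
        expected = EARTH_RADIUS_KM * np.pi / 180
        assert point_distance_km((0, 0), (1, 0)) == pytest.approx(111.195, abs=1e-3)
        assert point_distance_km((0, 0), (1, 0)) == pytest.approx(expected, abs=1e-9)
        assert point_distance_km((0, 0), (1, 0), "equirectangular") == pytest.approx(
            expected, abs=1e-9
        )

    def test_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(0)
        a_lat, b_lat = rng.uniform(-80, 80, (2, 1000))
        a_lon, b_lon = rng.uniform(-179, 179, (2, 1000))
        np.testing.assert_allclose(
            haversine_km(a_lat, a_lon, b_lat, b_lon),
            haversine_km(b_lat, b_lon, a_lat, a_lon),
            rtol=0, atol=0,
        )
        np.testing.assert_allclose(
            equirectangular_km(a_lat, a_lon, b_lat, b_lon),
            equirectangular_km(b_lat, b_lon, a_lat, a_lon),
            rtol=0, atol=0,
        )

    def test_metrics_agree_on_small_separations(self):
        rng = np.random.default_rng(1)
        lat = rng.uniform(35, 36, 200)
        lon = rng.uniform(-101, -100, 200)
        h = haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:])
        e = equirectangular_km(lat[:-1], lon[:-1], lat[1:], lon[1:])
        np.testing.assert_allclose(h, e, rtol=2e-4)

    def test_unknown_metric(self):
        with pytest.raises(ValueError):
            point_distance_km((0, 0), (1, 1), metric="manhattan")


class TestNearestResource:
    def test_single_resource(self):
        idx = ResourceIndex([40.0], [-100.0])
        i, d = nearest_resource((41.0, -100.0), idx)
        assert i == 0
        assert d == pytest.approx(EARTH_RADIUS_KM * np.pi / 180, rel=1e-9)

    def test_coincident_point_distance_zero(self):
        idx = ResourceIndex([40.0, 41.0, 42.0], [-100.0, -101.0, -99.0])
        i, d = nearest_resource((41.0, -101.0), idx)
        assert (i, d) == (1, 0.0)

    def test_duplicate_resources_tie_to_smallest_index(self):
        idx = ResourceIndex([40.0, 40.0, 40.0], [-100.0, -100.0, -100.0])
        i, _ = nearest_resource((40.5, -100.0), idx)
        assert i == 0

    def test_empty_resource_set_rejected(self):
        with pytest.raises(ValueError):
            ResourceIndex([], [])

    @pytest.mark.parametrize("metric", ["haversine", "equirectangular"])
    def test_indexed_equals_bruteforce(self, metric):
        rng = np.random.default_rng(2)
        idx = ResourceIndex(
            rng.uniform(25, 49, 200), rng.uniform(-124, -67, 200), metric=metric
        )
        qlat = rng.uniform(25, 49, 300)
        qlon = rng.uniform(-124, -67, 300)
        fast_i, fast_d = idx.query(qlat, qlon)
        slow_i, slow_d = idx.query_bruteforce(qlat, qlon)
        np.testing.assert_array_equal(fast_i, slow_i)
        np.testing.assert_allclose(fast_d, slow_d, rtol=0, atol=0)


class TestCountyMeans:
    def test_arithmetic_mean_of_two_individuals(self):
        resources = resources_frame([(40.0, -100.0)])
        individuals = pd.DataFrame(
            {
                "county_id": ["c1", "c1"],
                "latitude": [40.1, 40.2],
                "longitude": [-100.0, -100.0],
            }
        )
        out = county_mean_distances(individuals, resources)
        d1 = point_distance_km((40.1, -100.0), (40.0, -100.0))
        d2 = point_distance_km((40.2, -100.0), (40.0, -100.0))
        assert out.loc[0, "mean_distance_km"] == pytest.approx((d1 + d2) / 2, rel=1e-12)
        assert out.loc[0, "n_individuals"] == 2

    def test_nearest_resource_may_lie_outside_county(self):
        resources = resources_frame([(40.0, -100.0)])  # inside county A only
        individuals = pd.DataFrame(
            {"county_id": ["B", "B"], "latitude": [45.0, 46.0], "longitude": [-90.0, -91.0]}
        )
        out = county_mean_distances(individuals, resources)
        assert np.isfinite(out["mean_distance_km"]).all()

    def test_fixture_county_means_match_hand_computation(self, fixture_data):
        from gapmap.io import frame_from_records, records_from_frame
        from gapmap.resource_db import process_resources

        kept, _ = process_resources(records_from_frame(fixture_data["resources"]))
        out = county_mean_distances(
            fixture_data["individuals"], frame_from_records(kept)
        ).set_index("region_id")
        for county_id, expected in fixture_data["expected"]["county_mean_km"].items():
            assert out.loc[county_id, "mean_distance_km"] == pytest.approx(
                expected, abs=1e-9
            )

    def test_empty_category_raises_with_name(self):
        resources = resources_frame([(40.0, -100.0)], [{"Therapy"}])
        individuals = pd.DataFrame(
            {"county_id": ["A"], "latitude": [40.0], "longitude": [-100.0]}
        )
        with pytest.raises(ValueError, match="Diagnosis"):
            county_mean_distances(individuals, resources, "Diagnosis")

    def test_adding_a_resource_never_increases_any_county_mean(self, small_world):
        from gapmap.io import frame_from_records, records_from_frame
        from gapmap.population_sim import simulate_national
        from gapmap.resource_db import process_resources
        from gapmap.synthetic_data import strip_truth

        counties, raw, _ = small_world
        kept, _ = process_resources(records_from_frame(strip_truth(raw)))
        resources = frame_from_records(kept)
        individuals = simulate_national(counties.head(12), rng_seed=1)
        before = county_mean_distances(individuals, resources).set_index("region_id")
        extra = pd.DataFrame(
            [{"latitude": 37.0, "longitude": -110.0, "categories": {"Therapy"}}]
        )
        augmented = pd.concat(
            [resources[["latitude", "longitude", "categories"]], extra],
            ignore_index=True,
        )
        after = county_mean_distances(individuals, augmented).set_index("region_id")
        assert (
            after["mean_distance_km"] <= before["mean_distance_km"] + 1e-12
        ).all()

    def test_category_mean_at_least_all_mean(self, small_world):
        from gapmap.io import frame_from_records, records_from_frame
        from gapmap.population_sim import simulate_national
        from gapmap.resource_db import process_resources
        from gapmap.synthetic_data import strip_truth

        counties, raw, _ = small_world
        kept, _ = process_resources(records_from_frame(strip_truth(raw)))
        resources = frame_from_records(kept)
        individuals = simulate_national(counties.head(12), rng_seed=2)
        all_means = county_mean_distances(individuals, resources, "All").set_index("region_id")
        cat_means = county_mean_distances(individuals, resources, "Therapy").set_index("region_id")
        assert (
            cat_means["mean_distance_km"] >= all_means["mean_distance_km"] - 1e-12
        ).all()


class TestStateAggregation:
    def test_weighted_mean(self):
        summaries = pd.DataFrame(
            {
                "region_id": ["c1", "c2"],
                "region_kind": "county",
                "category": "All",
                "n_individuals": [1, 3],
                "mean_distance_km": [10.0, 20.0],
            }
        )
        out = aggregate_to_state(summaries, {"c1": "XX", "c2": "XX"})
        assert out.loc[0, "mean_distance_km"] == pytest.approx(17.5)
        assert out.loc[0, "n_individuals"] == 4

    def test_unweighted_alternative(self):
        summaries = pd.DataFrame(
            {
                "region_id": ["c1", "c2"],
                "region_kind": "county",
                "category": "All",
                "n_individuals": [1, 3],
                "mean_distance_km": [10.0, 20.0],
            }
        )
        out = aggregate_to_state(summaries, {"c1": "XX", "c2": "XX"}, weighted=False)
        assert out.loc[0, "mean_distance_km"] == pytest.approx(15.0)

    def test_single_county_state(self):
        summaries = pd.DataFrame(
            {
                "region_id": ["c1"],
                "region_kind": "county",
                "category": "All",
                "n_individuals": [7],
                "mean_distance_km": [12.5],
            }
        )
        out = aggregate_to_state(summaries, {"c1": "YY"})
        assert out.loc[0, "mean_distance_km"] == 12.5

    def test_missing_state_mapping_rejected(self):
        summaries = pd.DataFrame(
            {
                "region_id": ["c1"],
                "region_kind": "county",
                "category": "All",
                "n_individuals": [1],
                "mean_distance_km": [1.0],
            }
        )
        with pytest.raises(ValueError, match="c1"):
            aggregate_to_state(summaries, {})

    def test_state_mean_equals_individual_level_recomputation(self, small_world):
        from gapmap.io import frame_from_records, records_from_frame
        from gapmap.population_sim import simulate_national
        from gapmap.resource_db import process_resources
        from gapmap.synthetic_data import strip_truth

        counties, raw, _ = small_world
        kept, _ = process_resources(records_from_frame(strip_truth(raw)))
        resources = frame_from_records(kept)
        individuals = simulate_national(counties.head(25), rng_seed=3)
        county_means = county_mean_distances(individuals, resources)
        states = aggregate_to_state(county_means, counties).set_index("region_id")

        # oracle: recompute straight from the individual-level distances
        from gapmap.access_metrics import ResourceIndex

        idx = ResourceIndex(resources["latitude"], resources["longitude"])
        _, dist = idx.query(individuals["latitude"], individuals["longitude"])
        by_state = (
            pd.DataFrame(
                {
                    "state": individuals["county_id"].map(
                        dict(zip(counties["county_id"], counties["state"]))
                    ),
                    "d": dist,
                }
            )
            .groupby("state")["d"]
            .mean()
        )
        for state, expected in by_state.items():
            assert states.loc[state, "mean_distance_km"] == pytest.approx(
                expected, rel=1e-12
            )


class TestRanking:
    def test_descending_order(self):
        summaries = pd.DataFrame(
            {
                "region_id": ["A", "B", "C"],
                "region_kind": "state",
                "category": "All",
                "n_individuals": 1,
                "mean_distance_km": [5.0, 9.0, 7.0],
            }
        )
        assert rank_regions(summaries)["region_id"].tolist() == ["B", "C", "A"]
        assert rank_regions(summaries, "ascending")["region_id"].tolist() == ["A", "C", "B"]

    def test_ties_break_by_region_id(self):
        summaries = pd.DataFrame(
            {
                "region_id": ["Z", "A", "M"],
                "region_kind": "state",
                "category": "All",
                "n_individuals": 1,
                "mean_distance_km": [3.0, 3.0, 3.0],
            }
        )
        assert rank_regions(summaries)["region_id"].tolist() == ["A", "M", "Z"]

    def test_top10_matches_independent_sort(self):
        rng = np.random.default_rng(5)
        summaries = pd.DataFrame(
            {
                "region_id": [f"S{i:02d}" for i in range(50)],
                "region_kind": "state",
                "category": "All",
                "n_individuals": 1,
                "mean_distance_km": rng.uniform(1, 100, 50).round(1),
            }
        )
        expected = sorted(
            zip(summaries["mean_distance_km"], summaries["region_id"]),
            key=lambda t: (-t[0], t[1]),
        )[:10]
        got = rank_regions(summaries).head(10)
        assert got["region_id"].tolist() == [r for _, r in expected]


class TestDensityGrid:
    def test_one_point_per_quadrant(self):
        grid = density_grid([0.25, 0.25, 0.75, 0.75], [0.25, 0.75, 0.25, 0.75], 2, 2,
                            extent=(0, 0, 1, 1))
        np.testing.assert_array_equal(grid.counts, [[1, 1], [1, 1]])
        assert grid.n_outside == 0

    def test_all_points_one_cell(self):
        grid = density_grid([0.1] * 5, [0.1] * 5, 3, 3, extent=(0, 0, 1, 1))
        assert grid.counts[0, 0] == 5
        assert grid.counts.sum() == 5

    def test_conservation_with_outside_points(self):
        rng = np.random.default_rng(8)
        lat = rng.uniform(-10, 10, 1000)
        lon = rng.uniform(-10, 10, 1000)
        grid = density_grid(lat, lon, 5, 5, extent=(-5, -5, 5, 5))
        assert grid.counts.sum() + grid.n_outside == 1000

    def test_zero_area_extent_rejected(self):
        with pytest.raises(ValueError):
            density_grid([0.0], [0.0], 2, 2, extent=(0, 0, 0, 1))

    def test_frame_round_trip(self):
        grid = density_grid([0.5], [0.5], 2, 2, extent=(0, 0, 1, 1))
        assert isinstance(grid, DensityGrid)
        assert grid.to_frame().to_numpy().sum() == 1
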