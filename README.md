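# gapmap

Quantifying geographic gaps in access to autism services in the United
States — or in any synthetic stand-in for it — from a geocoded directory of
service listings and a county table with population estimates.

Autism spectrum disorder affects roughly 1 in 59 children, yet diagnostic
and therapeutic services are unevenly distributed: most counties host no
diagnostic provider at all, and rural families travel far for one. This
package implements the full analysis pipeline behind that kind of
resource-epidemiology claim, for researchers who want to run it on their own
resource directories (or audit it on synthetic data):

1. **Resource database cleaning** (`gapmap.resource_db`) — discard
   unmappable records, PO boxes, listings whose website text is unrelated to
   autism, and listings with no verifiable contact; deduplicate on rounded
   geo-coordinates + canonicalized program name; allocate each survivor to
   one or more of 7 service categories (*Diagnosis, Therapy, Health,
   Education, Recreation, Support, Other*) by keyword matching
   (`gapmap.keywords`).
2. **Population simulation** (`gapmap.population_sim`) — for each county,
   place `round(population / 59)` points uniformly at random inside the
   county's bounding box; each point is one simulated individual with
   autism.
3. **Access metrics** (`gapmap.access_metrics`) — for every simulated
   individual, the distance to the nearest resource of a category (anywhere,
   not just in their county), via an exact KD-tree search on the unit
   sphere; aggregated to county and state means and ranked.
4. **Resource load** (`gapmap.resource_load`) — a comparative
   demand-over-supply index for diagnostic services,

   RL = N / (59 · R),

   with N the regional population and R its diagnostic resource count,
   pooled to state level and normalized so the least-loaded state scores
   exactly 1.
5. **Synthetic data** (`gapmap.synthetic_data`) — county maps, populations
   and raw resource tables with injected duplicates/invalid records and
   hidden ground-truth labels, so every stage is testable without any
   external download.
6. **Orchestration** (`gapmap.pipeline`, `gapmap.cli`) — one config, one
   command, a reproducible report bundle with a manifest.

## Worked example

The built-in hand-checked fixture has 3 counties in 2 states, 5 resources
and 6 individuals:

```python
from gapmap.io import frame_from_records, records_from_frame
from gapmap.resource_db import process_resources, category_breakdown
from gapmap.access_metrics import county_mean_distances, aggregate_to_state
from gapmap.resource_load import resource_load_table
from gapmap.synthetic_data import worked_fixture

fx = worked_fixture()
kept, discarded = process_resources(records_from_frame(fx["resources"]))
resources = frame_from_records(kept)
print(category_breakdown(kept).to_string(index=False))
county = county_mean_distances(fx["individuals"], resources, "All")
states = aggregate_to_state(county, fx["counties"])
print(states.to_string(index=False))
print(resource_load_table(fx["counties"], resources)
      [["region_id", "N", "R", "raw_load", "normalized_load"]]
      .to_string(index=False))
```

prints

```
     category  count  percent
All resources      5    100.0
    Diagnosis      2     40.0
      Therapy      2     40.0
       Health      1     20.0
    Education      0      0.0
   Recreation      0      0.0
      Support      1     20.0
        Other      0      0.0
region_id region_kind category  n_individuals  mean_distance_km
       AA       state      All              5         36.227051
       BB       state      All              1         23.972412
region_id   N  R  raw_load  normalized_load
       AA 295  1       5.0              5.0
       BB  59  1       1.0              1.0
```

All 5 resources validate; two carry the Diagnosis label (40% of the
database, with multi-labelling allowed), individuals in state AA average
36.2 km from their nearest resource versus 24.0 km in BB, and state AA's
diagnostic load is 5× that of the least-loaded state BB (whose normalized
load is 1 by construction). The fixture's distances are frozen against an
independent great-circle computation, so these numbers double as a
regression oracle.

For an end-to-end run on synthetic data:

```bash
gapmap run --config run.yaml
```

with a `run.yaml` like

```yaml
out_dir: out
synth:
  n_states: 10
  counties_per_state: 6
seed: 1
```

which writes the category breakdown, county/state distance tables, top-10
rankings, the state resource-load table, a resource-density grid and a
`manifest.json` (checksums, parameters, versions, seed) that makes the
bundle byte-for-byte reproducible. Individual stages are exposed as
`gapmap synth / validate / simulate / distances / load`.

## Limitations

Counties are rectangles, not polygons; distances are straight-line
(great-circle by default, flat-projection Euclidean optionally), not road
distances; the simulated population is spatially uniform within each
county; and the resource load is a comparative index, not an absolute
demand estimate. See `docs/methods.md` for the full model description and
the reasoning behind each default.
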