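# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic data does and does not
emulate, and the numerical conventions.

## Resource validation and categorization

A raw resource record carries: program name, description, full address,
phone, email, URL, latitude/longitude (WGS84 decimal degrees), native
service-type phrases, and optionally pre-fetched website text plus a
broken-URL flag. Live HTTP fetching and scraping are deliberately out of
scope; "website broken/missing" is an input fact, which keeps every run
reproducible.

**Discard rules** (checked in priority order; the first hit wins):

1. *unmappable* — either coordinate missing; such records cannot enter any
   distance analysis.
2. *po_box* — the address matches a post-office-box pattern
   (`P.O. Box`, `PO Box`, `Post Office Box`, case-insensitive).
3. *invalid_address* — the address fails a minimal physicality heuristic: it
   must contain a street number (1–6 digit token) and at least one
   alphabetic word. Geocoding-grade address validation is out of scope.
4. *irrelevant_website* — website text is present but contains none of the
   autism-relevance phrases (`autism`, `autistic`, `asd`, `asperger`,
   `developmental disorder`) as a whole phrase.
5. *no_contact* — the URL is missing or flagged broken **and** no email is
   given. If an email *is* given, the record is retained with status
   `pending_email_validation` instead (the email-based re-verification
   workflow itself is out of scope); pending records participate in all
   downstream analyses.

**Deduplication.** Records are equivalent when they agree on
(latitude, longitude) rounded to 4 decimal places (~11 m — wide enough to
merge re-geocoded copies of one listing, narrow enough not to merge
neighbouring providers; configurable) and on the program name canonicalized
by case-folding, punctuation stripping and whitespace collapsing. Within a
class the most complete record survives (count of non-empty optional
fields; ties by input order), inheriting the union of service types and
categories. The survivor set is invariant under input permutation.

**Categorization.** Six categories are keyword-backed (the keyword
vocabulary is the curated service-type taxonomy of the major autism
resource directories); `Other` is the fallback. Native service-type phrases
are matched by *exact* phrase equality after canonicalization (case-fold +
whitespace collapse); only records with no service type fall back to
whole-phrase substring search over their website text. Exact matching is
deliberate: a phrase like "Special Education Attorneys" must *not* match
the Education keyword "Education" — it falls to `Other`. Records may carry
multiple categories, so per-category counts sum to more than the record
total; percentages are always of the record total, rounded half-up to two
decimals (matching how such tables are conventionally printed).

## Population simulation

The affected population is simulated, not observed. Per county, the number
of simulated individuals is `round_half_up(population / d)` with prevalence
denominator `d = 59` (the 1-in-59 prevalence estimate; configurable, as are
floor/ceil rounding). Half-up rounding is computed exactly in integer
arithmetic, `(2N + d) // (2d)`, and minimizes aggregate bias relative to
floor or ceil.

Each individual is an i.i.d. uniform draw inside the county's
*rectangular bounding box* — a deliberate simplification of county
polygons; it distorts most for coastal/irregular counties. Sampling is
uniform in degrees to mirror the simple procedure the analysis models; an
`equal_area` option corrects latitude sampling by cos(latitude) for users
who want density uniform per km².

Randomness: each county gets a sub-seed derived from the top-level seed and
a hash of its county id, so the national simulation is reproducible,
order-independent, and stable under adding/removing counties.

## Distance metrics and nearest-resource search

Default metric is great-circle (haversine) distance on a sphere of radius
6371.0088 km. Because straight-line "Euclidean" distance on lat/lon is only
meaningful locally, an `equirectangular` option provides flat-projection
Euclidean distance (longitude scaled by cos of a reference latitude); at
county scale the two agree to a few parts in 10⁴. Either way, straight-line
distance underestimates true road distance.

Nearest-resource queries use a KD-tree and are *exact*: haversine queries
embed points on the unit sphere, where chord length is strictly monotone in
central angle; equirectangular queries index the projected plane. Ties —
e.g. coincident resources — resolve to the smallest resource index, and a
brute-force scan using the identical distance computation is part of the
public API as an oracle (`ResourceIndex.query_bruteforce`).

County mean distance for a category averages, over the county's simulated
individuals, the distance to the nearest resource carrying that category
*anywhere* (cross-county access is the point of the analysis). A category
with no resources nationally raises an error naming the category rather
than silently producing empty output. Counties with zero simulated
individuals (population below d/2) are omitted from summaries rather than
reported as NaN. State means weight county means by their individual counts
(equivalently: average over all the state's individuals); an unweighted
county-average mode exists because either convention is defensible.
Individuals inherit their county's state, never a coordinate lookup, since
bounding boxes may cross state lines. Rankings sort by mean distance with
ties broken by region id. Because any category's resources are a subset of
all resources, per-category means are bounded below by the all-category
mean — a property the tests assert.

The resource-density grid is a plain 2-D histogram (counts conserve: cells
plus out-of-extent points equal total resources); the heat-map PNG is a
convenience output with no numerical contract.

## Resource load

Raw load of a region: `RL = N / (d · R)` with N its population, R its
count of diagnostic resources (resources assigned to counties by
bounding-box containment; overlapping boxes resolve to the smallest county
id). The index is linear in demand and inversely proportional to supply; it
deliberately carries no absolute meaning (no throughput or waitlist data
enters it) and supports only comparisons within one analysis.

Since most counties have R = 0, the state-level default *pools first*:
state load = (Σ N_c) / (d · Σ R_c), so zero-resource counties contribute
demand but no supply, and the statistic is invariant to how a state is
partitioned into counties. A `county_average` mode (mean of defined county
loads) is provided as the labelled alternative. States with no diagnostic
resource are reported as undefined and excluded from normalization.

Normalization divides every defined load by the exact minimum defined load,
so the least-loaded state scores exactly 1 (floating-point `x / x`),
ratios are preserved, and rescaling all populations by a constant changes
nothing.

## Synthetic data

The generator emulates the analysis inputs, not any real geography:

* **Counties** tile each synthetic state's rectangle with disjoint boxes
  (real county bounding boxes overlap; an overlap mode exists for
  robustness testing, but disjoint tiling keeps point-in-county assignment
  unambiguous for ground-truth tests). Populations are log-normal — median
  26,000, σ = 1.2 by default, mimicking the heavy right tail of real county
  sizes.
* **Resources** are placed population-proportionally (default ≈ 1 listing
  per 11,500 residents, giving a directory-scale database) or as a
  homogeneous Poisson process (used by the analytic benchmarks). Category
  labels follow directory-like marginals (Therapy 0.41, Support 0.29,
  Health 0.26, Education 0.20, Recreation 0.10, Diagnosis 0.09, Other 0.19,
  renormalized for drawing; 15% of keyword-backed records get a second
  category). Service-type phrases are drawn verbatim from the keyword
  taxonomy, so categorization recovers the generating categories with
  probability 1 — an exact recovery test, not a statistical one.
* **Dirt** is injected at configurable rates: near-duplicates (coordinates
  perturbed by < 5×10⁻⁵ degrees — below the dedup rounding cell — names
  case/punctuation-mangled) and one batch per discard reason, each
  constructed to trigger exactly its rule. Ground truth lives in
  `truth_*` columns that `strip_truth` removes before any validation code
  sees the table. Valid coordinates are snapped to the 10⁻⁴-degree lattice
  so duplicate injection is exact by construction.

What the synthetic world does *not* emulate: real address text and
geocoding noise, spatial clustering of resources within counties beyond
the population-proportional county totals, correlated category structure,
reporting bias of directories, and real census vintages. Passing tests
therefore certify the pipeline's arithmetic and contracts, not any claim
about the true U.S. resource landscape.

A hand-checkable worked fixture (3 counties, 5 resources, 6 individuals)
freezes expected outputs computed independently of the pipeline: nearest
distances via the arctangent form of the great-circle formula (a different
expression from the implementation's haversine, agreeing only if both are
right), aggregates and loads by hand arithmetic.

## Problem sizes and numerical conventions

The test suite exercises the pipeline end to end at 3,000 counties /
~100,000 simulated individuals / ~5,000 raw resources — the scale at which
the per-record Python validation loop and the vectorized KD-tree queries
are both comfortably fast on one CPU — and checks the Poisson
nearest-neighbour limit 1/(2√λ) at 20,000 individuals across 20 independent
resource draws, comparing against three Monte-Carlo standard errors of the
batch means (batching is what makes the error estimate honest: individuals
sharing one resource configuration are correlated, so a naive per-individual
standard error would be several times too small).

Tolerances and conventions: percentages half-up to 2 dp; fixture distances
asserted to 10⁻⁹ km; exact-equality assertions wherever the contract is
exact (KD-tree vs. brute force, normalization minimum of 1, dedup counts);
degenerate bounding boxes yield degenerate (not erroneous) samples; empty
inputs raise errors where a statistic would be undefined (breakdown of zero
records, load with no defined state).

## Known limitations

Rectangular counties, straight-line distances, uniform within-county
population, one prevalence denominator nationwide, no capacity/waitlist
modelling, and no live validation of URLs or emails. The pipeline measures
*geometric* access to *listed* resources; both qualifiers matter when
interpreting output.
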