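# Methods

## Study design

The package operationalises a scenario simulation of geographical
accessibility to home medical care. The unit of supply is a hospital or
clinic point (dental clinics excluded); the unit of demand is a
hypothetical patient aged ≥75 placed on a 500 m population mesh. Two
nested facility sets define the scenarios:

* **actual** — facilities observed to provide home medical care, defined
  from claims: at least one claim line with one of the eight home-care fee
  codes, for a patient aged ≥75, in the study fiscal year (2019 by
  default);
* **ideal** — every hospital and clinic.

Because the actual set is a subset of the ideal set and both scenarios
reuse the same patient draws within a run, each patient's ideal cost is
bounded by their actual cost. This monotonicity is asserted on every run
(`run_actual_vs_ideal` raises on violation) and makes every municipal
difference a pure facility-set effect rather than sampling noise.

## Patient simulation

For municipality *m* with patient count `n_m` (distinct qualifying
patients from the claims analysis, or any configured counts) and cell
populations `pop_i`:

* **allocation** — multinomial with `p_i = pop_i / Σ pop` (default), or
  deterministic largest-remainder (Hamilton) rounding with ties going to
  the lower cell index. Multinomial is the default because the trial
  design explicitly randomises patient locations; largest-remainder is
  provided for fully deterministic runs. Cells with zero ≥75 population
  never receive patients.
* **placement** — uniform over the half-open 500 m cell square, in
  continuous coordinates (no sub-grid snapping).
* **repetition** — the whole allocation + placement process is redrawn
  per trial (default 10 trials). Both layers are redrawn because nothing
  in the design privileges holding the allocation fixed.
* **seeding** — one master seed; the stream for each
  (trial, municipality) pair is derived via
  `SeedSequence([seed, trial, crc32(municipality_id)])`, so adding or
  reordering municipalities leaves other municipalities' draws unchanged
  and any trial can be regenerated in isolation.

## Closest-facility travel

The road network is an undirected graph in planar meter coordinates; edge
travel time is `length_m / (speed_kmh·1000/60)` minutes. Facilities and
patients snap to the Euclidean-nearest node (ties to the smallest node
id). A single multi-source Dijkstra run seeded at all facility nodes
yields, per patient, the minimizing facility, the primary cost, and the
secondary metric accumulated along the *same* optimal path — so the
reported minutes and kilometers always describe one route. Cost ties are
broken by facility id, then secondary cost, for determinism.

Choices a user can change, with defaults:

| parameter | default | meaning |
|---|---|---|
| objective | `time` | edge weight minimized (`time` or `distance`) |
| access leg | excluded | snap segments can be added at a straight-line speed |
| n_trials | 10 | patient redraws pooled per scenario |
| distance threshold | 16 km | fee-table reference limit for home visits |
| time threshold | 30 min | exceedance threshold for travel time |
| speeds | per `road_class` on each edge | no congestion or turn modeling |

Travel time is the default objective; the published analyses report both
time and distance without stating which was minimized, and the 16 km rule
argues distance matters, so the objective is a switch and the default is
documented rather than implied. Patients with no route to any facility are
kept with `reachable=False`: they are excluded from percentiles but
counted as exceeding every threshold (a patient with no route exceeds any
limit), with the exclusion count reported — conservative and explicit
rather than silently dropped.

## Summaries

Per municipality and prefecture-wide, over observations pooled across
trials: median and 25–75 percentiles of travel distance (km) and time
(min), computed by linear interpolation (NumPy's default, type-7), and
strict-inequality exceedance rates for the two thresholds ("over 16 km",
"longer than 30 minutes" — exactly 16 km does not exceed). Pooling across
trials is the primary aggregation; per-trial summaries are also emitted so
an averaged-over-trials reading can be inspected. The comparison table is
actual − ideal per municipality, ranked by the travel-time gap.

The municipal characteristics table recomputes population density as
`population / land_area_km2`, displayed at one decimal with the unrounded
value retained, and a Total row whose density uses summed population over
summed area. Claim counts are carried as given data, never recomputed from
rates (printed claim counts and usage-rate × population are not mutually
consistent in all published rows).

## Synthetic data: what it emulates, what it does not

The generator emulates the *statistical structure* the analysis relies on:

* an urban/rural density contrast (compact Gaussian-weighted urban cores
  around 2 800 persons/km² vs sparse rural strips under 100 persons/km²,
  echoing the two-to-three orders of magnitude observed between real
  municipalities);
* a nested provider subset (~35% of facilities, default), urban-biased
  (odds ×4), optionally forced absent in named rural municipalities —
  reproducing the observed pattern of depopulated municipalities whose
  hospitals exist but provide no home care;
* detour-prone rural roads: the lattice over mesh centers keeps only 55%
  of rural edges (connectivity restored by re-adding dropped edges), with
  rural edges 1.45× their chord at 30 km/h vs 1.1× at 40 km/h urban;
* municipal usage rates drawn from 1%–10%, the range seen in
  prefecture-wide claims data; planted patients receive 1–3 qualifying
  claims at providers (every provider guaranteed ≥1), with decoy claims
  interleaved that each violate exactly one qualifying criterion (code,
  age, fiscal year), so every filter clause is independently exercised
  and the claims filter recovers the generator's bookkeeping exactly.

It does **not** emulate: real geography or mesh-code systems, elevation or
mountain-pass travel, facility capacity, household clustering, or
within-cell land use. Passing tests therefore demonstrate the pipeline's
correctness and its qualitative behaviour (gaps concentrate where
providers are absent), not quantitative agreement with any real
prefecture's travel times — those depend on confidential claims data and
real road geometry.

Problem sizes: the packaged demo uses 5 municipalities, 135 mesh cells
(= network nodes), 18 facilities and ~325 patients per trial, chosen so a
full 10-trial two-scenario study runs in well under a second while still
exhibiting the urban/rural contrast; the robustness checks run 20 such
regions and 200 random networks of ≤50 nodes.

## Numerical and degenerate-input conventions

* Coordinates are planar meters throughout; "500 m mesh" means 500 m ×
  500 m square cells identified by center + size (polygons derived).
* Edge lengths must be ≥ the straight-line chord (validated with 1e-9
  relative slack), which guarantees network distance ≥ Euclidean distance.
* CSV round trips use full float precision (`float_precision="round_trip"`
  on read), so save → load is the identity on ids, integers and topology.
* Zero land area, negative populations, `pop_75plus > population`,
  orphan mesh cells, duplicate ids, and facility kinds outside
  {hospital, clinic} are load-time errors naming the file and row;
  a disconnected network is flagged as a warning, not an error.
* Municipalities with zero observations get explicit NaN rows; a
  municipality with patients but zero ≥75 population is an error
  (impossible denominator).
* A patient whose qualifying claims disagree on municipality is counted
  once, in the municipality of the first qualifying claim in file order
  (logged); fiscal-year matching is exact integer equality.

## Known limitations

Facility capacity is deliberately not modeled — every patient is served by
the closest facility regardless of load. Within-municipality disparity,
patients under 75, multi-year trends, one-way streets and time-of-day
congestion are out of scope. The euclidean mode exists as a diagnostic
baseline, not an analysis mode.
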