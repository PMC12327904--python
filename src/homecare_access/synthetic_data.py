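"""A self-consistent toy prefecture with known ground truth.

The generator emulates the geography the analysis assumes — a prefecture
mixing dense urban municipalities with sparse, elongated, depopulated
mountainous ones — at desk scale. Municipal mesh grids are laid side by
side in a strip; the road network is the lattice over mesh centers, with
rural edges thinned (forcing detours) while connectivity is preserved;
facilities are placed preferentially in urban cores and a nested provider
subset is drawn with an urban bias. Claims are then synthesised so that
the claims-filter definitions recover the generator's bookkeeping — the
provider set, per-municipality patient counts and planted usage rates —
exactly.

No attempt is made to imitate any real prefecture's shape, mesh-code
system or elevation; the point is the statistical structure (density
contrast, nested facility sets, detour-prone rural roads), not cartography.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .claims_filter import CLAIM_COLUMNS, HOME_CARE_SERVICE_CODES
from .geodata_model import (Facility, MeshCell, Municipality, RoadNetwork,
                            StudyRegion)

MESH_SIZE_M = 500.0

#: decoy service codes — valid-looking 9-digit codes outside the home-care set
_DECOY_CODES = ("113000110", "111000110", "120000310")


@dataclass(frozen=True)
class GeneratorParams:
    """Shape and intensity parameters of the toy prefecture.

    Defaults give 2 urban and 4 rural municipalities, ~170 mesh cells
    (= network nodes), a >=75 population around 7000 concentrated in the
    urban cores, ~24 facilities of which roughly a third are home-care
    providers (urban-biased), and municipal usage rates spanning 1%–10% —
    the range observed in prefecture-wide claims data. ``rural_no_provider``
    optionally names rural municipalities whose facilities are forced to
    non-provider status, reproducing the depopulated-municipality pattern
    where hospitals exist but none provides home care.
    """

    n_urban: int = 2
    n_rural: int = 4
    urban_grid: tuple[int, int] = (6, 6)    # (cols, rows) of 500 m cells
    rural_grid: tuple[int, int] = (7, 3)    # elongated valley shape
    urban_pop75: int = 3000                 # >=75 population per urban muni
    rural_pop75: int = 120
    urban_share_75: float = 0.12            # pop_75plus / population
    rural_share_75: float = 0.30
    urban_aging_rate: float = 0.28
    rural_aging_rate: float = 0.52
    rural_populated_cell_fraction: float = 0.3
    n_facilities: int = 24
    provider_fraction: float = 0.35
    urban_provider_bias: float = 4.0        # provider odds multiplier, urban
    rural_edge_keep_prob: float = 0.55      # lattice edges kept before reconnect
    urban_detour_factor: float = 1.1        # edge length / chord
    rural_detour_factor: float = 1.45
    urban_speed_kmh: float = 40.0
    rural_speed_kmh: float = 30.0
    usage_rate_range: tuple[float, float] = (0.01, 0.10)
    max_claims_per_patient: int = 3
    decoys_per_patient: float = 1.0
    fiscal_year: int = 2019
    rural_no_provider: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.provider_fraction, self.rural_populated_cell_fraction,
                     *self.usage_rate_range):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.n_facilities < 1:
            raise ValueError("need at least one facility")
        if self.provider_fraction == 0.0:
            # the actual scenario needs at least one provider
            raise ValueError("provider_fraction 0 leaves no provider")


@dataclass
class GroundTruth:
    """Generator bookkeeping enabling exact recovery tests."""

    provider_ids: set[str]
    patient_counts: dict[str, int]          # per municipality
    patient_ids: dict[str, list[str]]       # per municipality
    usage_rates: dict[str, float]           # realized n_patients / pop_75plus


def _municipality_specs(params: GeneratorParams) -> list[dict]:
    specs = []
    for i in range(params.n_urban):
        specs.append({"id": f"U{i+1:02d}", "name": f"Urban-{i+1}", "urban": True,
                      "grid": params.urban_grid, "pop75": params.urban_pop75,
                      "share75": params.urban_share_75,
                      "aging": params.urban_aging_rate})
    for i in range(params.n_rural):
        specs.append({"id": f"R{i+1:02d}", "name": f"Rural-{i+1}", "urban": False,
                      "grid": params.rural_grid, "pop75": params.rural_pop75,
                      "share75": params.rural_share_75,
                      "aging": params.rural_aging_rate})
    return specs


def generate_region(params: GeneratorParams = GeneratorParams()
                    ) -> tuple[StudyRegion, GroundTruth]:
    """Build the toy region and the bookkeeping needed for recovery tests.

    The region passes every structural invariant of the region model:
    mesh population sums match municipal totals, the provider set is
    nested in the facility set, and the road network is connected.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0]))
    specs = _municipality_specs(params)

    municipalities: dict[str, Municipality] = {}
    cells: list[MeshCell] = []
    col_offset = 0
    cell_grid: dict[tuple[int, int], MeshCell] = {}
    urban_ids = set()
    for spec in specs:
        cols, rows_n = spec["grid"]
        mid = spec["id"]
        if spec["urban"]:
            urban_ids.add(mid)
        # population surface: compact gaussian core (urban) or a few
        # scattered valley cells (rural)
        cxs = np.arange(cols)
        rys = np.arange(rows_n)
        gx, gy = np.meshgrid(cxs, rys, indexing="ij")
        if spec["urban"]:
            cx0, cy0 = (cols - 1) / 2.0, (rows_n - 1) / 2.0
            w = np.exp(-(((gx - cx0) / (cols / 4.0)) ** 2
                         + ((gy - cy0) / (rows_n / 4.0)) ** 2))
        else:
            w = np.zeros((cols, rows_n))
            n_pop = max(1, int(round(params.rural_populated_cell_fraction
                                     * cols * rows_n)))
            flat = rng.choice(cols * rows_n, size=n_pop, replace=False)
            w.flat[flat] = rng.uniform(0.5, 1.0, size=n_pop)
        pvec = (w / w.sum()).ravel()
        alloc = rng.multinomial(spec["pop75"], pvec).reshape(cols, rows_n)

        for i in range(cols):
            for j in range(rows_n):
                gcol = col_offset + i
                cell = MeshCell(
                    id=f"{mid}-c{i:02d}r{j:02d}", municipality_id=mid,
                    center_x=(gcol + 0.5) * MESH_SIZE_M,
                    center_y=(j + 0.5) * MESH_SIZE_M,
                    pop_75plus=int(alloc[i, j]), size_m=MESH_SIZE_M)
                cells.append(cell)
                cell_grid[(gcol, j)] = cell
        land_area = cols * rows_n * (MESH_SIZE_M / 1000.0) ** 2
        pop75 = int(alloc.sum())
        population = max(pop75, int(round(pop75 / spec["share75"])))
        municipalities[mid] = Municipality(
            id=mid, name=spec["name"], population=population,
            aging_rate=spec["aging"], land_area_km2=land_area, pop_75plus=pop75)
        col_offset += cols

    network = _build_network(cell_grid, urban_ids, params, rng)
    facilities = _place_facilities(municipalities, cells, urban_ids, params, rng)

    region = StudyRegion(municipalities, cells, facilities, network)
    # planted usage rates: urban at the low-middle of the range, rural
    # spanning it (the observed pattern has no clean urban/rural ordering)
    lo, hi = params.usage_rate_range
    truth_rates: dict[str, float] = {}
    patient_counts: dict[str, int] = {}
    patient_ids: dict[str, list[str]] = {}
    for mid, m in municipalities.items():
        rate = float(rng.uniform(lo, hi))
        n = int(round(rate * m.pop_75plus))
        if m.pop_75plus > 0 and n == 0:
            n = 1  # keep every municipality represented
        patient_counts[mid] = n
        truth_rates[mid] = n / m.pop_75plus if m.pop_75plus else 0.0
        patient_ids[mid] = [f"P-{mid}-{k:04d}" for k in range(n)]
    truth = GroundTruth(
        provider_ids={f.id for f in facilities if f.is_provider},
        patient_counts=patient_counts, patient_ids=patient_ids,
        usage_rates=truth_rates)
    return region, truth


def _build_network(cell_grid, urban_ids, params: GeneratorParams,
                   rng: np.random.Generator) -> RoadNetwork:
    """Lattice over mesh centers; rural edges thinned but kept connected."""
    nodes = []
    node_of: dict[tuple[int, int], str] = {}
    for (gc, r), cell in sorted(cell_grid.items()):
        nid = f"n{gc:03d}-{r:02d}"
        node_of[(gc, r)] = nid
        nodes.append((nid, cell.center_x, cell.center_y))

    def edge_for(a, b):
        ca, cb = cell_grid[a], cell_grid[b]
        rural = (ca.municipality_id not in urban_ids
                 or cb.municipality_id not in urban_ids)
        chord = float(np.hypot(ca.center_x - cb.center_x, ca.center_y - cb.center_y))
        detour = params.rural_detour_factor if rural else params.urban_detour_factor
        speed = params.rural_speed_kmh if rural else params.urban_speed_kmh
        cls = "rural" if rural else "urban"
        return (node_of[a], node_of[b], chord * detour, speed, cls), rural

    kept, dropped = [], []
    for (gc, r) in sorted(cell_grid):
        for nbr in ((gc + 1, r), (gc, r + 1)):
            if nbr not in cell_grid:
                continue
            edge, rural = edge_for((gc, r), nbr)
            if rural and rng.random() > params.rural_edge_keep_prob:
                dropped.append(edge)
            else:
                kept.append(edge)

    # reconnect with union-find over the dropped edges, in random order
    parent = {n[0]: n[0] for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra == rb:
            return False
        parent[ra] = rb
        return True

    for u, v, *_ in kept:
        union(u, v)
    rng.shuffle(dropped)
    for edge in dropped:
        if union(edge[0], edge[1]):
            kept.append(edge)
    return RoadNetwork(nodes=nodes, edges=kept)


def _place_facilities(municipalities, cells, urban_ids, params: GeneratorParams,
                      rng: np.random.Generator) -> list[Facility]:
    """Facility counts ∝ municipal population; providers urban-biased."""
    mids = list(municipalities)
    pops = np.array([municipalities[m].population for m in mids], dtype=float)
    share = pops / pops.sum()
    counts = np.floor(params.n_facilities * share).astype(int)
    counts[counts == 0] = 1  # every municipality hosts at least one facility
    while counts.sum() > params.n_facilities:
        counts[int(np.argmax(counts))] -= 1
    while counts.sum() < params.n_facilities:
        counts[int(np.argmax(share - counts / params.n_facilities))] += 1

    cells_by_m: dict[str, list[MeshCell]] = {m: [] for m in mids}
    for c in cells:
        cells_by_m[c.municipality_id].append(c)

    facilities: list[Facility] = []
    k = 0
    for mid, cnt in zip(mids, counts):
        mcells = cells_by_m[mid]
        weights = np.array([c.pop_75plus + 0.5 for c in mcells])
        weights /= weights.sum()
        for _ in range(int(cnt)):
            cell = mcells[int(rng.choice(len(mcells), p=weights))]
            h = cell.size_m / 2.0
            x = cell.center_x + rng.uniform(-h, h) * 0.8
            y = cell.center_y + rng.uniform(-h, h) * 0.8
            kind = "hospital" if rng.random() < 0.2 else "clinic"
            facilities.append(Facility(id=f"F{k:03d}", kind=kind, x=x, y=y,
                                       is_provider=False))
            k += 1

    # provider draw: urban-biased logistic weights, nested subset
    n_prov = max(1, int(round(params.provider_fraction * len(facilities))))
    eligible = []
    weights = []
    fac_muni = {}
    for f, mid in zip(facilities, np.repeat(mids, counts)):
        fac_muni[f.id] = mid
        if mid in params.rural_no_provider:
            continue
        eligible.append(f)
        weights.append(params.urban_provider_bias if mid in urban_ids else 1.0)
    if not eligible:
        raise ValueError("rural_no_provider excludes every facility")
    w = np.array(weights) / np.sum(weights)
    n_prov = min(n_prov, len(eligible))
    chosen = rng.choice(len(eligible), size=n_prov, replace=False, p=w)
    chosen_ids = {eligible[int(i)].id for i in chosen}
    out = [Facility(f.id, f.kind, f.x, f.y, f.id in chosen_ids) for f in facilities]
    return out


def generate_claims(region: StudyRegion, truth: GroundTruth,
                    params: GeneratorParams = GeneratorParams()) -> pd.DataFrame:
    """Synthesise a claims table consistent with the ground truth.

    Every planted patient gets 1..k qualifying claims at provider
    facilities; every provider is guaranteed at least one qualifying claim
    (so provider identification is exact). Decoy claims are interleaved,
    each non-qualifying by exactly one criterion — wrong service code,
    age < 75, or wrong fiscal year — so each filter clause is exercised
    independently. Applying the claims filter to the output recovers the
    ground truth exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    codes = sorted(HOME_CARE_SERVICE_CODES)
    providers = sorted(truth.provider_ids)
    all_fac = sorted(f.id for f in region.facilities)
    rows: list[tuple] = []

    all_patients: list[tuple[str, str]] = []  # (patient_id, municipality)
    for mid in sorted(truth.patient_ids):
        for pid in truth.patient_ids[mid]:
            all_patients.append((pid, mid))

    if all_patients and not providers:
        raise ValueError("patients planted but no provider facility exists")

    used_providers: set[str] = set()
    for pid, mid in all_patients:
        n_claims = int(rng.integers(1, params.max_claims_per_patient + 1))
        age = int(rng.integers(75, 96))
        for _ in range(n_claims):
            fid = providers[int(rng.integers(len(providers)))]
            used_providers.add(fid)
            rows.append((pid, age, mid, fid,
                         codes[int(rng.integers(len(codes)))], params.fiscal_year))
    # top up providers that drew no claim, reusing existing patients so
    # patient counts are unchanged
    for fid in providers:
        if fid not in used_providers and all_patients:
            pid, mid = all_patients[int(rng.integers(len(all_patients)))]
            rows.append((pid, int(rng.integers(75, 96)), mid, fid,
                         codes[int(rng.integers(len(codes)))], params.fiscal_year))

    # decoys: each breaks exactly one qualifying criterion
    n_decoys = int(round(params.decoys_per_patient * max(len(all_patients), 1)))
    for d in range(n_decoys):
        fid = all_fac[int(rng.integers(len(all_fac)))]
        mid = sorted(region.municipalities)[int(rng.integers(len(region.municipalities)))]
        kind = d % 3
        if kind == 0:    # wrong code
            rows.append((f"D-{d:05d}", int(rng.integers(75, 96)), mid, fid,
                         _DECOY_CODES[d % len(_DECOY_CODES)], params.fiscal_year))
        elif kind == 1:  # under age
            rows.append((f"D-{d:05d}", int(rng.integers(0, 75)), mid, fid,
                         codes[int(rng.integers(len(codes)))], params.fiscal_year))
        else:            # wrong fiscal year
            rows.append((f"D-{d:05d}", int(rng.integers(75, 96)), mid, fid,
                         codes[int(rng.integers(len(codes)))], params.fiscal_year - 1))

    df = pd.DataFrame(rows, columns=CLAIM_COLUMNS)
    return df.sample(frac=1.0, random_state=int(rng.integers(2**31))
                     ).reset_index(drop=True)


def make_demo_fixture(out_dir=None):
    """Deterministic packaged demo study: small, fast, and contrasty.

    Two urban and three rural municipalities (~160 network nodes,
    a few hundred patients); rural municipality ``R02`` hosts a clinic but
    no home-care provider, so the actual-vs-ideal gap concentrates there.
    Returns (region, claims, ground_truth, config dict); with ``out_dir``
    the region layers and claims are also written to disk.
    """
    params = GeneratorParams(
        n_urban=2, n_rural=3,
        urban_grid=(6, 6), rural_grid=(7, 3),
        urban_pop75=2500, rural_pop75=150,
        n_facilities=18, provider_fraction=0.4,
        rural_no_provider=("R02",),
        seed=20190,
    )
    region, truth = generate_region(params)
    claims = generate_claims(region, truth, params)
    config = {"trials": 10, "seed": 7, "objective": "time",
              "allocation_mode": "multinomial",
              "distance_threshold_km": 16.0, "time_threshold_min": 30.0}
    if out_dir is not None:
        from pathlib import Path

        from .geodata_model import save_region
        out_dir = Path(out_dir)
        save_region(region, out_dir)
        claims.to_csv(out_dir / "claims.csv", index=False)
        # paths relative to the config file, so the fixture is relocatable
        # and regenerated file sets are bytewise identical
        cfg = dict(config)
        cfg["region_dir"] = "."
        cfg["claims"] = "claims.csv"
        import yaml
        with open(out_dir / "study.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(cfg, fh)
    return region, claims, truth, config
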