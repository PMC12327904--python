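"""Domain types, file I/O and validation for the study region.

A study region bundles four layers, all in planar projected coordinates in
meters (no geographic lat/lon is kept internally — distances and the 500 m
mesh are metric):

* municipalities — administrative units carrying the >=75 population that
  is the denominator of home-care usage rates;
* mesh cells — axis-aligned 500 m squares carrying the >=75 population
  surface used to place hypothetical patients;
* facilities — hospital/clinic points, with a provider flag marking the
  subset observed to deliver home medical care (dental clinics are out of
  scope and rejected);
* road network — an undirected node/edge graph with per-edge length and
  speed from which travel times are derived.

On-disk representation is header-bearing UTF-8 CSV (plus optional GeoJSON
point/polygon layers for the spatial tables) so that a region survives a
save/load round trip exactly on ids, integer fields and topology.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import Point, box, mapping

FACILITY_KINDS = ("hospital", "clinic")

#: relative slack when checking edge length against the straight-line chord
_CHORD_RTOL = 1e-9


class RegionLoadError(ValueError):
    """A region file failed validation; message names the file and offender."""


@dataclass(frozen=True)
class Municipality:
    """One administrative unit of the study region.

    ``pop_75plus`` is the population aged >=75 — the eligible population
    for home medical care usage rates. ``aging_rate`` is the share aged
    >=65 as a fraction in [0, 1].
    """

    id: str
    name: str
    population: int
    aging_rate: float
    land_area_km2: float
    pop_75plus: int

    def __post_init__(self) -> None:
        if self.land_area_km2 <= 0:
            raise ValueError(f"municipality {self.id!r}: land_area_km2 must be > 0")
        if self.population < 0 or self.pop_75plus < 0:
            raise ValueError(f"municipality {self.id!r}: negative population")
        if self.pop_75plus > self.population:
            raise ValueError(
                f"municipality {self.id!r}: pop_75plus {self.pop_75plus} exceeds "
                f"population {self.population}"
            )
        if not 0 <= self.aging_rate <= 1:
            raise ValueError(f"municipality {self.id!r}: aging_rate outside [0, 1]")

    @property
    def density(self) -> float:
        """Population density in persons per km2 (unrounded)."""
        return self.population / self.land_area_km2


@dataclass(frozen=True)
class MeshCell:
    """One square population-mesh cell (default 500 m on a side)."""

    id: str
    municipality_id: str
    center_x: float
    center_y: float
    pop_75plus: int
    size_m: float = 500.0

    def __post_init__(self) -> None:
        if self.size_m <= 0:
            raise ValueError(f"mesh {self.id!r}: size_m must be > 0")
        if self.pop_75plus < 0:
            raise ValueError(f"mesh {self.id!r}: negative pop_75plus")

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the cell square."""
        h = self.size_m / 2.0
        return (self.center_x - h, self.center_y - h,
                self.center_x + h, self.center_y + h)

    def contains(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.bounds
        return xmin <= x < xmax and ymin <= y < ymax

    def polygon(self):
        """Derived shapely polygon (cells store only center + size)."""
        return box(*self.bounds)


@dataclass(frozen=True)
class Facility:
    """A hospital or clinic point.

    ``is_provider`` marks membership in the observed home-care provider
    subset; the provider set is always nested inside the full facility set,
    which is what makes the actual-vs-ideal scenario contrast monotone.
    """

    id: str
    kind: str
    x: float
    y: float
    is_provider: bool

    def __post_init__(self) -> None:
        if self.kind not in FACILITY_KINDS:
            raise ValueError(
                f"facility {self.id!r}: kind {self.kind!r} not in {FACILITY_KINDS} "
                "(dental clinics are out of scope)"
            )


@dataclass
class RoadNetwork:
    """Undirected road network with per-edge length and design speed.

    nodes: sequence of (id, x, y); edges: sequence of
    (u, v, length_m, speed_kmh, road_class). Edge travel time in minutes is
    ``length_m / (speed_kmh * 1000 / 60)``.
    """

    nodes: list[tuple[str, float, float]]
    edges: list[tuple[str, str, float, float, str]]

    def node_ids(self) -> list[str]:
        return [n[0] for n in self.nodes]

    def node_coords(self) -> dict[str, tuple[float, float]]:
        return {nid: (x, y) for nid, x, y in self.nodes}

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty if valid)."""
        problems: list[str] = []
        coords = self.node_coords()
        if len(coords) != len(self.nodes):
            problems.append("duplicate node ids in network")
        for u, v, length_m, speed_kmh, _cls in self.edges:
            if u not in coords or v not in coords:
                problems.append(f"edge ({u},{v}): endpoint missing from node list")
                continue
            if length_m <= 0 or speed_kmh <= 0:
                problems.append(f"edge ({u},{v}): nonpositive length or speed")
                continue
            chord = math.dist(coords[u], coords[v])
            if length_m < chord * (1.0 - _CHORD_RTOL):
                problems.append(
                    f"edge ({u},{v}): length_m {length_m:.3f} shorter than "
                    f"straight-line distance {chord:.3f}"
                )
        return problems

    def to_networkx(self) -> nx.Graph:
        """Graph with ``length_m``, ``speed_kmh``, ``time_min`` edge attrs.

        Parallel edges collapse to the faster one (undirected simple graph).
        """
        g = nx.Graph()
        for nid, x, y in self.nodes:
            g.add_node(nid, x=x, y=y)
        for u, v, length_m, speed_kmh, cls in self.edges:
            time_min = length_m / (speed_kmh * 1000.0 / 60.0)
            if g.has_edge(u, v) and g[u][v]["time_min"] <= time_min:
                continue
            g.add_edge(u, v, length_m=length_m, speed_kmh=speed_kmh,
                       road_class=cls, time_min=time_min)
        return g


@dataclass
class StudyRegion:
    """A validated bundle of municipalities, mesh, facilities and network."""

    municipalities: dict[str, Municipality]
    mesh_cells: list[MeshCell]
    facilities: list[Facility]
    network: RoadNetwork
    connected: bool = field(default=True, init=False)

    def __post_init__(self) -> None:
        problems = self.validate()
        fatal = [p for p in problems if not p.startswith("warning")]
        if fatal:
            raise RegionLoadError("invalid region:\n  " + "\n  ".join(fatal))

    def validate(self) -> list[str]:
        problems: list[str] = []
        if not self.facilities:
            problems.append("region has no facilities")
        fac_ids = [f.id for f in self.facilities]
        if len(set(fac_ids)) != len(fac_ids):
            problems.append("duplicate facility ids")
        mesh_ids = [c.id for c in self.mesh_cells]
        if len(set(mesh_ids)) != len(mesh_ids):
            problems.append("duplicate mesh ids")
        for cell in self.mesh_cells:
            if cell.municipality_id not in self.municipalities:
                problems.append(
                    f"mesh {cell.id!r} references unknown municipality "
                    f"{cell.municipality_id!r}"
                )
        # mesh-to-municipality population conservation
        sums: dict[str, int] = {}
        for cell in self.mesh_cells:
            sums[cell.municipality_id] = sums.get(cell.municipality_id, 0) + cell.pop_75plus
        for mid, m in self.municipalities.items():
            if mid in sums and sums[mid] != m.pop_75plus:
                problems.append(
                    f"municipality {mid!r}: mesh pop_75plus sum {sums[mid]} != "
                    f"declared {m.pop_75plus}"
                )
        problems.extend(self.network.validate())
        g = self.network.to_networkx()
        if g.number_of_nodes() and not nx.is_connected(g):
            self.connected = False
            problems.append(
                f"warning: network has {nx.number_connected_components(g)} "
                "connected components"
            )
        return problems

    def facility_subset(self, providers_only: bool) -> list[Facility]:
        if providers_only:
            return [f for f in self.facilities if f.is_provider]
        return list(self.facilities)

    def mesh_by_municipality(self) -> dict[str, list[MeshCell]]:
        out: dict[str, list[MeshCell]] = {mid: [] for mid in self.municipalities}
        for cell in self.mesh_cells:
            out[cell.municipality_id].append(cell)
        return out


# ---------------------------------------------------------------------------
# file I/O

_MUNI_COLS = ["id", "name", "population", "aging_rate", "land_area_km2", "pop_75plus"]
_MESH_COLS = ["id", "municipality_id", "center_x", "center_y", "size_m", "pop_75plus"]
_FAC_COLS = ["id", "kind", "x", "y", "is_provider"]
_NODE_COLS = ["id", "x", "y"]
_EDGE_COLS = ["u", "v", "length_m", "speed_kmh", "road_class"]

FILE_NAMES = {
    "municipalities": "municipalities.csv",
    "meshes": "meshes.csv",
    "facilities": "facilities.csv",
    "nodes": "network_nodes.csv",
    "edges": "network_edges.csv",
}


def _read_csv(path: Path, required: Sequence[str]) -> pd.DataFrame:
    if not path.exists():
        raise RegionLoadError(f"{path}: file not found")
    df = pd.read_csv(path, dtype={c: str for c in ("id", "municipality_id", "u", "v")},
                     float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise RegionLoadError(f"{path}: missing columns {missing}")
    return df


def _read_geojson_points(path: Path, props: Sequence[str]) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    rows = []
    for feat in gj.get("features", []):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise RegionLoadError(f"{path}: expected Point features")
        x, y = geom["coordinates"][:2]
        row = {k: feat.get("properties", {}).get(k) for k in props}
        row["x"], row["y"] = x, y
        rows.append(row)
    return pd.DataFrame(rows)


def load_region(directory: str | Path, *, paths: Mapping[str, str | Path] | None = None,
                ) -> StudyRegion:
    """Load and validate a study region from a directory of layer files.

    ``paths`` overrides individual layer file locations; facility and mesh
    layers may instead be GeoJSON point files (``.geojson`` suffix).
    Raises :class:`RegionLoadError` naming the offending file and row on
    schema or invariant violations.
    """
    directory = Path(directory)
    loc = {k: Path(paths[k]) if paths and k in paths else directory / v
           for k, v in FILE_NAMES.items()}

    mdf = _read_csv(loc["municipalities"], _MUNI_COLS)
    municipalities: dict[str, Municipality] = {}
    for i, row in mdf.iterrows():
        mid = str(row["id"])
        if mid in municipalities:
            raise RegionLoadError(f"{loc['municipalities']}: duplicate id {mid!r} (row {i})")
        try:
            municipalities[mid] = Municipality(
                id=mid, name=str(row["name"]),
                population=int(row["population"]),
                aging_rate=float(row["aging_rate"]),
                land_area_km2=float(row["land_area_km2"]),
                pop_75plus=int(row["pop_75plus"]),
            )
        except ValueError as exc:
            raise RegionLoadError(f"{loc['municipalities']} row {i}: {exc}") from exc

    mesh_path = loc["meshes"]
    if mesh_path.suffix == ".geojson":
        cdf = _read_geojson_points(mesh_path, ["id", "municipality_id", "size_m", "pop_75plus"])
        cdf = cdf.rename(columns={"x": "center_x", "y": "center_y"})
    else:
        cdf = _read_csv(mesh_path, _MESH_COLS)
    cells = []
    for i, row in cdf.iterrows():
        try:
            cells.append(MeshCell(
                id=str(row["id"]), municipality_id=str(row["municipality_id"]),
                center_x=float(row["center_x"]), center_y=float(row["center_y"]),
                size_m=float(row["size_m"]), pop_75plus=int(row["pop_75plus"]),
            ))
        except ValueError as exc:
            raise RegionLoadError(f"{mesh_path} row {i}: {exc}") from exc

    fac_path = loc["facilities"]
    if fac_path.suffix == ".geojson":
        fdf = _read_geojson_points(fac_path, ["id", "kind", "is_provider"])
    else:
        fdf = _read_csv(fac_path, _FAC_COLS)
    facilities = []
    for i, row in fdf.iterrows():
        try:
            facilities.append(Facility(
                id=str(row["id"]), kind=str(row["kind"]),
                x=float(row["x"]), y=float(row["y"]),
                is_provider=_parse_bool(row["is_provider"]),
            ))
        except ValueError as exc:
            raise RegionLoadError(f"{fac_path} row {i}: {exc}") from exc

    ndf = _read_csv(loc["nodes"], _NODE_COLS)
    edf = _read_csv(loc["edges"], _EDGE_COLS)
    network = RoadNetwork(
        nodes=[(str(r["id"]), float(r["x"]), float(r["y"])) for _, r in ndf.iterrows()],
        edges=[(str(r["u"]), str(r["v"]), float(r["length_m"]),
                float(r["speed_kmh"]), str(r["road_class"])) for _, r in edf.iterrows()],
    )
    try:
        return StudyRegion(municipalities, cells, facilities, network)
    except RegionLoadError as exc:
        raise RegionLoadError(f"{directory}: {exc}") from exc


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValueError(f"cannot parse boolean {v!r}")


def save_region(region: StudyRegion, directory: str | Path,
                *, geojson: bool = True) -> list[Path]:
    """Write a region to ``directory``; returns the file paths written.

    CSV layers are authoritative and round-trip exactly (coordinates are
    written with ``repr`` precision). GeoJSON point/polygon layers for
    facilities and mesh cells are written alongside for interoperability.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    mdf = pd.DataFrame(
        [(m.id, m.name, m.population, m.aging_rate, m.land_area_km2, m.pop_75plus)
         for m in region.municipalities.values()], columns=_MUNI_COLS)
    cdf = pd.DataFrame(
        [(c.id, c.municipality_id, c.center_x, c.center_y, c.size_m, c.pop_75plus)
         for c in region.mesh_cells], columns=_MESH_COLS)
    fdf = pd.DataFrame(
        [(f.id, f.kind, f.x, f.y, f.is_provider) for f in region.facilities],
        columns=_FAC_COLS)
    ndf = pd.DataFrame(region.network.nodes, columns=_NODE_COLS)
    edf = pd.DataFrame(region.network.edges, columns=_EDGE_COLS)

    for name, df in (("municipalities", mdf), ("meshes", cdf), ("facilities", fdf),
                     ("nodes", ndf), ("edges", edf)):
        path = directory / FILE_NAMES[name]
        df.to_csv(path, index=False, float_format=None)
        written.append(path)

    if geojson:
        fac_features = [
            {"type": "Feature",
             "geometry": mapping(Point(f.x, f.y)),
             "properties": {"id": f.id, "kind": f.kind, "is_provider": f.is_provider}}
            for f in region.facilities]
        mesh_features = [
            {"type": "Feature",
             "geometry": mapping(c.polygon()),
             "properties": {"id": c.id, "municipality_id": c.municipality_id,
                            "pop_75plus": c.pop_75plus, "size_m": c.size_m}}
            for c in region.mesh_cells]
        for fname, feats in (("facilities.geojson", fac_features),
                             ("meshes.geojson", mesh_features)):
            path = directory / fname
            with open(path, "w", encoding="utf-8") as fh:
                json.dump({"type": "FeatureCollection", "features": feats}, fh)
            written.append(path)
    return written


# ---------------------------------------------------------------------------
# summary table

def municipality_summary_table(
    region: StudyRegion | Iterable[Municipality],
    claims_summary: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-municipality characteristics table with a Total row.

    Columns: municipality name, population, aging rate (%), land area
    (km2), population density (persons/km2; ``density`` unrounded,
    ``density_display`` rounded to one decimal), and — when a claims
    summary from :func:`~homecare_access.claims_filter.usage_summary` is
    supplied — the claim count and usage rate (%).

    The Total row sums population/area/claims and recomputes density as
    summed population over summed area; its usage rate is the
    patient-weighted prefecture rate.
    """
    munis = (list(region.municipalities.values())
             if isinstance(region, StudyRegion) else list(region))
    if not munis:
        raise ValueError("no municipalities")
    rows = []
    for m in munis:
        row = {
            "municipality_id": m.id,
            "name": m.name,
            "population": m.population,
            "aging_rate_pct": round(m.aging_rate * 100.0, 1),
            "land_area_km2": m.land_area_km2,
            "density": m.density,
            "density_display": round(m.density, 1),
        }
        rows.append(row)
    df = pd.DataFrame(rows).set_index("municipality_id")

    if claims_summary is not None:
        df = df.join(claims_summary[["n_claims", "n_patients", "usage_rate"]])
        df["n_claims"] = df["n_claims"].fillna(0).astype(int)
        df["n_patients"] = df["n_patients"].fillna(0).astype(int)
        df["usage_rate_pct"] = (df["usage_rate"].fillna(0.0) * 100.0).round(1)

    total_pop = int(df["population"].sum())
    total_area = float(df["land_area_km2"].sum())
    total = {
        "name": "Total",
        "population": total_pop,
        "aging_rate_pct": float("nan"),
        "land_area_km2": total_area,
        "density": total_pop / total_area,
        "density_display": round(total_pop / total_area, 1),
    }
    # aging rate of the total is the population-weighted mean
    weights = np.array([m.population for m in munis], dtype=float)
    if weights.sum() > 0:
        rate = float(np.average([m.aging_rate for m in munis], weights=weights))
        total["aging_rate_pct"] = round(rate * 100.0, 1)
    if claims_summary is not None:
        total["n_claims"] = int(df["n_claims"].sum())
        total["n_patients"] = int(df["n_patients"].sum())
        pop75 = sum(m.pop_75plus for m in munis)
        total["usage_rate"] = (total["n_patients"] / pop75) if pop75 else float("nan")
        total["usage_rate_pct"] = round(total["usage_rate"] * 100.0, 1) if pop75 else float("nan")
    total_df = pd.DataFrame([total], index=pd.Index(["Total"], name="municipality_id"))
    return pd.concat([df, total_df])
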