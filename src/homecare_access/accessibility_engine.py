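"""Closest-facility travel costs on the road network.

For every patient point and a given facility set, find the facility
minimizing a network travel cost (travel time by default) and report both
the minutes and the meters of that same optimal path — the closest
facility may lie outside the patient's own municipality.

The query is a single multi-source Dijkstra run seeded at every facility's
snapped network node, tracking for each settled node which facility won
and the secondary metric accumulated along the winning path. Patients with
no route to any facility are retained with ``reachable=False`` rather than
dropped, so downstream summaries can account for them explicitly.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .geodata_model import Facility, RoadNetwork

ACCESS_COLUMNS = ["patient_id", "facility_id", "network_distance_m",
                  "travel_time_min", "reachable",
                  "snap_distance_patient_m", "snap_distance_facility_m"]


@dataclass(frozen=True)
class CostModel:
    """Cost settings for the closest-facility query.

    objective: which edge weight is minimized — ``"time"`` (minutes,
    default) or ``"distance"`` (meters); the other quantity is reported
    along the same optimal path.
    access_leg_speed_kmh: if set, the straight-line snap segments at the
    patient and facility ends are added to the cost at this speed;
    excluded from the cost by default.
    """

    objective: str = "time"
    access_leg_speed_kmh: float | None = None

    def __post_init__(self) -> None:
        if self.objective not in ("time", "distance"):
            raise ValueError(f"objective must be 'time' or 'distance', got {self.objective!r}")
        if self.access_leg_speed_kmh is not None and self.access_leg_speed_kmh <= 0:
            raise ValueError("access_leg_speed_kmh must be > 0")


def snap_to_network(points: np.ndarray | Sequence[tuple[float, float]],
                    network: RoadNetwork) -> tuple[list[str], np.ndarray]:
    """Euclidean-nearest network node for each point.

    Ties are broken by the smallest node id. Returns (node ids, snap
    distances in m). Accepts a single (x, y) pair or an (n, 2) array.
    """
    if not network.nodes:
        raise ValueError("cannot snap to an empty network")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    # nodes sorted by id so that argmin's first-match rule == smallest id
    nodes = sorted(network.nodes, key=lambda n: n[0])
    ids = [n[0] for n in nodes]
    coords = np.array([(n[1], n[2]) for n in nodes], dtype=float)
    d2 = ((pts[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    idx = np.argmin(d2, axis=1)
    return [ids[i] for i in idx], np.sqrt(d2[np.arange(len(pts)), idx])


def _multi_source_costs(graph: nx.Graph, sources: dict[str, tuple[float, str]],
                        primary: str, secondary: str
                        ) -> dict[str, tuple[float, float, str]]:
    """Multi-source Dijkstra with facility attribution.

    ``sources`` maps a seed node to (initial cost, facility id). Returns,
    per reachable node, (primary cost, secondary cost along the same path,
    winning facility id). Ties on primary cost are broken by facility id,
    then secondary cost, for determinism.
    """
    dist: dict[str, tuple[float, float, str]] = {}
    heap: list[tuple[float, str, float, str]] = []
    for node, (cost0, fid) in sources.items():
        if node in graph:
            heapq.heappush(heap, (cost0, fid, 0.0, node))
    while heap:
        d, fid, sec, node = heapq.heappop(heap)
        if node in dist:
            continue
        dist[node] = (d, sec, fid)
        for nbr, attrs in graph[node].items():
            if nbr in dist:
                continue
            heapq.heappush(heap, (d + attrs[primary], fid, sec + attrs[secondary], nbr))
    return dist


def nearest_facility(patients: pd.DataFrame, facilities: Sequence[Facility],
                     network: RoadNetwork,
                     cost_model: CostModel = CostModel()) -> pd.DataFrame:
    """Closest facility, network distance and travel time per patient.

    ``patients`` needs columns ``id`` (or ``patient_id``), ``x``, ``y``.
    Returns one row per patient with the facility minimizing the cost
    model's objective; ``network_distance_m`` and ``travel_time_min``
    describe the same optimal path. Unreachable patients get
    ``reachable=False`` and infinite costs.
    """
    if not facilities:
        raise ValueError("facility set is empty")
    graph = network.to_networkx()
    primary, secondary = (("time_min", "length_m") if cost_model.objective == "time"
                          else ("length_m", "time_min"))

    fac_xy = np.array([(f.x, f.y) for f in facilities], dtype=float)
    fac_nodes, fac_snap = snap_to_network(fac_xy, network)
    leg_v = cost_model.access_leg_speed_kmh

    # one seed per node; on shared nodes the smaller facility id wins,
    # unless access legs differentiate the initial costs
    sources: dict[str, tuple[float, str]] = {}
    snap_by_fid = {}
    for f, node, sd in sorted(zip(facilities, fac_nodes, fac_snap),
                              key=lambda t: t[0].id):
        snap_by_fid[f.id] = float(sd)
        cost0 = 0.0
        if leg_v is not None:
            cost0 = (sd / (leg_v * 1000.0 / 60.0) if cost_model.objective == "time"
                     else float(sd))
        if node not in sources or cost0 < sources[node][0]:
            sources[node] = (cost0, f.id)
    costs = _multi_source_costs(graph, sources, primary, secondary)

    pid_col = "patient_id" if "patient_id" in patients.columns else "id"
    pts = patients[["x", "y"]].to_numpy(dtype=float)
    pat_nodes, pat_snap = snap_to_network(pts, network)

    rows = []
    for pid, node, sd in zip(patients[pid_col].astype(str), pat_nodes, pat_snap):
        hit = costs.get(node)
        if hit is None:
            rows.append((pid, None, math.inf, math.inf, False, float(sd), math.nan))
            continue
        d, sec, fid = hit
        if leg_v is not None:
            leg = sd / (leg_v * 1000.0 / 60.0) if cost_model.objective == "time" else sd
            d = d + leg
        if cost_model.objective == "time":
            time_min, dist_m = d, sec
        else:
            dist_m, time_min = d, sec
        rows.append((pid, fid, float(dist_m), float(time_min), True,
                     float(sd), snap_by_fid[fid]))
    return pd.DataFrame(rows, columns=ACCESS_COLUMNS)


def euclidean_nearest(patients: pd.DataFrame, facilities: Sequence[Facility],
                      representative_speed_kmh: float = 30.0) -> pd.DataFrame:
    """Straight-line nearest facility — a baseline/diagnostic mode.

    Distance is the Euclidean chord; time converts it at a single
    representative speed. Ties go to the lower facility id. Since every
    network edge is at least as long as its chord, the network distance of
    :func:`nearest_facility` is bounded below by this distance.
    """
    if not facilities:
        raise ValueError("facility set is empty")
    facs = sorted(facilities, key=lambda f: f.id)
    fac_xy = np.array([(f.x, f.y) for f in facs], dtype=float)
    pid_col = "patient_id" if "patient_id" in patients.columns else "id"
    pts = patients[["x", "y"]].to_numpy(dtype=float)
    d = np.sqrt(((pts[:, None, :] - fac_xy[None, :, :]) ** 2).sum(axis=2))
    idx = np.argmin(d, axis=1)  # first minimum -> lowest id (facs sorted)
    best = d[np.arange(len(pts)), idx]
    time_min = best / (representative_speed_kmh * 1000.0 / 60.0)
    return pd.DataFrame({
        "patient_id": patients[pid_col].astype(str).to_numpy(),
        "facility_id": [facs[i].id for i in idx],
        "network_distance_m": best,
        "travel_time_min": time_min,
        "reachable": True,
        "snap_distance_patient_m": 0.0,
        "snap_distance_facility_m": 0.0,
    })
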