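"""Closest-facility engine: snapping, shortest paths, oracle equivalence."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from homecare_access import (
    CostModel,
    Facility,
    RoadNetwork,
    euclidean_nearest,
    nearest_facility,
    snap_to_network,
)

from conftest import patients_frame, random_network


def fac(id, x, y, provider=True):
    return Facility(id=id, kind="clinic", x=x, y=y, is_provider=provider)


class TestSnap:
    def test_coincident_point(self, line_network):
        nodes, dists = snap_to_network([(1000.0, 0.0)], line_network)
        assert nodes == ["B"] and dists[0] == 0.0

    def test_equidistant_tie_breaks_to_smaller_id(self):
        net = RoadNetwork(nodes=[("a", 0, 0), ("b", 10, 0)],
                          edges=[("a", "b", 10, 30, "local")])
        nodes, _ = snap_to_network([(5.0, 0.0)], net)
        assert nodes == ["a"]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(42)
        net = random_network(rng, 40)
        pts = rng.uniform(0, 10_000, size=(100, 2))
        got_nodes, got_d = snap_to_network(pts, net)
        coords = net.node_coords()
        for p, gn, gd in zip(pts, got_nodes, got_d):
            best = min(coords, key=lambda n: (np.hypot(*(p - coords[n])), n))
            assert gn == best
            assert gd == pytest.approx(np.hypot(*(p - coords[best])))

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            snap_to_network([(0, 0)], RoadNetwork(nodes=[], edges=[]))


class TestNearestFacility:
    def test_patient_at_facility_node(self, line_network):
        res = nearest_facility(patients_frame([("p", 0.0, 0.0)]),
                               [fac("F1", 0, 0)], line_network)
        assert res.loc[0, "facility_id"] == "F1"
        assert res.loc[0, "network_distance_m"] == 0.0
        assert res.loc[0, "travel_time_min"] == 0.0

    def test_line_graph_hand_computed(self, line_network):
        """Facility at A, patient at C: 2000 m at 30 km/h -> 4.0 min."""
        res = nearest_facility(patients_frame([("p", 2000.0, 0.0)]),
                               [fac("F1", 0, 0)], line_network)
        assert res.loc[0, "network_distance_m"] == pytest.approx(2000.0)
        assert res.loc[0, "travel_time_min"] == pytest.approx(4.0)

    def test_distance_objective_same_path_both_metrics(self, line_network):
        res = nearest_facility(patients_frame([("p", 2000.0, 0.0)]),
                               [fac("F1", 0, 0)], line_network,
                               CostModel(objective="distance"))
        assert res.loc[0, "network_distance_m"] == pytest.approx(2000.0)
        assert res.loc[0, "travel_time_min"] == pytest.approx(4.0)

    def test_unreachable_flagged_not_dropped(self):
        net = RoadNetwork(
            nodes=[("a", 0, 0), ("b", 100, 0), ("z", 50_000, 0)],
            edges=[("a", "b", 100, 30, "local")])
        res = nearest_facility(patients_frame([("p", 50_000.0, 0.0)]),
                               [fac("F1", 0, 0)], net)
        assert not res.loc[0, "reachable"]
        assert np.isinf(res.loc[0, "travel_time_min"])

    def test_multi_source_equals_exhaustive_oracle(self):
        """Multi-source result == min over per-facility Dijkstra, exactly."""
        rng = np.random.default_rng(2024)
        for _ in range(30):
            n = int(rng.integers(5, 50))
            net = random_network(rng, n)
            g = net.to_networkx()
            coords = net.node_coords()
            k = int(rng.integers(1, 5))
            fids = rng.choice(n, size=k, replace=False)
            facs = [fac(f"F{i}", *coords[f"n{j:02d}"]) for i, j in enumerate(fids)]
            pts = rng.uniform(0, 10_000, size=(10, 2))
            res = nearest_facility(patients_frame(
                [(f"p{i}", *p) for i, p in enumerate(pts)]), facs, net)
            pat_nodes, _ = snap_to_network(pts, net)
            for i, pn in enumerate(pat_nodes):
                best = np.inf
                for f in facs:
                    fn, _ = snap_to_network([(f.x, f.y)], net)
                    try:
                        c = nx.dijkstra_path_length(g, fn[0], pn, weight="time_min")
                    except nx.NetworkXNoPath:
                        c = np.inf
                    best = min(best, c)
                got = res.loc[i, "travel_time_min"]
                if np.isinf(best):
                    assert not res.loc[i, "reachable"]
                else:
                    assert got == pytest.approx(best, abs=1e-9)

    def test_facility_superset_monotonicity(self):
        """Adding facilities can only shrink each patient's optimal cost."""
        rng = np.random.default_rng(9)
        net = random_network(rng, 40)
        coords = net.node_coords()
        node_ids = sorted(coords)
        all_facs = [fac(f"F{i}", *coords[node_ids[j]])
                    for i, j in enumerate(rng.choice(40, size=8, replace=False))]
        sub = all_facs[:3]
        pts = patients_frame([(f"p{i}", *xy) for i, xy in
                              enumerate(rng.uniform(0, 10_000, size=(50, 2)))])
        res_sub = nearest_facility(pts, sub, net)
        res_all = nearest_facility(pts, all_facs, net)
        assert (res_all["travel_time_min"] <= res_sub["travel_time_min"] + 1e-9).all()

    def test_empty_facility_set_rejected(self, line_network):
        with pytest.raises(ValueError):
            nearest_facility(patients_frame([("p", 0, 0)]), [], line_network)


class TestEuclidean:
    def test_single_facility_always_chosen(self):
        res = euclidean_nearest(patients_frame([("p", 0, 0), ("q", 5, 5)]),
                                [fac("F1", 3, 4)])
        assert (res["facility_id"] == "F1").all()
        assert res.loc[0, "network_distance_m"] == pytest.approx(5.0)

    def test_tie_goes_to_lower_facility_id(self):
        res = euclidean_nearest(patients_frame([("p", 0.0, 0.0)]),
                                [fac("F2", 10, 0), fac("F1", -10, 0)])
        assert res.loc[0, "facility_id"] == "F1"

    def test_network_distance_dominates_euclidean(self):
        """Edge lengths >= chords, so network distance >= straight line."""
        rng = np.random.default_rng(77)
        net = random_network(rng, 35)
        coords = net.node_coords()
        node_ids = sorted(coords)
        facs = [fac(f"F{i}", *coords[node_ids[j]])
                for i, j in enumerate(rng.choice(35, size=4, replace=False))]
        # patients on network nodes so no snap gap biases the comparison
        pts = patients_frame([(f"p{i}", *coords[node_ids[j]]) for i, j in
                              enumerate(rng.choice(35, size=20, replace=False))])
        net_res = nearest_facility(pts, facs, net,
                                   CostModel(objective="distance"))
        euc_res = euclidean_nearest(pts, facs)
        reach = net_res["reachable"]
        assert (net_res.loc[reach, "network_distance_m"] + 1e-9
                >= euc_res.loc[reach, "network_distance_m"]).all()
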