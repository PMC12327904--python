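import numpy as np
import pandas as pd
import pytest

from homecare_access import (
    Facility,
    MeshCell,
    Municipality,
    RoadNetwork,
    StudyRegion,
    make_demo_fixture,
)


@pytest.fixture(scope="session")
def tiny_region() -> StudyRegion:
    """One municipality, 4 mesh cells (2x2), 2 facilities, 4-node ring network."""
    muni = Municipality(id="M1", name="Miniville", population=100,
                        aging_rate=0.35, land_area_km2=1.0, pop_75plus=40)
    cells = [
        MeshCell(id="c00", municipality_id="M1", center_x=250, center_y=250, pop_75plus=10),
        MeshCell(id="c10", municipality_id="M1", center_x=750, center_y=250, pop_75plus=10),
        MeshCell(id="c01", municipality_id="M1", center_x=250, center_y=750, pop_75plus=10),
        MeshCell(id="c11", municipality_id="M1", center_x=750, center_y=750, pop_75plus=10),
    ]
    facilities = [
        Facility(id="F1", kind="clinic", x=250, y=250, is_provider=True),
        Facility(id="F2", kind="hospital", x=750, y=750, is_provider=False),
    ]
    network = RoadNetwork(
        nodes=[("n00", 250, 250), ("n10", 750, 250), ("n01", 250, 750), ("n11", 750, 750)],
        edges=[("n00", "n10", 500, 30, "local"), ("n10", "n11", 500, 30, "local"),
               ("n11", "n01", 500, 30, "local"), ("n01", "n00", 500, 30, "local")],
    )
    return StudyRegion({"M1": muni}, cells, facilities, network)


@pytest.fixture(scope="session")
def line_network() -> RoadNetwork:
    """A--B--C line, each edge 1000 m at 30 km/h (2 min per edge)."""
    return RoadNetwork(
        nodes=[("A", 0, 0), ("B", 1000, 0), ("C", 2000, 0)],
        edges=[("A", "B", 1000, 30, "local"), ("B", "C", 1000, 30, "local")],
    )


@pytest.fixture(scope="session")
def demo():
    """The packaged deterministic demo study (region, claims, truth, config)."""
    region, claims, truth, config = make_demo_fixture()
    return region, claims, truth, config


def random_network(rng: np.random.Generator, n_nodes: int) -> RoadNetwork:
    """Random connected planar-ish network for oracle comparisons."""
    xy = rng.uniform(0, 10_000, size=(n_nodes, 2))
    ids = [f"n{i:02d}" for i in range(n_nodes)]
    edges = []
    # random spanning tree, then extra chords
    order = rng.permutation(n_nodes)
    for k in range(1, n_nodes):
        i, j = int(order[k]), int(order[int(rng.integers(0, k))])
        edges.append((i, j))
    n_extra = int(rng.integers(0, n_nodes))
    for _ in range(n_extra):
        i, j = int(rng.integers(n_nodes)), int(rng.integers(n_nodes))
        if i != j:
            edges.append((i, j))
    out = []
    seen = set()
    for i, j in edges:
        key = (min(i, j), max(i, j))
        if key in seen:
            continue
        seen.add(key)
        chord = float(np.hypot(*(xy[i] - xy[j])))
        length = chord * float(rng.uniform(1.0, 1.6)) + 1.0
        speed = float(rng.choice([20.0, 30.0, 50.0]))
        out.append((ids[i], ids[j], length, speed, "any"))
    return RoadNetwork(nodes=[(ids[i], *xy[i]) for i in range(n_nodes)], edges=out)


def patients_frame(points) -> pd.DataFrame:
    return pd.DataFrame(points, columns=["id", "x", "y"])
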