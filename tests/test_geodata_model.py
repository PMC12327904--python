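"""Region model: validation, file round trips, and the summary table."""

import dataclasses

import pandas as pd
import pytest

from homecare_access import (
    Facility,
    MeshCell,
    Municipality,
    RegionLoadError,
    StudyRegion,
    load_region,
    municipality_summary_table,
    save_region,
)
from homecare_access.geodata_model import FILE_NAMES


def test_domain_type_invariants():
    with pytest.raises(ValueError):
        Municipality(id="m", name="m", population=10, aging_rate=0.5,
                     land_area_km2=0.0, pop_75plus=1)
    with pytest.raises(ValueError):
        Municipality(id="m", name="m", population=10, aging_rate=0.5,
                     land_area_km2=1.0, pop_75plus=11)
    with pytest.raises(ValueError, match="dental"):
        Facility(id="f", kind="dental_clinic", x=0, y=0, is_provider=False)
    with pytest.raises(ValueError):
        MeshCell(id="c", municipality_id="m", center_x=0, center_y=0,
                 pop_75plus=-1)


def test_mesh_population_conservation_enforced(tiny_region):
    muni = dataclasses.replace(tiny_region.municipalities["M1"], pop_75plus=41)
    with pytest.raises(RegionLoadError, match="sum"):
        StudyRegion({"M1": muni}, tiny_region.mesh_cells,
                    tiny_region.facilities, tiny_region.network)


def test_orphan_mesh_cell_rejected(tiny_region):
    cells = tiny_region.mesh_cells + [
        MeshCell(id="orphan", municipality_id="X", center_x=0, center_y=0,
                 pop_75plus=0)]
    with pytest.raises(RegionLoadError, match="'X'"):
        StudyRegion(dict(tiny_region.municipalities), cells,
                    tiny_region.facilities, tiny_region.network)


def test_edge_shorter_than_chord_rejected(tiny_region):
    from homecare_access import RoadNetwork
    net = RoadNetwork(nodes=[("a", 0, 0), ("b", 1000, 0)],
                      edges=[("a", "b", 900, 30, "local")])
    assert any("shorter than" in p for p in net.validate())


def test_save_load_round_trip(tiny_region, tmp_path):
    written = save_region(tiny_region, tmp_path)
    assert {p.name for p in written} >= set(FILE_NAMES.values())
    back = load_region(tmp_path)
    assert sorted(back.municipalities) == sorted(tiny_region.municipalities)
    assert [(c.id, c.center_x, c.center_y, c.pop_75plus, c.municipality_id)
            for c in back.mesh_cells] == [
           (c.id, c.center_x, c.center_y, c.pop_75plus, c.municipality_id)
            for c in tiny_region.mesh_cells]
    assert [(f.id, f.kind, f.x, f.y, f.is_provider) for f in back.facilities] \
        == [(f.id, f.kind, f.x, f.y, f.is_provider) for f in tiny_region.facilities]
    assert sorted(back.network.edges) == sorted(tiny_region.network.edges)
    # conservation survives the round trip
    assert sum(c.pop_75plus for c in back.mesh_cells) == \
        back.municipalities["M1"].pop_75plus


def test_generated_region_round_trip(demo, tmp_path):
    region, *_ = demo
    save_region(region, tmp_path)
    back = load_region(tmp_path)
    assert len(back.mesh_cells) == len(region.mesh_cells)
    assert len(back.network.edges) == len(region.network.edges)
    assert {f.id for f in back.facilities if f.is_provider} == \
        {f.id for f in region.facilities if f.is_provider}


def test_load_error_names_file_and_row(tmp_path, tiny_region):
    save_region(tiny_region, tmp_path)
    path = tmp_path / "municipalities.csv"
    df = pd.read_csv(path)
    df.loc[0, "population"] = -5
    df.to_csv(path, index=False)
    with pytest.raises(RegionLoadError, match="municipalities.csv row 0"):
        load_region(tmp_path)


def test_missing_column_rejected(tmp_path, tiny_region):
    save_region(tiny_region, tmp_path)
    path = tmp_path / "facilities.csv"
    pd.read_csv(path).drop(columns="is_provider").to_csv(path, index=False)
    with pytest.raises(RegionLoadError, match="is_provider"):
        load_region(tmp_path)


@pytest.mark.parametrize("population,area,expected", [
    (384, 274.2, 1.4),     # sparse mountainous municipality
    (328, 154.9, 2.1),     # smallest municipality
    (1286651, 3690.9, 348.6),  # whole-prefecture pooled density
])
def test_density_display_rounding(population, area, expected):
    m = Municipality(id="m", name="m", population=population, aging_rate=0.5,
                     land_area_km2=area, pop_75plus=0)
    table = municipality_summary_table([m])
    assert table.loc["m", "density_display"] == pytest.approx(expected)


def test_summary_table_total_row():
    ms = [
        Municipality(id="a", name="A", population=1000, aging_rate=0.30,
                     land_area_km2=10.0, pop_75plus=100),
        Municipality(id="b", name="B", population=500, aging_rate=0.50,
                     land_area_km2=40.0, pop_75plus=200),
    ]
    usage = pd.DataFrame({"n_claims": [30, 10], "n_patients": [20, 8],
                          "usage_rate": [0.2, 0.04]},
                         index=pd.Index(["a", "b"], name="municipality_id"))
    table = municipality_summary_table(ms, usage)
    total = table.loc["Total"]
    assert total["population"] == 1500
    assert total["land_area_km2"] == pytest.approx(50.0)
    assert total["density"] == pytest.approx(1500 / 50.0)
    assert total["n_claims"] == 40
    # pooled usage rate = total patients / total pop_75plus
    assert total["usage_rate"] == pytest.approx(28 / 300)


def test_single_municipality_total_equals_row():
    m = Municipality(id="only", name="Only", population=800, aging_rate=0.4,
                     land_area_km2=20.0, pop_75plus=90)
    table = municipality_summary_table([m])
    assert table.loc["Total", "population"] == table.loc["only", "population"]
    assert table.loc["Total", "density"] == pytest.approx(table.loc["only", "density"])
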