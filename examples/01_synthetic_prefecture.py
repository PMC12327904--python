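"""Generate a toy prefecture and inspect its urban/rural structure.

The generator builds a small region mixing dense urban municipalities with
sparse mountainous ones: a 500 m population mesh for residents aged >=75,
hospitals/clinics with a nested home-care provider subset, and a road
network whose rural edges are thinned and detour-prone.
"""

from homecare_access import GeneratorParams, generate_region, municipality_summary_table

region, truth = generate_region(GeneratorParams(seed=11))

print(f"municipalities : {len(region.municipalities)}")
print(f"mesh cells     : {len(region.mesh_cells)} (500 m squares)")
print(f"facilities     : {len(region.facilities)} "
      f"({sum(f.is_provider for f in region.facilities)} home-care providers)")
print(f"network        : {len(region.network.nodes)} nodes, "
      f"{len(region.network.edges)} edges, connected={region.connected}")

print("\nper-municipality characteristics (density in persons/km2):")
print(municipality_summary_table(region)[
    ["name", "population", "aging_rate_pct", "land_area_km2", "density_display"]
].to_string())
# Urban rows show densities in the thousands; rural rows are 1-2 orders of
# magnitude sparser — the contrast the accessibility analysis feeds on.
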