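"""Consistency arithmetic on the packaged Nara Prefecture reference table.

The packaged table carries the published characteristics of Nara's 39
municipalities. Population density and the prefecture Total row are pure
arithmetic on the printed columns, so the package recomputes them; the
published Nanwa-area scenario medians feed the comparison operation.
"""

import pandas as pd

from homecare_access import Municipality, compare, municipality_summary_table
from homecare_access.datasets import NARA_TOTAL, nanwa_reported_medians, nara_municipal_table

table = nara_municipal_table()
print(f"municipal populations sum to {table['population'].sum():,} "
      f"(published total {NARA_TOTAL['population']:,})")
print(f"municipal claims sum to {table['n_claims'].sum():,} "
      f"(published total {NARA_TOTAL['n_claims']:,})")

munis = [Municipality(id=n, name=n, population=int(r["population"]),
                      aging_rate=r["aging_rate_pct"] / 100.0,
                      land_area_km2=float(r["land_area_km2"]), pop_75plus=0)
         for n, r in table.iterrows()]
summary = municipality_summary_table(munis)
for name in ("Kamikitayama", "Nosegawa", "Total"):
    printed = (NARA_TOTAL["density_printed"] if name == "Total"
               else table.loc[name, "density_printed"])
    print(f"density {name:14s}: recomputed {summary.loc[name, 'density_display']:6.1f}"
          f"  printed {printed:6.1f}")

med = nanwa_reported_medians()
diff = compare(pd.DataFrame({"median_time_min": med["median_time_actual_min"]}),
               pd.DataFrame({"median_time_min": med["median_time_ideal_min"]}))
print("\npublished Nanwa-area medians -> actual-minus-ideal time gaps (min):")
print(diff["delta_median_time_min"].round(1).to_string())
# Totsukawa's 26.8 min gap is the travel time its patients would save if
# every hospital/clinic provided home medical care.
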