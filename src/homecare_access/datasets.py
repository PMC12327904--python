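"""Packaged reference tables for Nara Prefecture (the worked example region).

``nara_municipal_table`` carries the published characteristics of the 39
municipalities of Nara Prefecture — 2020 census population and aging rate,
land area, population density, and the fiscal-year 2019 home-medical-care
claim counts and usage rates from prefecture-wide claims analysis —
together with the prefecture Total row. The printed claim counts and
usage rates are treated as given data (they are outputs of a confidential
claims database, not recomputable here); population density and the Total
row, by contrast, are pure arithmetic on the printed columns, which makes
the table a consistency oracle for
:func:`~homecare_access.geodata_model.municipality_summary_table`.

``nanwa_reported_medians`` carries the published per-municipality median
travel times and distances, under the observed-provider ("actual") and
all-facility ("ideal") scenarios, for the four depopulated municipalities
of the southern Nanwa area where the scenario contrast is largest.
"""

from __future__ import annotations

import io

import pandas as pd

_NARA_CSV = """\
name,population,aging_rate_pct,land_area_km2,density_printed,n_claims,usage_rate_pct
Nara,347947,32.5,276.9,1256.40,34335,6.8
Kashihara,118344,30,39.6,2991.50,5370,3.9
Ikoma,114508,30,53.2,2154.40,7755,5.8
Yamatokoriyama,80760,34.4,42.7,1891.80,5135,4.6
Kashiba,77212,24.8,24.3,3182.70,3931,5.4
Tenri,60717,27.9,86.4,702.6,4160,5.8
Yamatotakada,59797,32.9,16.5,3628.50,3838,4.4
Sakurai,52975,33.1,98.9,535.6,3812,5.4
Katsuragi,37199,28.1,33.7,1103.20,1424,3.4
Koryo,33910,27.3,16.3,2080.40,1154,3.6
Tawaramoto,30840,32.6,21.1,1462.30,1497,4.9
Ikaruga,27408,30.7,14.3,1920.70,2108,6.0
Uda,25732,44.5,247.5,104,2103,4.7
Gojo,25487,42.4,292,87.3,1769,4.2
Oji,23667,28.9,7,3376.20,1518,5.4
Sango,22688,33,8.8,2581.10,2018,7.2
Gose,22259,43.9,60.6,367.4,1096,2.6
Kanmaki,20815,37,6.1,3390.10,1586,5.3
Heguri,17545,39.9,23.9,734.1,2484,7.9
Kawai,16314,40.2,8.2,1982.30,1523,5.3
Oyodo,15530,37.5,38.1,407.6,381,2.2
Kawanishi,7716,36,5.9,1301.20,457,3.6
Ando,6930,37.2,4.3,1607.90,439,4.9
Takatori,6235,43.6,25.8,241.8,274,2.5
Miyake,6097,37.2,4.1,1501.70,457,4.7
Yoshino,5457,54,95.7,57.1,407,2.7
Asuka,4767,43.2,24.1,197.8,238,3.1
Shimoichi,4356,49.7,62,70.3,154,2.0
Yamazoe,2909,51.6,66.5,43.7,289,4.4
Totsukawa,2695,43.4,672.4,4,254,3.6
Higashiyoshino,1337,60.5,131.7,10.2,224,5.1
Mitsue,1298,61.2,79.6,16.3,50,1.6
Soni,1175,53.5,47.8,24.6,140,5.0
Tenkawa,1048,53.3,175.7,6,60,1.5
Kawakami,1039,56.1,269.3,3.9,112,2.7
Shimokitayama,690,47.9,133.4,5.2,39,2.1
Kurotaki,536,54,47.7,11.2,24,0.9
Kamikitayama,384,49.6,274.2,1.4,37,2.6
Nosegawa,328,51.6,154.9,2.1,62,10.5
"""

#: printed prefecture Total row (column sums and pooled density/rate)
NARA_TOTAL = {
    "population": 1286651,
    "aging_rate_pct": 32.7,
    "land_area_km2": 3690.9,
    "density_printed": 348.6,
    "n_claims": 92714,
    "usage_rate_pct": 5.3,
}

#: published municipal median travel time (min) and distance (km) in the
#: actual (observed providers) and ideal (all facilities) scenarios for the
#: Nanwa-area municipalities with the largest scenario contrast
_NANWA_CSV = """\
name,median_time_actual_min,median_time_ideal_min,median_distance_actual_km,median_distance_ideal_km
Totsukawa,32.6,5.8,28.4,3.9
Kawakami,30.1,11.8,17.2,8.6
Kurotaki,21.3,5.2,13.9,2.1
Kamikitayama,20.7,3.5,10.8,1.5
"""


def nara_municipal_table(include_total: bool = False) -> pd.DataFrame:
    """The published municipal characteristics table, indexed by name.

    With ``include_total=True`` the prefecture Total row is appended.
    """
    df = pd.read_csv(io.StringIO(_NARA_CSV)).set_index("name")
    if include_total:
        df.loc["Total"] = pd.Series(NARA_TOTAL)
        df["population"] = df["population"].astype(int)
        df["n_claims"] = df["n_claims"].astype(int)
    return df


def nanwa_reported_medians() -> pd.DataFrame:
    """Published Nanwa-area municipal medians per scenario, indexed by name.

    The travel-time columns feed the scenario comparison directly: the
    reported actual-minus-ideal gaps are 26.8 (Totsukawa), 18.3
    (Kawakami), 16.1 (Kurotaki) and 17.2 (Kamikitayama) minutes.
    """
    return pd.read_csv(io.StringIO(_NANWA_CSV)).set_index("name")
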