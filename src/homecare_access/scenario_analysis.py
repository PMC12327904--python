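"""Actual-vs-ideal scenario runs and per-municipality disparity summaries.

The *actual* scenario restricts the facility set to observed home-care
providers; the *ideal* scenario uses every hospital and clinic. Both
scenarios reuse the identical patient draws within one study run (same
seed), so the contrast is a pure facility-set effect: since the provider
set is nested in the full set, every patient's ideal cost is bounded above
by their actual cost, and every municipal median/rate difference is
nonnegative — an invariant asserted on every run.

The whole patient-generation + closest-facility process is repeated over
``n_trials`` independent trials (default 10) to absorb the locational
uncertainty of patients known only at 500 m mesh resolution;
patient-level observations are pooled across trials before medians and
exceedance rates are taken (per-trial summaries are also available).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .accessibility_engine import CostModel, nearest_facility
from .claims_filter import QualifyingRule, read_claims, usage_summary
from .geodata_model import StudyRegion, load_region, municipality_summary_table
from .patient_simulator import generate_trial

#: index label of the prefecture-wide (all municipalities pooled) summary row
PREFECTURE_ROW_ID = "__prefecture__"


@dataclass(frozen=True)
class ScenarioConfig:
    """One scenario: facility selection plus trial and threshold settings.

    distance_threshold_km defaults to 16 km — the Japanese fee-table
    reference limit on home-visit travel distance; time_threshold_min
    defaults to 30 minutes.
    """

    name: str = "actual"
    providers_only: bool = True
    n_trials: int = 10
    seed: int = 0
    distance_threshold_km: float = 16.0
    time_threshold_min: float = 30.0
    allocation_mode: str = "multinomial"
    cost_model: CostModel = field(default_factory=CostModel)

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.distance_threshold_km <= 0 or self.time_threshold_min <= 0:
            raise ValueError("thresholds must be > 0")


SUMMARY_COLUMNS = [
    "n_patient_obs", "n_unreachable",
    "median_distance_km", "p25_distance_km", "p75_distance_km",
    "median_time_min", "p25_time_min", "p75_time_min",
    "rate_over_16km", "rate_over_30min",
]


def run_scenario(region: StudyRegion, patient_counts: Mapping[str, int],
                 config: ScenarioConfig) -> pd.DataFrame:
    """Run one scenario over all trials; return pooled per-patient results.

    For each trial the patients are regenerated (allocation and within-cell
    placement both redrawn) and routed to the closest facility of the
    scenario's facility set. The returned frame carries ``trial`` and
    ``municipality_id`` columns alongside the access results.
    """
    facilities = region.facility_subset(config.providers_only)
    if not facilities:
        raise ValueError(f"scenario {config.name!r}: facility selection is empty")
    pooled = []
    for t in range(1, config.n_trials + 1):
        patients = generate_trial(region, patient_counts, trial_index=t,
                                  seed=config.seed, mode=config.allocation_mode)
        res = nearest_facility(patients, facilities, region.network,
                               config.cost_model)
        res.insert(0, "trial", t)
        res = res.merge(patients[["id", "municipality_id", "mesh_id"]],
                        left_on="patient_id", right_on="id").drop(columns="id")
        pooled.append(res)
    return pd.concat(pooled, ignore_index=True)


def run_actual_vs_ideal(region: StudyRegion, patient_counts: Mapping[str, int],
                        config: ScenarioConfig = ScenarioConfig()
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run both scenarios on identical patient draws (same seed).

    Returns (actual results, ideal results). Asserts patientwise cost
    monotonicity: with the provider set nested in the full facility set and
    draws shared, no patient can be worse off in the ideal scenario.
    """
    actual = run_scenario(region, patient_counts,
                          replace(config, name="actual", providers_only=True))
    ideal = run_scenario(region, patient_counts,
                         replace(config, name="ideal", providers_only=False))
    key = ["trial", "patient_id"]
    merged = actual.set_index(key).join(ideal.set_index(key), rsuffix="_ideal")
    obj = ("travel_time_min" if config.cost_model.objective == "time"
           else "network_distance_m")
    bad = merged[obj + "_ideal"] > merged[obj] + 1e-9
    if bad.any():
        raise AssertionError(
            f"superset monotonicity violated for {int(bad.sum())} patients")
    return actual, ideal


def summarize(results: pd.DataFrame, region: StudyRegion | None = None,
              distance_threshold_km: float = 16.0,
              time_threshold_min: float = 30.0,
              by_trial: bool = False) -> pd.DataFrame:
    """Per-municipality medians, quartiles and threshold-exceedance rates.

    Percentiles (linear interpolation) are computed over reachable
    observations pooled across trials; exceedance rates use strict
    inequality ("over 16 km", "longer than 30 minutes") with unreachable
    patients counted as exceeding any threshold (a patient with no route
    exceeds every limit) and included in the denominator. Distances are
    reported in km. A prefecture-wide row (index ``PREFECTURE_ROW_ID``)
    pools every municipality. With ``by_trial=True`` rows are per
    (municipality, trial) instead and no prefecture row is added.

    Municipalities of ``region`` with zero observations get a row of NaNs
    (explicit missing markers) with ``n_patient_obs`` 0.
    """
    if results.empty:
        raise ValueError("no access results to summarize")

    def one(group: pd.DataFrame) -> pd.Series:
        n = len(group)
        reach = group[group["reachable"]]
        n_unreach = n - len(reach)
        km = reach["network_distance_m"].to_numpy() / 1000.0
        mins = reach["travel_time_min"].to_numpy()
        if len(reach):
            qd = np.percentile(km, [25, 50, 75])
            qt = np.percentile(mins, [25, 50, 75])
        else:
            qd = qt = [np.nan] * 3
        over_d = int((km > distance_threshold_km).sum()) + n_unreach
        over_t = int((mins > time_threshold_min).sum()) + n_unreach
        return pd.Series({
            "n_patient_obs": n, "n_unreachable": n_unreach,
            "median_distance_km": qd[1], "p25_distance_km": qd[0],
            "p75_distance_km": qd[2],
            "median_time_min": qt[1], "p25_time_min": qt[0], "p75_time_min": qt[2],
            "rate_over_16km": over_d / n, "rate_over_30min": over_t / n,
        })

    if by_trial:
        out = results.groupby(["municipality_id", "trial"]).apply(one, include_groups=False)
    else:
        out = results.groupby("municipality_id").apply(one, include_groups=False)
        out.loc[PREFECTURE_ROW_ID] = one(results)
    for c in ("n_patient_obs", "n_unreachable"):
        out[c] = out[c].astype(int)
    if region is not None and not by_trial:
        missing = [m for m in region.municipalities if m not in out.index]
        for mid in missing:
            out.loc[mid] = pd.Series({"n_patient_obs": 0, "n_unreachable": 0})
        out["n_patient_obs"] = out["n_patient_obs"].fillna(0).astype(int)
        out["n_unreachable"] = out["n_unreachable"].fillna(0).astype(int)
    return out[SUMMARY_COLUMNS]


def compare(summary_actual: pd.DataFrame, summary_ideal: pd.DataFrame) -> pd.DataFrame:
    """Per-municipality scenario differences (actual − ideal), ranked.

    Operates on any pair of summary frames sharing an index and the
    median/rate columns; rows are sorted by the travel-time gap so the
    municipalities that would benefit most from universal provision come
    first. Raises if the two summaries cover different municipalities.
    """
    a, b = summary_actual, summary_ideal
    if set(a.index) != set(b.index):
        only = set(a.index) ^ set(b.index)
        raise ValueError(f"summaries cover different municipalities: {sorted(only)}")
    b = b.reindex(a.index)
    out = pd.DataFrame(index=a.index.copy())
    for col, delta in (("median_time_min", "delta_median_time_min"),
                       ("median_distance_km", "delta_median_distance_km"),
                       ("rate_over_16km", "delta_rate_over_16km"),
                       ("rate_over_30min", "delta_rate_over_30min")):
        if col in a.columns and col in b.columns:
            out[delta] = a[col] - b[col]
    return out.sort_values("delta_median_time_min", ascending=False)


# ---------------------------------------------------------------------------
# full-study driver

def run_full_study(config: str | Path | Mapping, out_dir: str | Path | None = None):
    """Run the whole pipeline from a single YAML/JSON config.

    Config keys (all optional unless noted):

    * ``region_dir`` — directory of region layer files, OR
      ``synthetic`` — parameter mapping for
      :func:`~homecare_access.synthetic_data.generate_region`;
    * ``claims`` — claims CSV path (defaults to synthetic claims when the
      region is synthetic);
    * ``rule`` — mapping with ``codes`` / ``min_age`` / ``fiscal_year``;
    * ``trials`` (default 10), ``seed`` (default 0), ``objective``
      (``time``/``distance``), ``allocation_mode``,
      ``distance_threshold_km`` (16), ``time_threshold_min`` (30).

    Returns a dict bundle with the region, usage table, pooled access
    results, per-scenario summaries and the comparison table; when
    ``out_dir`` is given, every table is written as CSV together with a
    run log recording seeds and settings.
    """
    from . import synthetic_data  # deferred: synthetic_data imports this module's deps

    base = Path(".")
    if isinstance(config, (str, Path)):
        with open(config, encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
        base = Path(config).parent  # relative input paths anchor at the config file
        for key in ("region_dir", "claims"):
            if key in cfg:
                cfg[key] = str(base / cfg[key])
    else:
        cfg = dict(config)

    stage = "load-region"
    try:
        ground_truth = None
        claims = None
        if "region_dir" in cfg:
            region = load_region(cfg["region_dir"])
        elif "synthetic" in cfg:
            params = synthetic_data.GeneratorParams(**cfg["synthetic"])
            region, ground_truth = synthetic_data.generate_region(params)
            claims = synthetic_data.generate_claims(region, ground_truth, params)
        else:
            raise ValueError("config needs 'region_dir' or 'synthetic'")

        stage = "claims"
        rule_cfg = cfg.get("rule", {})
        rule = QualifyingRule(
            code_set=frozenset(str(c) for c in rule_cfg["codes"]) if "codes" in rule_cfg
            else QualifyingRule.code_set,
            min_age=int(rule_cfg.get("min_age", 75)),
            fiscal_year=int(rule_cfg.get("fiscal_year", 2019)))
        if "claims" in cfg:
            claims = read_claims(cfg["claims"])
        if claims is None:
            raise ValueError("no claims source: give 'claims' or 'synthetic'")
        usage = usage_summary(claims, rule, region)
        patient_counts = usage["n_patients"].to_dict()

        stage = "scenarios"
        scen = ScenarioConfig(
            n_trials=int(cfg.get("trials", 10)), seed=int(cfg.get("seed", 0)),
            distance_threshold_km=float(cfg.get("distance_threshold_km", 16.0)),
            time_threshold_min=float(cfg.get("time_threshold_min", 30.0)),
            allocation_mode=str(cfg.get("allocation_mode", "multinomial")),
            cost_model=CostModel(objective=str(cfg.get("objective", "time"))))
        actual, ideal = run_actual_vs_ideal(region, patient_counts, scen)

        stage = "summaries"
        kw = dict(distance_threshold_km=scen.distance_threshold_km,
                  time_threshold_min=scen.time_threshold_min)
        summary_actual = summarize(actual, region, **kw)
        summary_ideal = summarize(ideal, region, **kw)
        comparison = compare(summary_actual.drop(index=PREFECTURE_ROW_ID),
                             summary_ideal.drop(index=PREFECTURE_ROW_ID))
        table = municipality_summary_table(region, usage)
    except Exception as exc:
        raise RuntimeError(f"study failed at stage {stage!r}: {exc}") from exc

    bundle = {
        "region": region, "ground_truth": ground_truth, "usage": usage,
        "access_actual": actual, "access_ideal": ideal,
        "summary_actual": summary_actual, "summary_ideal": summary_ideal,
        "summary_actual_by_trial": summarize(actual, by_trial=True, **kw),
        "summary_ideal_by_trial": summarize(ideal, by_trial=True, **kw),
        "comparison": comparison, "municipality_table": table,
        "config": {"trials": scen.n_trials, "seed": scen.seed,
                   "objective": scen.cost_model.objective,
                   "allocation_mode": scen.allocation_mode,
                   "distance_threshold_km": scen.distance_threshold_km,
                   "time_threshold_min": scen.time_threshold_min,
                   "rule": {"codes": sorted(rule.code_set),
                            "min_age": rule.min_age,
                            "fiscal_year": rule.fiscal_year}},
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name in ("usage", "access_actual", "access_ideal", "summary_actual",
                     "summary_ideal", "summary_actual_by_trial",
                     "summary_ideal_by_trial", "comparison", "municipality_table"):
            bundle[name].to_csv(out_dir / f"{name}.csv")
        with open(out_dir / "run_log.json", "w", encoding="utf-8") as fh:
            json.dump(bundle["config"], fh, indent=2)
    return bundle
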