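"""Scenario runs, municipal summaries and the actual-vs-ideal comparison."""

import numpy as np
import pandas as pd
import pytest

from homecare_access import (
    PREFECTURE_ROW_ID,
    ScenarioConfig,
    compare,
    run_actual_vs_ideal,
    run_full_study,
    run_scenario,
    summarize,
)


def results_frame(times_min, municipality="M1", distances_km=None, reachable=None):
    n = len(times_min)
    distances_km = distances_km if distances_km is not None else [1.0] * n
    reachable = reachable if reachable is not None else [True] * n
    return pd.DataFrame({
        "trial": 1,
        "patient_id": [f"p{i}" for i in range(n)],
        "municipality_id": municipality,
        "facility_id": "F1",
        "network_distance_m": np.array(distances_km) * 1000.0,
        "travel_time_min": times_min,
        "reachable": reachable,
    })


class TestSummarize:
    def test_small_sample_linear_interpolation(self):
        out = summarize(results_frame([10.0, 20.0, 30.0]))
        row = out.loc["M1"]
        assert row["median_time_min"] == 20.0
        assert row["p25_time_min"] == 15.0
        assert row["p75_time_min"] == 25.0
        assert row["p25_time_min"] <= row["median_time_min"] <= row["p75_time_min"]

    def test_rate_zero_when_all_below_threshold(self):
        out = summarize(results_frame([5.0] * 4, distances_km=[10.0] * 4))
        assert out.loc["M1", "rate_over_16km"] == 0.0

    def test_exceedance_strict_inequality(self):
        # exactly 16 km / 30 min does NOT exceed
        out = summarize(results_frame([30.0, 30.1], distances_km=[16.0, 16.1]))
        assert out.loc["M1", "rate_over_16km"] == 0.5
        assert out.loc["M1", "rate_over_30min"] == 0.5

    def test_hand_tallied_rate(self):
        km = [1, 5, 10, 15, 17, 20, 30, 16]  # 3 of 8 strictly over 16
        out = summarize(results_frame([1.0] * 8, distances_km=km))
        assert out.loc["M1", "rate_over_16km"] == pytest.approx(3 / 8)

    def test_unreachable_counted_as_exceeding(self):
        out = summarize(results_frame(
            [1.0, np.inf], distances_km=[1.0, np.inf], reachable=[True, False]))
        row = out.loc["M1"]
        assert row["n_unreachable"] == 1
        assert row["rate_over_16km"] == 0.5
        assert row["median_time_min"] == 1.0  # percentiles over reachable only

    def test_rates_non_increasing_in_threshold(self):
        frame = results_frame(list(range(1, 60, 7)),
                              distances_km=list(range(1, 60, 7)))
        rates = [summarize(frame, distance_threshold_km=t).loc["M1", "rate_over_16km"]
                 for t in (5, 16, 30, 60)]
        assert rates == sorted(rates, reverse=True)

    def test_prefecture_row_pools_all_municipalities(self):
        frame = pd.concat([results_frame([10.0] * 3, "M1"),
                           results_frame([20.0] * 3, "M2")], ignore_index=True)
        out = summarize(frame)
        assert out.loc[PREFECTURE_ROW_ID, "n_patient_obs"] == 6
        med = out.loc[PREFECTURE_ROW_ID, "median_time_min"]
        assert 10.0 <= med <= 20.0


class TestCompare:
    def test_identical_summaries_all_zero(self):
        s = summarize(results_frame([10.0, 20.0, 30.0]))
        diff = compare(s, s)
        assert (diff.fillna(0) == 0).all().all()

    def test_reported_municipal_medians_reproduce_printed_gaps(self):
        """Actual vs ideal municipal medians for the Nanwa-area municipalities."""
        from homecare_access.datasets import nanwa_reported_medians
        med = nanwa_reported_medians()
        actual = pd.DataFrame({"median_time_min": med["median_time_actual_min"]})
        ideal = pd.DataFrame({"median_time_min": med["median_time_ideal_min"]})
        diff = compare(actual, ideal)
        assert diff.loc["Totsukawa", "delta_median_time_min"] == pytest.approx(26.8)
        assert diff.loc["Kawakami", "delta_median_time_min"] == pytest.approx(18.3)
        # ranked: the largest-gap municipality comes first
        assert diff.index[0] == "Totsukawa"

    def test_mismatched_municipalities_rejected(self):
        a = summarize(results_frame([1.0], "M1"))
        b = summarize(results_frame([1.0], "M2"))
        with pytest.raises(ValueError, match="different municipalities"):
            compare(a, b)


class TestRunScenario:
    def test_counts_conserved_across_trials(self, demo):
        region, _, truth, _ = demo
        cfg = ScenarioConfig(n_trials=1, seed=1)
        one = run_scenario(region, truth.patient_counts, cfg)
        assert len(one) == sum(truth.patient_counts.values())
        ten = run_scenario(region, truth.patient_counts,
                           ScenarioConfig(n_trials=10, seed=1))
        assert len(ten) == 10 * len(one)

    def test_same_seed_identical_results(self, demo):
        region, _, truth, _ = demo
        cfg = ScenarioConfig(n_trials=2, seed=42)
        a = run_scenario(region, truth.patient_counts, cfg)
        b = run_scenario(region, truth.patient_counts, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_ideal_never_worse_patientwise(self, demo):
        region, _, truth, _ = demo
        actual, ideal = run_actual_vs_ideal(region, truth.patient_counts,
                                            ScenarioConfig(n_trials=2, seed=3))
        key = ["trial", "patient_id"]
        m = actual.set_index(key).join(ideal.set_index(key), rsuffix="_i")
        assert (m["travel_time_min_i"] <= m["travel_time_min"] + 1e-9).all()
        diff = compare(summarize(actual).drop(index=PREFECTURE_ROW_ID),
                       summarize(ideal).drop(index=PREFECTURE_ROW_ID))
        assert (diff["delta_median_time_min"] >= -1e-9).all()
        assert (diff["delta_rate_over_16km"] >= -1e-9).all()


class TestFullStudy:
    def test_demo_config_end_to_end(self, demo, tmp_path):
        bundle = run_full_study({"synthetic": {"rural_no_provider": ("R02",),
                                               "seed": 20190},
                                 "trials": 2, "seed": 7}, out_dir=tmp_path)
        comp = bundle["comparison"]
        assert comp.loc["R02", "delta_median_time_min"] > 0
        assert (tmp_path / "run_log.json").exists()
        assert (tmp_path / "comparison.csv").exists()

    def test_rerun_is_deterministic(self):
        cfg = {"synthetic": {"seed": 5}, "trials": 1, "seed": 2}
        a = run_full_study(cfg)
        b = run_full_study(cfg)
        pd.testing.assert_frame_equal(a["summary_actual"], b["summary_actual"])
        pd.testing.assert_frame_equal(a["comparison"], b["comparison"])

    def test_stage_errors_are_labelled(self):
        with pytest.raises(RuntimeError, match="stage 'load-region'"):
            run_full_study({"region_dir": "/nonexistent/path"})
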