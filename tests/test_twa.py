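import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pmexposure import StudyConfig
from pmexposure.twa import (
    UndefinedDayError,
    compute_daily_exposure,
    measured_daily,
    scenario_s1,
    scenario_s2,
    scenario_s3,
    twa,
)


class TestGenericTWA:
    def test_single_pair_returns_its_concentration(self):
        assert twa([(17.3, 5.0)]) == pytest.approx(17.3)

    def test_handbook_times_with_study_means(self):
        # hand arithmetic: (26.48*15.86 + 15.30*3.34) / 19.2 = 24.54 (2 d.p.)
        expected = (26.48 * 15.86 + 15.30 * 3.34) / (15.86 + 3.34)
        assert twa([(26.48, 15.86), (15.30, 3.34)]) == pytest.approx(expected, rel=1e-12)
        assert round(twa([(26.48, 15.86), (15.30, 3.34)]), 2) == 24.54

    def test_equal_weights_reduce_to_arithmetic_mean(self, rng):
        c = rng.uniform(0, 50, 6)
        assert twa([(ci, 4.0) for ci in c]) == pytest.approx(float(np.mean(c)))

    def test_zero_total_time_is_undefined(self):
        with pytest.raises(UndefinedDayError):
            twa([(10.0, 0.0), (20.0, 0.0)])

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.floats(0, 500, allow_nan=False),
                st.floats(0.01, 24, allow_nan=False),
            ),
            min_size=1,
            max_size=8,
        ),
        st.floats(0.1, 10),
    )
    def test_boundedness_and_scale_equivariance(self, pairs, k):
        v = twa(pairs)
        cs = [c for c, _ in pairs]
        assert min(cs) - 1e-9 <= v <= max(cs) + 1e-9
        assert twa([(c * k, t) for c, t in pairs]) == pytest.approx(v * k, rel=1e-9)


class TestScenarioS1:
    def test_equal_concentrations_collapse(self, cfg):
        assert scenario_s1(12.0, 12.0, cfg) == pytest.approx(12.0)

    def test_study_mean_inputs(self, cfg):
        assert scenario_s1(26.48, 15.30, cfg) == pytest.approx(24.535, abs=0.005)

    def test_zero_house_concentration(self, cfg):
        assert scenario_s1(0.0, 10.0, cfg) == pytest.approx(10.0 * 3.34 / 19.2)

    def test_missing_mean_excludes_day(self, cfg):
        with pytest.raises(UndefinedDayError):
            scenario_s1(float("nan"), 10.0, cfg)


class TestScenarioS2:
    def test_all_house_day_is_home_monitor_mean(self, cfg, one_day_occupancy):
        day = one_day_occupancy.copy()
        day["microenv"] = "house"
        assert scenario_s2(day, cfg) == pytest.approx(30.0)

    def test_two_term_arithmetic(self, cfg):
        # 12 h house at 30, 2 h outdoor at 10 -> (30*12 + 10*2)/14
        slots = pd.date_range("2023-01-02", periods=28, freq="30min")
        micro = np.array(["house"] * 24 + ["outdoor"] * 4, dtype=object)
        day = pd.DataFrame(
            {"microenv": micro, "c_house": 30.0, "c_outdoor_gps": 10.0}, index=slots
        )
        assert scenario_s2(day, cfg) == pytest.approx((30 * 12 + 10 * 2) / 14, abs=1e-9)

    def test_other_labels_excluded_from_both_sides(self, cfg, one_day_occupancy):
        day = one_day_occupancy.copy()
        day.loc[day.index[:10], "microenv"] = "office"  # 5 h office dropped
        # remaining terms: 18 h house at 30 and 1 h outdoor at 10
        assert scenario_s2(day, cfg) == pytest.approx((30 * 18 + 10 * 1) / 19)

    def test_matches_slot_level_brute_force(self, cfg, rng):
        n = 48
        micro = rng.choice(["house", "outdoor", "office"], n, p=[0.6, 0.2, 0.2])
        day = pd.DataFrame(
            {
                "microenv": micro,
                "c_house": rng.uniform(5, 50, n),
                "c_outdoor_gps": rng.uniform(5, 50, n),
            }
        )
        num = den = 0.0
        for _, r in day.iterrows():
            if r["microenv"] == "house":
                num += r["c_house"] * 0.5
                den += 0.5
            elif r["microenv"] == "outdoor":
                num += r["c_outdoor_gps"] * 0.5
                den += 0.5
        assert scenario_s2(day, cfg) == pytest.approx(num / den, rel=1e-12)


class TestScenarioS3:
    def _day(self, micro, preds, gps=22.0):
        day = pd.DataFrame({"microenv": micro})
        day["c_outdoor_gps"] = gps
        for lab, v in preds.items():
            day[f"c_ind_{lab}"] = v
        return day

    def test_constant_predictions_collapse(self, cfg):
        micro = ["house"] * 30 + ["office"] * 10 + ["outdoor"] * 8
        preds = {m: 9.0 for m in ("house", "office", "educational_facility",
                                  "transportation", "other_indoor")}
        day = self._day(micro, preds, gps=9.0)
        assert scenario_s3(day, cfg) == pytest.approx(9.0)

    def test_two_label_arithmetic(self, cfg):
        # 20 h house at 14, 4 h outdoor at 22 -> (14*20 + 22*4)/24 = 15.33
        micro = ["house"] * 40 + ["outdoor"] * 8
        day = self._day(micro, {"house": 14.0}, gps=22.0)
        assert scenario_s3(day, cfg) == pytest.approx(15.333, abs=0.001)

    def test_matches_generic_twa_on_raw_slot_table(self, cfg, rng):
        labels = ["house", "office", "transportation", "outdoor"]
        micro = rng.choice(labels, 48, p=[0.5, 0.25, 0.05, 0.2])
        preds = {
            lab: rng.uniform(5, 30)
            for lab in ("house", "office", "educational_facility",
                        "transportation", "other_indoor")
        }
        day = self._day(micro, preds, gps=17.0)
        pairs = []
        for m in micro:
            pairs.append((17.0 if m == "outdoor" else preds[m], 0.5))
        from pmexposure.twa import twa

        assert scenario_s3(day, cfg) == pytest.approx(twa(pairs), rel=1e-12)

    def test_missing_prediction_for_occupied_label_excludes_day(self, cfg):
        micro = ["house"] * 40 + ["educational_facility"] * 8
        day = self._day(micro, {"house": 14.0})
        with pytest.raises(UndefinedDayError, match="educational_facility"):
            scenario_s3(day, cfg)

    def test_transportation_gps_switch(self):
        cfg_gps = StudyConfig(transport_uses_gps=True)
        micro = ["house"] * 40 + ["transportation"] * 8
        day = self._day(micro, {"house": 10.0, "transportation": 10.0}, gps=40.0)
        v = scenario_s3(day, cfg_gps)
        assert v == pytest.approx((10 * 20 + 40 * 4) / 24)


class TestMeasuredDaily:
    def _personal(self, values, start="2023-01-02"):
        t = pd.date_range(start, periods=len(values), freq="min")
        return pd.DataFrame({"participant_id": "P1", "timestamp": t, "pm25": values})

    def test_constant_series(self, cfg):
        out = measured_daily(self._personal(np.full(1440, 8.0)), cfg)
        assert out["measured"].iloc[0] == pytest.approx(8.0)

    def test_half_day_levels_average(self, cfg):
        v = np.r_[np.full(720, 10.0), np.full(720, 20.0)]
        out = measured_daily(self._personal(v), cfg)
        assert out["measured"].iloc[0] == pytest.approx(15.0)

    def test_insufficient_coverage_excluded(self, cfg):
        out = measured_daily(self._personal(np.full(600, 8.0)), cfg)  # 10 h only
        assert out.empty

    def test_gap_laden_day_matches_minute_weighted_brute_force(self, cfg, rng):
        v = rng.uniform(2, 40, 1440)
        mask = rng.random(1440) < 0.9  # ~21.6 h valid
        df = self._personal(v)
        df.loc[~mask, "pm25"] = np.nan
        out = measured_daily(df, cfg)
        assert out["measured"].iloc[0] == pytest.approx(float(np.nanmean(df["pm25"])))


class TestDailyTable:
    def test_daily_table_invariants(self, fitted_results, cfg):
        d = fitted_results.daily
        # scenario outputs bounded by their own inputs
        ok = d.dropna(subset=["s1"])
        lo = np.minimum(ok["s1_c_house"], ok["s1_c_outdoor"])
        hi = np.maximum(ok["s1_c_house"], ok["s1_c_outdoor"])
        assert ((ok["s1"] >= lo - 1e-9) & (ok["s1"] <= hi + 1e-9)).all()
        # accounted hours never exceed 24
        from pmexposure.config import MICROENVS

        hours = d[[f"t_{m}" for m in MICROENVS]].sum(axis=1)
        assert (hours <= 24 + 1e-9).all()

    def test_gappy_day_excluded_from_tad_scenarios(self, cfg):
        slots = pd.date_range("2023-01-02", periods=48, freq="30min")
        occ = pd.DataFrame(
            {
                "participant_id": "P1",
                "slot_start": slots,
                "microenv": "house",
                "is_gap": [True] * 10 + [False] * 38,  # 5 h of gaps
                "c_outdoor_gps": 10.0,
                "c_outdoor_home": 8.0,
                "c_ind_house": 9.0,
            }
        )
        home_slots = pd.DataFrame(
            {"participant_id": "P1", "slot_start": slots, "c_house": 30.0}
        )
        personal = pd.DataFrame(
            {
                "participant_id": "P1",
                "timestamp": pd.date_range("2023-01-02", periods=1440, freq="min"),
                "pm25": 12.0,
            }
        )
        daily = compute_daily_exposure(occ, home_slots, personal, cfg)
        row = daily.iloc[0]
        assert np.isnan(row["s2"]) and np.isnan(row["s3"])
        assert row["s1"] == pytest.approx(scenario_s1(30.0, 8.0, cfg))
        assert row["measured"] == pytest.approx(12.0)
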