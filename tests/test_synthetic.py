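import filecmp

import numpy as np
import pandas as pd
import pytest

from pmexposure import SimScenario, simulate_outdoor_field, simulate_study
from pmexposure.io import (
    read_diary,
    read_met,
    read_sensor_table,
    read_series,
    read_track,
)
from pmexposure.kriging import fit_variogram
from pmexposure.synthetic import _peak_series, scenario_from_preset


class TestOutdoorField:
    def test_degenerate_scenario_gives_constant_field(self):
        scn = SimScenario(
            spatial_sill=0.0,
            urban_excess=0.0,
            diurnal_amplitude=0.0,
            day_effect_sd=0.0,
            hour_effect_sd=0.0,
            rng_seed=1,
        )
        field = simulate_outdoor_field(scn)
        x = np.array([500.0, 4000.0, 9000.0])
        v = field(x, x, np.array([0.0, 3000.0, 9000.0]))
        assert np.allclose(v, scn.mean_ugm3)

    def test_sampler_is_deterministic(self):
        scn = SimScenario(rng_seed=5)
        f1 = simulate_outdoor_field(scn)
        f2 = simulate_outdoor_field(scn)
        x = np.linspace(0, 9999, 50)
        t = np.linspace(0, 7 * 1440 - 1, 50)
        assert np.array_equal(f1(x, x[::-1], t), f2(x, x[::-1], t))

    def test_empirical_variogram_recovers_spatial_range(self):
        scn = SimScenario(
            n_sensors=500, diurnal_amplitude=0.0, day_effect_sd=0.0,
            hour_effect_sd=0.0, urban_excess=0.0, rng_seed=42,
        )
        field = simulate_outdoor_field(scn)
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 10_000, (1000, 2))
        z = field(pts[:, 0], pts[:, 1], np.zeros(1000))
        vg = fit_variogram(pts[:, 0], pts[:, 1], z)
        assert abs(vg.range_m - scn.spatial_range_m) / scn.spatial_range_m < 0.25

    def test_urban_excess_raises_core_over_suburbs(self):
        scn = SimScenario(spatial_sill=0.0, day_effect_sd=0.0, hour_effect_sd=0.0,
                          diurnal_amplitude=0.0, rng_seed=2)
        field = simulate_outdoor_field(scn)
        t = np.zeros(1)
        core = field(np.array([5000.0]), np.array([5000.0]), t)[0]
        suburb = field(np.array([800.0]), np.array([800.0]), t)[0]
        assert core - suburb == pytest.approx(scn.urban_excess, rel=0.05)


class TestPeakProcess:
    def test_zero_rate_contributes_nothing(self):
        rng = np.random.default_rng(0)
        assert not _peak_series(rng, 1440, 0.0, 300.0, 3.0).any()

    def test_mean_daily_load_matches_design(self):
        # E[load] = rate * E[M] / decay / 24h
        rng = np.random.default_rng(1)
        loads = [_peak_series(rng, 1440 * 30, 3.0, 290.0, 3.0).mean() for _ in range(5)]
        expected = 3.0 * 290.0 / 3.0 / 24.0
        assert np.mean(loads) == pytest.approx(expected, rel=0.2)


class TestParticipants:
    def test_infiltration_identity_without_peaks(self):
        scn = SimScenario(
            n_participants=1, n_days=2,
            infiltration={**SimScenario().infiltration, "house": (1.0, 0.0)},
            peak_events_per_day=0.0, monitor_noise_sd=0.0,
            sensor_cadence_min=1, rng_seed=3,
        )
        study = simulate_study(scn)
        home = study.homes.iloc[0]
        n_min = scn.n_days * 1440
        outdoor = study.field(
            np.full(n_min, home["x_m"]), np.full(n_min, home["y_m"]), np.arange(n_min)
        )
        assert np.allclose(study.home_monitor["pm25"].to_numpy(), outdoor, atol=1e-9)

    def test_all_house_truth_equals_home_monitor_when_unattenuated(self):
        # with attenuation 1 the breathing zone is the monitor's microenvironment
        scn = SimScenario(
            n_participants=1, n_days=1, peak_personal_attenuation=1.0,
            monitor_noise_sd=0.0, sensor_cadence_min=1, rng_seed=4,
        )
        study = simulate_study(scn)
        diary = study.diary
        house_slots = diary.loc[diary["microenv"] == "house", "slot_start"]
        personal = study.personal.copy()
        personal["slot_start"] = personal["timestamp"].dt.floor("30min")
        merged = personal[personal["slot_start"].isin(house_slots)].merge(
            study.home_monitor, on=["participant_id", "timestamp"], suffixes=("_p", "_h")
        )
        assert np.allclose(merged["pm25_p"], merged["pm25_h"], atol=1e-9)

    def test_occupancy_budget_near_study_pattern(self, small_study):
        diary = small_study.diary
        n_days = diary.groupby("participant_id")["slot_start"].apply(
            lambda s: s.dt.normalize().nunique()
        )
        hours = (
            diary.groupby(["participant_id", "microenv"])["slot_start"].count() * 0.5
        )
        per_day = hours.groupby("microenv").sum() / n_days.sum()
        assert per_day["house"] == pytest.approx(12.0, abs=3.0)
        assert per_day["outdoor"] == pytest.approx(1.5, abs=1.0)
        indoor = per_day.drop("outdoor").sum()
        assert indoor > 19.0  # indoor-dominated days


class TestDesignedBiases:
    def test_home_monitor_exceeds_infiltration_prediction(self):
        """The designed bias: with peaks on, measured home daily means exceed
        the infiltration-only indoor model in >= 80% of participant-days."""
        n_ok = n_tot = 0
        for seed in range(20):
            scn = SimScenario(n_participants=2, n_days=2, n_sensors=10, rng_seed=seed)
            study = simulate_study(scn)
            a, b = scn.infiltration["house"]
            hm = study.home_monitor.copy()
            hm["date"] = hm["timestamp"].dt.normalize()
            for (pid, _), sub in hm.groupby(["participant_id", "date"]):
                home = study.homes.set_index("participant_id").loc[pid]
                t0 = (sub["timestamp"] - pd.Timestamp(scn.start_date)).dt.total_seconds() / 60
                base = a * study.field(
                    np.full(len(sub), home["x_m"]), np.full(len(sub), home["y_m"]),
                    t0.to_numpy(),
                ) + b
                n_tot += 1
                n_ok += sub["pm25"].mean() > base.mean()
        assert n_ok / n_tot >= 0.8

    def test_gps_outdoor_exceeds_home_cell_outdoor(self, small_study):
        """Urban-excess design: outdoor concentration along activity
        trajectories exceeds the outdoor concentration at home."""
        study = small_study
        tr = study.tracks.copy()
        tr["slot_start"] = tr["timestamp"].dt.floor("30min")
        tr = tr.merge(study.diary, on=["participant_id", "slot_start"])
        away = tr[tr["microenv"].isin(["outdoor", "transportation"])]
        t_min = (away["timestamp"] - pd.Timestamp(study.scenario.start_date)).dt.total_seconds() / 60
        c_away = study.field(
            away["x_m"].to_numpy(), away["y_m"].to_numpy(), t_min.to_numpy()
        )
        homes = study.homes
        c_home = []
        for _, h in homes.iterrows():
            n = 500
            tt = np.linspace(0, study.scenario.n_days * 1440 - 1, n)
            c_home.append(
                study.field(np.full(n, h["x_m"]), np.full(n, h["y_m"]), tt).mean()
            )
        assert c_away.mean() > np.mean(c_home)


class TestDeterminismAndValidity:
    def test_fixed_seed_byte_identical_files(self, tmp_path):
        scn = SimScenario(n_participants=2, n_days=2, n_sensors=15, rng_seed=9)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_study(scn).write(d1)
        simulate_study(scn).write(d2)
        for f in d1.iterdir():
            assert filecmp.cmp(f, d2 / f.name, shallow=False), f.name

    def test_emitted_tables_pass_validation(self, tiny_study, tmp_path):
        tiny_study.write(tmp_path)
        for name, reader in [
            ("sensors.csv", read_sensor_table),
            ("diary.csv", read_diary),
            ("tracks.csv", read_track),
            ("met.csv", read_met),
            ("home_monitor.csv", read_series),
            ("personal.csv", read_series),
        ]:
            out = reader(tmp_path / name)
            assert out.n_rejected == 0, name

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError):
            scenario_from_preset("huge")

    def test_scenario_invariants(self):
        with pytest.raises(ValueError):
            SimScenario(spatial_sill=1.0, spatial_nugget=2.0)
        with pytest.raises(ValueError):
            SimScenario(n_participants=0)
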