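"""Model/Results facade over the exposure-assessment pipeline.

:class:`TWAExposureModel` is built from a study dataset (sensor network,
home monitors, GPS tracks, diaries, meteorology, personal monitors and an
indoor-model training table); ``fit()`` runs kriging, indoor-model
training, trajectory fusion and the three TWA scenarios, and returns a
:class:`TWAExposureResults` carrying the per-participant-day exposure
table, evaluation metrics, contribution profiles and a ``summary()``
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import contribution as contrib
from . import evaluation, io, kriging, microenv, trajectory, twa
from .config import INDOOR_MICROENVS, StudyConfig


@dataclass
class ExposureData:
    """The six study tables plus the indoor-model training table."""

    sensors: pd.DataFrame
    home_monitor: pd.DataFrame
    tracks: pd.DataFrame
    diary: pd.DataFrame
    met: pd.DataFrame
    personal: pd.DataFrame
    microenv_training: pd.DataFrame | None = None

    @classmethod
    def from_csv_dir(cls, path) -> "ExposureData":
        """Load a directory written by ``exposure simulate`` (or with the
        same file names), validating every table."""
        path = Path(path)
        kw = {
            "sensors": io.read_sensor_table(path / "sensors.csv").df,
            "home_monitor": io.read_series(path / "home_monitor.csv").df,
            "tracks": io.read_track(path / "tracks.csv").df,
            "diary": io.read_diary(path / "diary.csv").df,
            "met": io.read_met(path / "met.csv").df,
            "personal": io.read_series(path / "personal.csv").df,
        }
        train = path / "microenv_training.csv"
        if train.exists():
            kw["microenv_training"] = pd.read_csv(
                train, parse_dates=["timestamp"], float_precision="round_trip"
            )
        return cls(**kw)

    @classmethod
    def from_simulation(cls, study) -> "ExposureData":
        return cls(
            sensors=study.sensors,
            home_monitor=study.home_monitor,
            tracks=study.tracks,
            diary=study.diary,
            met=study.met,
            personal=study.personal,
            microenv_training=study.microenv_training,
        )


class TWAExposureModel:
    """Personal PM2.5 exposure model over three TWA scenarios."""

    def __init__(self, data: ExposureData, config: StudyConfig | None = None):
        self.data = data
        self.config = config or StudyConfig()

    # -- pipeline stages ---------------------------------------------------

    def _grids(self):
        cfg = self.config
        geom = kriging.GridGeometry.from_points(
            self.data.sensors["x_m"], self.data.sensors["y_m"], cfg.grid_cell_size_m
        )
        g25 = kriging.krige_sensor_series(
            self.data.sensors, geom, "pm25", max_neighbors=cfg.kriging_max_neighbors
        )
        g10 = kriging.krige_sensor_series(
            self.data.sensors, geom, "pm10", max_neighbors=cfg.kriging_max_neighbors
        )
        return geom, g25, g10

    def _features_and_predictions(self, matched25, matched10, predictors):
        """Per-participant hourly feature rows from the GPS-matched kriged
        surfaces, predicted per indoor label and spread to 30-min slots."""
        met = self.data.met.copy()
        met["hour"] = met["timestamp"]
        h25 = matched25.assign(hour=matched25["timestamp"].dt.floor("h"))
        h10 = matched10.assign(hour=matched10["timestamp"].dt.floor("h"))
        g25 = h25.groupby(["participant_id", "hour"], as_index=False)["c_outdoor_gps"].mean()
        g10 = (
            h10.groupby(["participant_id", "hour"], as_index=False)["c_outdoor_gps"]
            .mean()
            .rename(columns={"c_outdoor_gps": "pm10"})
        )
        feats = g25.merge(g10, on=["participant_id", "hour"]).merge(
            met.drop(columns=["timestamp"]), on="hour", how="left"
        )
        feats = feats.rename(columns={"c_outdoor_gps": "outdoor_pm25"})
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = feats["outdoor_pm25"] / feats["pm10"]
        feats["ratio_pm25_pm10"] = np.clip(ratio.fillna(1.0), 1e-6, 1.0)
        feats = feats.dropna(subset=microenv.FEATURES).reset_index(drop=True)

        pred_frames = []
        for label in INDOOR_MICROENVS:
            if label not in predictors:
                continue
            vals = predictors[label].predict(feats)
            hourly = pd.DataFrame(
                {
                    "participant_id": feats["participant_id"],
                    "timestamp": feats["hour"],
                    f"c_ind_{label}": vals,
                }
            )
            slot_frames = []
            for pid, sub in hourly.groupby("participant_id"):
                s = microenv.hourly_to_slots(
                    sub[["timestamp", f"c_ind_{label}"]], f"c_ind_{label}"
                )
                s.insert(0, "participant_id", pid)
                slot_frames.append(s)
            pred_frames.append(pd.concat(slot_frames, ignore_index=True))
        out = pred_frames[0]
        for f in pred_frames[1:]:
            out = out.merge(f, on=["participant_id", "slot_start"], how="outer")
        return out

    def fit(self, seed: int | None = None) -> "TWAExposureResults":
        """Run the full pipeline and return the results object."""
        cfg = self.config
        seed = cfg.rng_seed if seed is None else seed
        if self.data.microenv_training is None:
            raise ValueError("an indoor-model training table is required to fit S3")

        geom, grids25, grids10 = self._grids()
        predictors = microenv.train_all(self.data.microenv_training, seed=seed)

        matched25 = trajectory.match_track_to_grid(self.data.tracks, grids25)
        matched10 = trajectory.match_track_to_grid(self.data.tracks, grids10)
        gps_slots = trajectory.slot_mean_gps(matched25)

        homes = trajectory.infer_homes(self.data.tracks, self.data.diary)
        home_frames = []
        for _, row in homes.sort_values("participant_id").iterrows():
            hs = trajectory.home_cell_series((row["x_m"], row["y_m"]), grids25)
            hs.insert(0, "participant_id", row["participant_id"])
            home_frames.append(hs)
        home_cell = pd.concat(home_frames, ignore_index=True)

        occ = trajectory.build_occupancy(self.data.diary, gps_slots, home_cell)
        preds = self._features_and_predictions(matched25, matched10, predictors)
        occ = occ.merge(preds, on=["participant_id", "slot_start"], how="left")

        hm = self.data.home_monitor.copy()
        hm["slot_start"] = hm["timestamp"].dt.floor("30min")
        home_slots = hm.groupby(["participant_id", "slot_start"], as_index=False)[
            "pm25"
        ].mean().rename(columns={"pm25": "c_house"})

        daily = twa.compute_daily_exposure(occ, home_slots, self.data.personal, cfg)
        return TWAExposureResults(
            model=self,
            daily=daily,
            predictors=predictors,
            occupancy=occ,
            grid_geometry=geom,
            diagnostics={
                "n_hours_kriged": len(grids25),
                "weight_sum_max_err": max(
                    g.diagnostics.get("weight_sum_max_err", 0.0) for g in grids25.values()
                ),
            },
        )


@dataclass
class TWAExposureResults:
    """Fitted exposure estimates and their evaluation."""

    model: TWAExposureModel
    daily: pd.DataFrame
    predictors: dict
    occupancy: pd.DataFrame
    grid_geometry: kriging.GridGeometry
    diagnostics: dict = field(default_factory=dict)

    @property
    def config(self) -> StudyConfig:
        return self.model.config

    def metrics(self) -> pd.DataFrame:
        return evaluation.summarize_scenarios(self.daily)

    def contributions(self) -> pd.DataFrame:
        return contrib.cte_rme_table(self.daily, self.config)

    def paired_tests(self) -> pd.DataFrame:
        return evaluation.paired_comparisons(self.daily)

    def summary(self) -> str:
        """Evaluation table (Mean, S.D., CV, Median, Max, MAE, RMSE, r,
        ratio) plus CTE/RME indoor contributions, as printable text."""
        m = self.metrics()
        cols = ["scenario", "n_days", "mean", "sd", "cv_pct", "median", "max",
                "mae", "rmse", "pearson_r", "mean_ratio_to_measured"]
        lines = ["Daily TWA PM2.5 by scenario (ug/m3)", "-" * 78,
                 m[cols].to_string(index=False, float_format=lambda v: f"{v:8.2f}")]
        c = self.contributions()
        c = c[c["convention"] == self.config.contribution_convention]
        lines += ["", f"Indoor/outdoor contribution ({self.config.contribution_convention})",
                  "-" * 78,
                  c[["scenario", "level", "indoor_pct", "outdoor_pct"]].to_string(
                      index=False, float_format=lambda v: f"{v:7.1f}")]
        return "\n".join(lines)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_table(self.daily.round(6), outdir / "daily_exposure.csv")
        io.write_table(self.metrics().round(6), outdir / "metrics.csv")
        io.write_table(self.contributions().round(6), outdir / "contributions.csv")

    def plot_scatter(self, ax=None):
        """Measured vs estimated scatter per scenario."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for s, marker in zip(("s1", "s2", "s3"), "o^s"):
            m = self.daily[["measured", s]].dropna()
            ax.scatter(m["measured"], m[s], marker=marker, s=18, alpha=0.7, label=s.upper())
        lim = [0, float(np.nanmax(self.daily[["measured", "s1", "s2", "s3"]].to_numpy())) * 1.05]
        ax.plot(lim, lim, "k--", lw=1)
        ax.set_xlabel("measured daily PM2.5 (ug/m3)")
        ax.set_ylabel("estimated daily TWA PM2.5 (ug/m3)")
        ax.legend()
        return ax
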