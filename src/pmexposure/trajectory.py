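"""Fusing GPS tracks, diaries and kriged grids into occupancy series.

The diary is the authoritative occupancy record: when a GPS fix and a
diary label disagree (fix inside the home cell but label "office"), the
label wins. GPS only supplies *where* the outdoor concentration is read
from. Diary gaps are carried explicitly; a participant-day whose gaps
exceed a configurable threshold is excluded downstream, otherwise gap
slots inherit the previous slot's label.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import SLOT_MINUTES, SLOTS_PER_DAY
from .kriging import GridField

logger = logging.getLogger("pmexposure.trajectory")


def _grid_times(grids: dict[pd.Timestamp, GridField]) -> pd.DatetimeIndex:
    return pd.DatetimeIndex(sorted(grids)).sort_values()


def nearest_grid_time(times: pd.DatetimeIndex, t: pd.Series) -> pd.DatetimeIndex:
    """Temporally nearest grid timestamp for each t; ties -> earlier."""
    tv = t.to_numpy()
    gv = times.to_numpy()
    idx = np.searchsorted(gv, tv)
    idx = np.clip(idx, 0, len(gv) - 1)
    prev = np.clip(idx - 1, 0, len(gv) - 1)
    d_next = np.abs(gv[idx] - tv)
    d_prev = np.abs(tv - gv[prev])
    use_prev = d_prev <= d_next  # tie -> earlier timestamp
    return pd.DatetimeIndex(np.where(use_prev, gv[prev], gv[idx]))


def match_track_to_grid(
    track: pd.DataFrame, grids: dict[pd.Timestamp, GridField]
) -> pd.DataFrame:
    """Per-fix outdoor concentration from the temporally nearest grid.

    Fixes outside the grid extent are snapped to the nearest boundary cell
    and counted. Returns the track with added columns ``grid_time`` and
    ``c_outdoor_gps``.
    """
    times = _grid_times(grids)
    out = track.reset_index(drop=True).copy()
    out["grid_time"] = nearest_grid_time(times, out["timestamp"])
    conc = np.empty(len(out))
    n_out = 0
    for gt, sub in out.groupby("grid_time"):
        g = grids[pd.Timestamp(gt)]
        col, row, n = g.geom.clip_locate(sub["x_m"].to_numpy(), sub["y_m"].to_numpy())
        conc[sub.index.to_numpy()] = g.values[row, col]
        n_out += n
    if n_out:
        logger.warning("track matching: %d fix(es) outside grid extent snapped to boundary", n_out)
    out["c_outdoor_gps"] = conc
    return out


def slot_mean_gps(matched: pd.DataFrame) -> pd.DataFrame:
    """Average per-fix outdoor concentrations up to 30-min slots."""
    df = matched.copy()
    df["slot_start"] = df["timestamp"].dt.floor(f"{SLOT_MINUTES}min")
    return (
        df.groupby(["participant_id", "slot_start"], as_index=False)["c_outdoor_gps"]
        .mean()
    )


def home_cell_series(
    home_xy: tuple[float, float], grids: dict[pd.Timestamp, GridField]
) -> pd.DataFrame:
    """Fixed-cell outdoor series at the home location (one row per grid
    time step)."""
    times = _grid_times(grids)
    vals = [grids[t].lookup(home_xy[0], home_xy[1]) for t in times]
    return pd.DataFrame({"timestamp": times, "c_outdoor_home": vals})


def infer_homes(track: pd.DataFrame, diary: pd.DataFrame) -> pd.DataFrame:
    """Residential location per participant: median GPS position over
    house-labeled slots (the panel data carry no explicit home table)."""
    d = diary.copy()
    t = track.copy()
    t["slot_start"] = t["timestamp"].dt.floor(f"{SLOT_MINUTES}min")
    merged = t.merge(d, on=["participant_id", "slot_start"], how="inner")
    at_home = merged[merged["microenv"] == "house"]
    homes = (
        at_home.groupby("participant_id", as_index=False)[["x_m", "y_m"]].median()
    )
    return homes


def build_occupancy(
    diary: pd.DataFrame,
    gps_slots: pd.DataFrame,
    home_slots: pd.DataFrame,
) -> pd.DataFrame:
    """Join diary labels with slot-level outdoor concentrations.

    Returns one row per participant per 30-min slot on a complete lattice
    spanning each participant's diary days, with columns: microenv (gap
    slots forward-filled from the previous label), ``is_gap`` (original
    missingness), ``c_outdoor_gps`` and ``c_outdoor_home``. Slots with a
    label but no GPS coverage keep the label and a NaN concentration.
    """
    frames = []
    for pid, sub in diary.groupby("participant_id"):
        days = sub["slot_start"].dt.normalize().unique()
        lattice = pd.DatetimeIndex(
            np.concatenate(
                [
                    pd.date_range(d, periods=SLOTS_PER_DAY, freq=f"{SLOT_MINUTES}min").to_numpy()
                    for d in sorted(days)
                ]
            )
        )
        full = pd.DataFrame({"participant_id": pid, "slot_start": lattice})
        full = full.merge(sub, on=["participant_id", "slot_start"], how="left")
        full["is_gap"] = full["microenv"].isna()
        full["microenv"] = full["microenv"].ffill()
        frames.append(full)
    occ = pd.concat(frames, ignore_index=True)
    occ = occ.merge(gps_slots, on=["participant_id", "slot_start"], how="left")
    hs = home_slots.copy()
    if "slot_start" not in hs.columns:
        # hourly home-cell series: expand to the slot lattice by nearest time
        hs = hs.rename(columns={"timestamp": "grid_time"})
        times = pd.DatetimeIndex(hs["grid_time"])
        occ["grid_time"] = nearest_grid_time(times, occ["slot_start"] + pd.Timedelta(minutes=SLOT_MINUTES // 2))
        key = ["grid_time"]
        if "participant_id" in hs.columns:
            key = ["participant_id", "grid_time"]
        occ = occ.merge(hs, on=key, how="left").drop(columns=["grid_time"])
    else:
        occ = occ.merge(hs, on=["participant_id", "slot_start"], how="left")
    return occ


def day_hours_by_label(occ: pd.DataFrame) -> pd.DataFrame:
    """Hours per microenvironment per participant-day (gap-filled labels);
    labeled + gap hours always account for the full 24 h lattice."""
    df = occ.copy()
    df["date"] = df["slot_start"].dt.normalize()
    hours = (
        df.pivot_table(
            index=["participant_id", "date"],
            columns="microenv",
            values="slot_start",
            aggfunc="count",
        )
        .fillna(0)
        * (SLOT_MINUTES / 60.0)
    )
    hours["gap_h"] = (
        df.groupby(["participant_id", "date"])["is_gap"].sum() * (SLOT_MINUTES / 60.0)
    )
    return hours.reset_index()


def excluded_days(occ: pd.DataFrame, max_gap_h: float) -> pd.DataFrame:
    """Participant-days whose diary gaps exceed the threshold."""
    df = occ.copy()
    df["date"] = df["slot_start"].dt.normalize()
    gap_h = df.groupby(["participant_id", "date"])["is_gap"].sum() * (SLOT_MINUTES / 60.0)
    bad = gap_h[gap_h > max_gap_h].reset_index().rename(columns={"is_gap": "gap_h"})
    if len(bad):
        logger.info("excluding %d participant-day(s) with diary gaps > %.1f h", len(bad), max_gap_h)
    return bad
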