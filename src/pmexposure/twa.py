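"""Daily time-weighted-average (TWA) exposure under three scenarios.

The generic TWA of concentration/time pairs is

    C_TWA = sum_i C_i * T_i / sum_i T_i            [ug/m3]

Scenarios differ in which concentrations and times enter:

* S1 — measured home concentration and the home-cell outdoor
  concentration, weighted by fixed exposure-factors-handbook times
  (15.86 h indoors at home, 3.34 h outdoors).
* S2 — measured home concentration over diary home hours plus
  GPS-matched outdoor concentration over diary outdoor hours; exactly two
  terms, other labels' hours are excluded from the denominator.
* S3 — model-predicted indoor concentration for every occupied indoor
  label plus GPS-matched outdoor concentration, each weighted by diary
  hours.

All scenarios are computed slot-first: the generic TWA is applied once
per participant-day over 30-min slices, so the denominator is the day's
TAD-accounted hours (which may be below 24 h); no renormalization to 24 h
is applied.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import INDOOR_MICROENVS, MICROENVS, SLOT_MINUTES, StudyConfig

logger = logging.getLogger("pmexposure.twa")

SLOT_H = SLOT_MINUTES / 60.0


class UndefinedDayError(ValueError):
    """The day's weights sum to zero; the TWA is undefined."""


def twa(pairs) -> float:
    """Generic time-weighted average of (concentration, hours) pairs."""
    c = np.array([p[0] for p in pairs], dtype=float)
    t = np.array([p[1] for p in pairs], dtype=float)
    if np.any(t < 0):
        raise ValueError("occupancy times must be non-negative")
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    total = t.sum()
    if total <= 0:
        raise UndefinedDayError("total occupancy time is zero")
    return float((c * t).sum() / total)


def scenario_s1(home_measured: float, home_cell_outdoor: float, cfg: StudyConfig) -> float:
    """Fixed-time scenario from daily mean concentrations."""
    if not (np.isfinite(home_measured) and np.isfinite(home_cell_outdoor)):
        raise UndefinedDayError("S1 requires both daily mean concentrations")
    return twa(
        [(home_measured, cfg.s1_time_house_h), (home_cell_outdoor, cfg.s1_time_outdoor_h)]
    )


def _slot_pairs(day: pd.DataFrame, conc_col_by_label: dict[str, str]):
    """(concentration, SLOT_H) pairs for the slots whose label appears in
    the mapping; slots with a missing concentration are skipped and
    counted."""
    pairs, n_missing = [], 0
    for _, row in day.iterrows():
        col = conc_col_by_label.get(row["microenv"])
        if col is None:
            continue
        c = row[col]
        if pd.isna(c):
            n_missing += 1
            continue
        pairs.append((float(c), SLOT_H))
    return pairs, n_missing


def scenario_s2(day: pd.DataFrame, cfg: StudyConfig) -> float:
    """Two-term TAD scenario for one participant-day.

    ``day`` needs columns microenv, c_house (slot-mean home monitor) and
    c_outdoor_gps. Hours labeled office/educational/transportation/
    other_indoor are dropped from numerator and denominator (set
    ``cfg.s2_fold_indoor_into_house`` to fold them into the house term).
    """
    mapping = {"house": "c_house", "outdoor": "c_outdoor_gps"}
    if cfg.s2_fold_indoor_into_house:
        for m in INDOOR_MICROENVS:
            mapping[m] = "c_house"
    pairs, _ = _slot_pairs(day, mapping)
    if not pairs:
        raise UndefinedDayError("no house or outdoor TAD hours with data")
    return twa(pairs)


def scenario_s3(day: pd.DataFrame, cfg: StudyConfig) -> float:
    """All-microenvironment TAD scenario for one participant-day.

    ``day`` needs c_outdoor_gps plus a prediction column ``c_ind_<label>``
    for every occupied indoor label. A missing prediction for an occupied
    label excludes the day (raises), naming the label.
    """
    mapping = {"outdoor": "c_outdoor_gps"}
    for m in INDOOR_MICROENVS:
        mapping[m] = "c_outdoor_gps" if (m == "transportation" and cfg.transport_uses_gps) else f"c_ind_{m}"
    for m in day["microenv"].unique():
        col = mapping[m]
        if col not in day.columns or day.loc[day["microenv"] == m, col].isna().all():
            raise UndefinedDayError(f"no indoor prediction available for occupied label {m!r}")
    pairs, _ = _slot_pairs(day, mapping)
    if not pairs:
        raise UndefinedDayError("no TAD hours with data")
    return twa(pairs)


def measured_daily(personal: pd.DataFrame, cfg: StudyConfig) -> pd.DataFrame:
    """Daily mean of the personal monitor per participant-day.

    Days with fewer valid minutes than ``min_personal_coverage_h`` are
    excluded. Returns participant_id, date, measured, valid_h.
    """
    df = personal.dropna(subset=["pm25"]).copy()
    df["date"] = df["timestamp"].dt.normalize()
    g = df.groupby(["participant_id", "date"]).agg(
        measured=("pm25", "mean"), valid_minutes=("pm25", "size")
    )
    g["valid_h"] = g["valid_minutes"] / 60.0
    kept = g[g["valid_h"] >= cfg.min_personal_coverage_h].reset_index()
    n_drop = len(g) - len(kept)
    if n_drop:
        logger.info("measured_daily: excluded %d day(s) with < %.0f h coverage",
                    n_drop, cfg.min_personal_coverage_h)
    return kept[["participant_id", "date", "measured", "valid_h"]]


def compute_daily_exposure(
    occ: pd.DataFrame,
    home_slots: pd.DataFrame,
    personal: pd.DataFrame,
    cfg: StudyConfig,
) -> pd.DataFrame:
    """Assemble the per-participant-day exposure table.

    Parameters
    ----------
    occ
        Occupancy series with microenv, is_gap, c_outdoor_gps,
        c_outdoor_home and prediction columns ``c_ind_<label>``.
    home_slots
        participant_id, slot_start, c_house (slot-mean home monitor).
    personal
        Minute-level personal monitor series (ground truth).

    Days whose diary gaps exceed ``cfg.max_diary_gap_h`` get NaN for the
    TAD-based scenarios (S2, S3); S1 and the measured mean do not use the
    diary and are kept.
    """
    df = occ.merge(home_slots, on=["participant_id", "slot_start"], how="left")
    df["date"] = df["slot_start"].dt.normalize()
    meas = measured_daily(personal, cfg).set_index(["participant_id", "date"])

    rows = []
    for (pid, date), day in df.groupby(["participant_id", "date"]):
        gap_h = float(day["is_gap"].sum()) * SLOT_H
        rec: dict = {"participant_id": pid, "date": date, "gap_h": gap_h}
        for m in MICROENVS:
            rec[f"t_{m}"] = float((day["microenv"] == m).sum()) * SLOT_H

        c_house_daily = float(day["c_house"].mean()) if day["c_house"].notna().any() else np.nan
        c_out_home_daily = (
            float(day["c_outdoor_home"].mean()) if day["c_outdoor_home"].notna().any() else np.nan
        )
        rec["s1_c_house"], rec["s1_c_outdoor"] = c_house_daily, c_out_home_daily
        try:
            rec["s1"] = scenario_s1(c_house_daily, c_out_home_daily, cfg)
        except UndefinedDayError:
            rec["s1"] = np.nan

        tad_ok = gap_h <= cfg.max_diary_gap_h
        house_slots_ = day[day["microenv"] == "house"]
        out_slots = day[day["microenv"] == "outdoor"]
        rec["s2_c_house"] = float(house_slots_["c_house"].mean()) if len(house_slots_) else np.nan
        rec["s2_c_outdoor"] = (
            float(out_slots["c_outdoor_gps"].mean()) if len(out_slots) else np.nan
        )
        rec["s2_t_house"] = float(house_slots_["c_house"].notna().sum()) * SLOT_H
        rec["s2_t_outdoor"] = float(out_slots["c_outdoor_gps"].notna().sum()) * SLOT_H
        try:
            rec["s2"] = scenario_s2(day, cfg) if tad_ok else np.nan
        except UndefinedDayError:
            rec["s2"] = np.nan

        for m in INDOOR_MICROENVS:
            col = f"c_ind_{m}"
            sub = day[day["microenv"] == m]
            rec[f"s3_c_{m}"] = (
                float(sub[col].mean()) if col in day.columns and len(sub) and sub[col].notna().any() else np.nan
            )
        rec["s3_c_outdoor"] = rec["s2_c_outdoor"]
        try:
            rec["s3"] = scenario_s3(day, cfg) if tad_ok else np.nan
        except UndefinedDayError as e:
            logger.info("S3 excluded for %s %s: %s", pid, date.date(), e)
            rec["s3"] = np.nan

        key = (pid, date)
        rec["measured"] = float(meas.loc[key, "measured"]) if key in meas.index else np.nan
        rows.append(rec)
    return pd.DataFrame(rows)
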