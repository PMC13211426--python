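"""CSV readers/writers with strict schema validation.

Every reader returns a :class:`ValidatedTable`: the cleaned ``pandas``
DataFrame plus a rejection log in which each discarded input row appears
exactly once with the reason it violated an invariant. Structural problems
(missing columns, unknown diary labels, conflicting duplicate diary slots)
raise :class:`SchemaError` instead of being row-filtered, because they
indicate a malformed file rather than a bad record.

Expected headers
----------------
sensor   : station_id,x_m,y_m,timestamp,pm25,pm10
diary    : participant_id,slot_start,microenv
track    : participant_id,timestamp,x_m,y_m
met      : timestamp,temp_c,wind_ms,rh_pct,precip_mm
series   : participant_id,timestamp,pm25   (home monitor / personal monitor)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import MICROENVS, SLOT_MINUTES

logger = logging.getLogger("pmexposure.io")

TIMESTAMP_FORMAT = "%Y-%m-%d %H:%M:%S"

SCHEMAS = {
    "sensor": ["station_id", "x_m", "y_m", "timestamp", "pm25", "pm10"],
    "diary": ["participant_id", "slot_start", "microenv"],
    "track": ["participant_id", "timestamp", "x_m", "y_m"],
    "met": ["timestamp", "temp_c", "wind_ms", "rh_pct", "precip_mm"],
    "series": ["participant_id", "timestamp", "pm25"],
}


class SchemaError(ValueError):
    """The file's structure (not an individual row) violates the schema."""


@dataclass
class ValidatedTable:
    """A validated table plus the log of rejected rows."""

    df: pd.DataFrame
    rejections: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["row", "reason"])
    )
    #: reader-specific warnings, e.g. flagged cadence gaps in GPS tracks
    flags: list = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)


def _require_columns(df: pd.DataFrame, kind: str) -> None:
    missing = [c for c in SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise SchemaError(f"{kind} file is missing column(s): {', '.join(missing)}")


def _parse_timestamps(df: pd.DataFrame, col: str) -> tuple[pd.Series, pd.Series]:
    """Parse a timestamp column; return (parsed, bad_mask)."""
    parsed = pd.to_datetime(df[col], errors="coerce")
    return parsed, parsed.isna() & df[col].notna() | df[col].isna()


def _finish(df: pd.DataFrame, reject: dict[int, str], kind: str) -> ValidatedTable:
    rej = pd.DataFrame(
        {"row": list(reject.keys()), "reason": list(reject.values())}
    ).sort_values("row", ignore_index=True)
    kept = df.drop(index=list(reject.keys())).reset_index(drop=True)
    if len(rej):
        logger.warning("%s: rejected %d row(s)", kind, len(rej))
    return ValidatedTable(df=kept, rejections=rej)


def _mark(reject: dict[int, str], mask: pd.Series, reason: str) -> None:
    # first violation wins so each row is logged exactly once
    for idx in mask[mask].index:
        reject.setdefault(int(idx), reason)


def read_sensor_table(path) -> ValidatedTable:
    """Read a sensor-network observation table.

    Row invariants: finite coordinates, non-negative concentrations,
    pm25 <= pm10 where both are present, and strictly increasing
    timestamps within each station (later duplicates/regressions are
    rejected, keeping the first occurrence).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, "sensor")
    reject: dict[int, str] = {}
    ts, bad_ts = _parse_timestamps(df, "timestamp")
    _mark(reject, bad_ts, "unparseable timestamp")
    for c in ("x_m", "y_m"):
        _mark(reject, ~np.isfinite(pd.to_numeric(df[c], errors="coerce")), f"non-finite {c}")
    pm25 = pd.to_numeric(df["pm25"], errors="coerce")
    pm10 = pd.to_numeric(df["pm10"], errors="coerce")
    _mark(reject, pm25 < 0, "negative pm25")
    _mark(reject, pm10 < 0, "negative pm10")
    _mark(reject, (pm25 > pm10) & pm25.notna() & pm10.notna(), "pm25 exceeds pm10")
    df = df.assign(timestamp=ts, pm25=pm25, pm10=pm10)
    # monotonicity within station, evaluated on rows not already rejected
    ok = ~df.index.isin(list(reject))
    sub = df[ok].sort_index()
    non_increasing = sub.groupby("station_id")["timestamp"].diff() <= pd.Timedelta(0)
    _mark(reject, non_increasing, "timestamp not strictly increasing within station")
    return _finish(df, reject, "sensor")


def read_diary(path) -> ValidatedTable:
    """Read a time-activity diary on the 30-min slot lattice.

    Unknown microenvironment labels and conflicting duplicate
    (participant, slot) entries raise :class:`SchemaError`. Off-lattice
    slot times are rejected row-wise. Missing slots are *not* filled here;
    downstream modules decide how to treat gaps.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, "diary")
    unknown = sorted(set(df["microenv"].dropna()) - set(MICROENVS))
    if unknown:
        raise SchemaError(
            f"unknown microenvironment label(s): {', '.join(map(str, unknown))}; "
            f"expected one of {', '.join(MICROENVS)}"
        )
    reject: dict[int, str] = {}
    ts, bad_ts = _parse_timestamps(df, "slot_start")
    _mark(reject, bad_ts, "unparseable slot_start")
    off = (ts.dt.minute % SLOT_MINUTES != 0) | (ts.dt.second != 0)
    _mark(reject, off & ~bad_ts, "slot_start not on the 30-min lattice")
    _mark(reject, df["microenv"].isna(), "missing microenv")
    df = df.assign(slot_start=ts)
    ok = df.drop(index=list(reject))
    dup = ok.duplicated(["participant_id", "slot_start"], keep=False)
    if dup.any():
        conflicting = (
            ok[dup].groupby(["participant_id", "slot_start"])["microenv"].nunique() > 1
        )
        if conflicting.any():
            key = conflicting[conflicting].index[0]
            raise SchemaError(
                f"conflicting duplicate diary entries for participant "
                f"{key[0]} at {key[1]}"
            )
        # identical duplicates: keep first, log the rest
        extra = ok.duplicated(["participant_id", "slot_start"], keep="first")
        _mark(reject, extra, "duplicate (participant, slot) entry")
    return _finish(df, reject, "diary")


def read_track(path, cadence_min: int = 1) -> ValidatedTable:
    """Read GPS tracks; cadence gaps are flagged, never filled."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, "track")
    reject: dict[int, str] = {}
    ts, bad_ts = _parse_timestamps(df, "timestamp")
    _mark(reject, bad_ts, "unparseable timestamp")
    for c in ("x_m", "y_m"):
        _mark(reject, ~np.isfinite(pd.to_numeric(df[c], errors="coerce")), f"non-finite {c}")
    df = df.assign(timestamp=ts)
    out = _finish(df, reject, "track")
    gaps = (
        out.df.sort_values(["participant_id", "timestamp"])
        .groupby("participant_id")["timestamp"]
        .diff()
    )
    n_gaps = int((gaps > pd.Timedelta(minutes=cadence_min)).sum())
    if n_gaps:
        out.flags.append(f"{n_gaps} cadence gap(s) exceeding {cadence_min} min")
        logger.warning("track: %s", out.flags[-1])
    return out


def read_met(path) -> ValidatedTable:
    """Read the meteorology series (hourly)."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, "met")
    reject: dict[int, str] = {}
    ts, bad_ts = _parse_timestamps(df, "timestamp")
    _mark(reject, bad_ts, "unparseable timestamp")
    rh = pd.to_numeric(df["rh_pct"], errors="coerce")
    _mark(reject, (rh < 0) | (rh > 100), "relative humidity outside [0, 100]")
    _mark(reject, pd.to_numeric(df["precip_mm"], errors="coerce") < 0, "negative precipitation")
    return _finish(df.assign(timestamp=ts), reject, "met")


def read_series(path) -> ValidatedTable:
    """Read a concentration series (home or personal monitor)."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, "series")
    reject: dict[int, str] = {}
    ts, bad_ts = _parse_timestamps(df, "timestamp")
    _mark(reject, bad_ts, "unparseable timestamp")
    pm25 = pd.to_numeric(df["pm25"], errors="coerce")
    _mark(reject, pm25 < 0, "negative pm25")
    _mark(reject, pm25.isna(), "missing pm25")
    return _finish(df.assign(timestamp=ts, pm25=pm25), reject, "series")


READERS = {
    "sensor": read_sensor_table,
    "diary": read_diary,
    "track": read_track,
    "met": read_met,
    "series": read_series,
}


def write_table(df: pd.DataFrame, path) -> None:
    """Write a table with the canonical timestamp format so that a
    write→read round trip is value-identical and repeated writes are
    byte-identical."""
    out = df.copy()
    for c in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[c]):
            out[c] = out[c].dt.strftime(TIMESTAMP_FORMAT)
    # shortest-roundtrip float formatting: values survive write->read exactly
    out.to_csv(path, index=False, float_format=lambda v: repr(float(v)))
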