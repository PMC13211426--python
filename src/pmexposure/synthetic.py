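"""Synthetic study generator.

Emulates a winter urban panel study of personal PM2.5 exposure: a
low-cost outdoor sensor network, a fixed indoor monitor in each home, GPS
tracks at 1-min cadence, 30-min time-activity diaries, hourly meteorology
and a personal (breathing-zone) monitor that serves as ground truth.

The generator is built so that the qualitative biases reported for such
panels emerge by construction:

* an urban-core concentration excess, so that GPS-matched outdoor
  concentrations during activity exceed the outdoor concentration at the
  (suburban) home grid cell;
* episodic indoor source events at home (cooking-like spikes with
  exponential decay), so that the measured home series exceeds any
  infiltration-only indoor model prediction;
* occupancy dominated by indoor microenvironments (~12 h/day at home,
  ~1.5 h/day outdoors).

The stationary home monitor sits next to the episodic sources and records
peaks at full strength; the occupant's breathing zone receives a damped
version (``peak_personal_attenuation``) and only while at home. Setting
the attenuation to 1 makes personal truth identical to the occupied
microenvironment's concentration everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.interpolate import RegularGridInterpolator
from scipy.linalg import cholesky

from .config import MICROENVS

MIN_PER_DAY = 24 * 60


class SimScenario(BaseModel):
    """Parameters of one synthetic study.

    Defaults are the small desk-scale preset used throughout the test
    suite; ``PRESETS['study']`` mirrors the full panel scale (93
    participants, 60 days, ~200 sensors).
    """

    n_participants: int = Field(5, ge=1)
    n_days: int = Field(7, ge=1)
    n_sensors: int = Field(50, ge=1)
    domain_extent_m: tuple[float, float] = (10_000.0, 10_000.0)
    start_date: str = "2023-01-02"  # a Monday

    # outdoor field: spherical spatial GRF + diurnal cycle + temporal AR(1)
    mean_ugm3: float = 15.0
    spatial_range_m: float = 2000.0
    spatial_sill: float = 25.0
    spatial_nugget: float = 0.0
    diurnal_amplitude: float = 3.0
    day_effect_sd: float = 10.0
    day_effect_rho: float = 0.5
    hour_effect_sd: float = 2.0
    hour_effect_rho: float = 0.8
    #: concentration excess at the urban core (Gaussian bump, scale 2 km)
    urban_excess: float = 7.0

    #: infiltration line (slope, intercept ug/m3) per indoor microenvironment
    infiltration: dict[str, tuple[float, float]] = {
        "house": (0.6, 5.0),
        "office": (0.4, 4.0),
        "educational_facility": (0.4, 4.0),
        "transportation": (0.4, 4.0),
        "other_indoor": (0.4, 4.0),
    }

    # episodic indoor sources at home: minute-scale transients (cooking-like),
    # ~20 min e-folding, magnitudes of a few hundred ug/m3
    peak_events_per_day: float = Field(3.0, ge=0)
    peak_magnitude_ugm3: float = Field(290.0, ge=0)  # mean of exponential draw
    peak_decay_per_h: float = Field(3.0, gt=0)
    #: fraction of the monitor-recorded peak reaching the breathing zone
    peak_personal_attenuation: float = Field(0.3, ge=0, le=1)

    sensor_noise_sd: float = Field(2.0, ge=0)
    monitor_noise_sd: float = Field(1.0, ge=0)
    sensor_cadence_min: int = Field(10, ge=1)
    track_cadence_min: int = Field(1, ge=1)
    #: training sites per microenvironment for the indoor-model table
    n_train_sites: int = Field(8, ge=1)
    #: knot spacing of the latent spatial lattice
    knot_spacing_m: float = Field(400.0, gt=0)
    rng_seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimScenario":
        if self.spatial_sill < self.spatial_nugget:
            raise ValueError("sill must be >= nugget")
        if self.spatial_nugget < 0:
            raise ValueError("nugget must be >= 0")
        return self


PRESETS: dict[str, dict] = {
    "small": {},
    "study": {
        "n_participants": 93,
        "n_days": 60,
        "n_sensors": 200,
        "sensor_cadence_min": 1,
    },
}


def scenario_from_preset(name: str, seed: int = 0) -> SimScenario:
    try:
        kwargs = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    return SimScenario(rng_seed=seed, **kwargs)


class OutdoorField:
    """Deterministic continuous sampler (x_m, y_m, minutes-since-start) ->
    ug/m3, built once from a scenario and a seed.

    Composition: spatial Gaussian random field with spherical covariance
    (drawn on a knot lattice, bilinearly interpolated) + AR(1) day and hour
    effects + sinusoidal diurnal cycle + an urban-core excess bump; clipped
    at zero.
    """

    def __init__(self, scn: SimScenario, rng: np.random.Generator):
        self.scn = scn
        w, h = scn.domain_extent_m
        self.center = np.array([w / 2.0, h / 2.0])
        s = scn.knot_spacing_m
        kx = np.arange(0.0, w + s, s)
        ky = np.arange(0.0, h + s, s)
        KX, KY = np.meshgrid(kx, ky, indexing="ij")
        pts = np.column_stack([KX.ravel(), KY.ravel()])
        psill = scn.spatial_sill - scn.spatial_nugget
        if psill > 0:
            d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
            hr = np.clip(d / scn.spatial_range_m, 0.0, 1.0)
            cov = psill * (1.0 - 1.5 * hr + 0.5 * hr**3)
            cov[d >= scn.spatial_range_m] = 0.0
            cov[np.diag_indices_from(cov)] = psill + 1e-8 * max(psill, 1.0)
            z = cholesky(cov, lower=True) @ rng.standard_normal(len(pts))
        else:
            z = np.zeros(len(pts))
        self._interp = RegularGridInterpolator(
            (kx, ky), z.reshape(len(kx), len(ky)), method="linear",
            bounds_error=False, fill_value=None,
        )
        # temporal processes over the study horizon
        n_hours = scn.n_days * 24
        self._day = _ar1(rng, scn.n_days, scn.day_effect_rho, scn.day_effect_sd)
        self._hour = _ar1(rng, n_hours, scn.hour_effect_rho, scn.hour_effect_sd)

    def ratio_pm25_pm10(self, t_min):
        """Deterministic diurnal PM2.5/PM10 ratio in (0, 1]."""
        t_h = np.asarray(t_min, dtype=float) / 60.0
        return 0.6 + 0.08 * np.sin(2 * np.pi * (t_h - 3.0) / 24.0)

    def __call__(self, x, y, t_min):
        scn = self.scn
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        t_h = np.asarray(t_min, dtype=float) / 60.0
        day = np.clip((t_h // 24).astype(int), 0, scn.n_days - 1)
        hour = np.clip(t_h.astype(int), 0, scn.n_days * 24 - 1)
        spatial = self._interp(np.column_stack([np.ravel(x), np.ravel(y)])).reshape(x.shape)
        diurnal = scn.diurnal_amplitude * np.sin(2 * np.pi * (t_h % 24 - 3.0) / 24.0)
        r2 = ((x - self.center[0]) ** 2 + (y - self.center[1]) ** 2) / 2000.0**2
        excess = scn.urban_excess * np.exp(-r2)
        out = scn.mean_ugm3 + spatial + self._day[day] + self._hour[hour] + diurnal + excess
        return np.clip(out, 0.0, None)


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) path with marginal standard deviation sd."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    e = rng.standard_normal(n)
    out = np.empty(n)
    out[0] = e[0]
    for i in range(1, n):
        out[i] = rho * out[i - 1] + np.sqrt(1 - rho**2) * e[i]
    return sd * out


def simulate_outdoor_field(scn: SimScenario, rng: np.random.Generator | None = None) -> OutdoorField:
    if rng is None:
        rng = np.random.default_rng(scn.rng_seed)
    return OutdoorField(scn, rng)


# ---------------------------------------------------------------------------
# participants: diaries, tracks, monitors, personal truth


#: weekday template as (n_slots, label) runs; 48 slots = 24 h
_WEEKDAY = [
    (14, "house"), (1, "transportation"), (8, "office"), (1, "outdoor"),
    (5, "office"), (2, "educational_facility"), (2, "other_indoor"),
    (1, "outdoor"), (1, "transportation"), (2, "other_indoor"),
    (1, "outdoor"), (10, "house"),
]
_WEEKEND = [
    (18, "house"), (1, "transportation"), (4, "other_indoor"),
    (5, "outdoor"), (1, "transportation"), (19, "house"),
]


def _day_labels(rng: np.random.Generator, weekend: bool) -> np.ndarray:
    template = _WEEKEND if weekend else _WEEKDAY
    labels: list[str] = []
    for n, lab in template:
        labels.extend([lab] * n)
    labels_arr = np.array(labels)
    # jitter: rotate the whole day by -1/0/+1 slot (shifted wake-up)
    shift = rng.integers(-1, 2)
    return np.roll(labels_arr, shift)


@dataclass
class SimulatedStudy:
    """All generated tables, plus generator internals useful in tests."""

    scenario: SimScenario
    sensors: pd.DataFrame
    home_monitor: pd.DataFrame
    tracks: pd.DataFrame
    diary: pd.DataFrame
    met: pd.DataFrame
    personal: pd.DataFrame
    microenv_training: pd.DataFrame
    homes: pd.DataFrame  # participant_id, x_m, y_m (true home locations)
    field: OutdoorField

    def write(self, outdir) -> None:
        from pathlib import Path

        from .io import write_table

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_table(self.sensors, outdir / "sensors.csv")
        write_table(self.home_monitor, outdir / "home_monitor.csv")
        write_table(self.tracks, outdir / "tracks.csv")
        write_table(self.diary, outdir / "diary.csv")
        write_table(self.met, outdir / "met.csv")
        write_table(self.personal, outdir / "personal.csv")
        write_table(self.microenv_training, outdir / "microenv_training.csv")


def _peak_series(
    rng: np.random.Generator, n_min: int, rate_per_day: float,
    magnitude: float, decay_per_h: float,
) -> np.ndarray:
    """Minute-resolution contribution of exponentially decaying source
    events with Poisson daily counts and exponential magnitudes."""
    out = np.zeros(n_min)
    if rate_per_day == 0 or magnitude == 0:
        return out
    n_days = n_min // MIN_PER_DAY
    lam_min = decay_per_h / 60.0
    for d in range(n_days):
        for _ in range(rng.poisson(rate_per_day)):
            t0 = d * MIN_PER_DAY + int(rng.integers(0, MIN_PER_DAY))
            m = rng.exponential(magnitude)
            span = min(n_min - t0, int(np.log(max(m, 1e-9) / 0.05) / lam_min) + 1)
            if span > 0:
                out[t0 : t0 + span] += m * np.exp(-lam_min * np.arange(span))
    return out


def simulate_met(scn: SimScenario, rng: np.random.Generator) -> pd.DataFrame:
    n_hours = scn.n_days * 24
    t = pd.date_range(scn.start_date, periods=n_hours, freq="h")
    hod = np.arange(n_hours) % 24
    temp = 2.0 + 6.0 * np.sin(2 * np.pi * (hod - 14) / 24) + _ar1(rng, n_hours, 0.9, 3.0)
    wind = np.clip(2.0 + _ar1(rng, n_hours, 0.8, 1.0), 0.1, None)
    rh = np.clip(60.0 - 1.5 * (temp - 2.0) + _ar1(rng, n_hours, 0.8, 8.0), 15.0, 98.0)
    precip = np.where(rng.random(n_hours) < 0.04, rng.exponential(1.0, n_hours), 0.0)
    return pd.DataFrame(
        {"timestamp": t, "temp_c": temp, "wind_ms": wind, "rh_pct": rh, "precip_mm": precip}
    )


def simulate_sensors(scn: SimScenario, field: OutdoorField, rng: np.random.Generator) -> pd.DataFrame:
    w, h = scn.domain_extent_m
    sx = rng.uniform(0, w, scn.n_sensors)
    sy = rng.uniform(0, h, scn.n_sensors)
    t_min = np.arange(0, scn.n_days * MIN_PER_DAY, scn.sensor_cadence_min)
    times = pd.Timestamp(scn.start_date) + pd.to_timedelta(t_min, unit="m")
    frames = []
    for i in range(scn.n_sensors):
        pm25 = field(np.full(t_min.shape, sx[i]), np.full(t_min.shape, sy[i]), t_min)
        pm25 = np.clip(pm25 + rng.normal(0, scn.sensor_noise_sd, len(t_min)), 0, None)
        pm10 = pm25 / field.ratio_pm25_pm10(t_min)
        pm10 = np.maximum(pm10 + rng.normal(0, scn.sensor_noise_sd, len(t_min)), pm25)
        frames.append(
            pd.DataFrame(
                {
                    "station_id": f"S{i:04d}",
                    "x_m": sx[i],
                    "y_m": sy[i],
                    "timestamp": times,
                    "pm25": pm25,
                    "pm10": pm10,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_participants(scn: SimScenario, field: OutdoorField, rng: np.random.Generator):
    """Diaries, tracks, home monitors and breathing-zone truth.

    Returns (diary, tracks, home_monitor, personal, homes) DataFrames.
    """
    start = pd.Timestamp(scn.start_date)
    n_min = scn.n_days * MIN_PER_DAY
    t_all = np.arange(n_min)
    w, h = scn.domain_extent_m
    center = np.array([w / 2, h / 2])

    diaries, tracks, homes_rows, home_rows, personal_rows = [], [], [], [], []
    a = {k: v[0] for k, v in scn.infiltration.items()}
    b = {k: v[1] for k, v in scn.infiltration.items()}

    for p in range(scn.n_participants):
        pid = f"P{p:03d}"
        # suburban home, urban-core workplace
        ang, r = rng.uniform(0, 2 * np.pi), rng.uniform(3000, 4500)
        home = center + r * np.array([np.cos(ang), np.sin(ang)])
        home = np.clip(home, 100, [w - 100, h - 100])
        ang2, r2 = rng.uniform(0, 2 * np.pi), rng.uniform(0, 800)
        work = center + r2 * np.array([np.cos(ang2), np.sin(ang2)])
        homes_rows.append({"participant_id": pid, "x_m": home[0], "y_m": home[1]})

        # diary: per-day label sequence on the 30-min lattice
        labels = np.concatenate(
            [
                _day_labels(rng, weekend=(start + pd.Timedelta(days=d)).dayofweek >= 5)
                for d in range(scn.n_days)
            ]
        )
        slot_starts = start + pd.to_timedelta(np.arange(len(labels)) * 30, unit="m")
        diaries.append(
            pd.DataFrame({"participant_id": pid, "slot_start": slot_starts, "microenv": labels})
        )

        # minute-resolution positions consistent with the diary
        lab_min = np.repeat(labels, 30)[:n_min]
        x = np.empty(n_min)
        y = np.empty(n_min)
        at_home_anchor = np.isin(lab_min, ["house"])
        # anchor: home before first transit of the day and after last; work side otherwise
        x[:], y[:] = home
        away = np.isin(lab_min, ["office", "educational_facility"])
        x[away], y[away] = work
        # other_indoor/outdoor: in the urban core (commercial districts) for
        # daytime and evening activities, near home late at night
        flex = np.isin(lab_min, ["other_indoor", "outdoor"])
        hod = (t_all % MIN_PER_DAY) / 60.0
        near_work = flex & (hod >= 8) & (hod < 20)
        near_home = flex & ~near_work
        x[near_work], y[near_work] = work[0], work[1]
        x[near_home], y[near_home] = home[0], home[1]
        # transportation: linear home<->work within each transit run
        trans = lab_min == "transportation"
        if trans.any():
            runs = np.flatnonzero(np.diff(np.r_[0, trans.view(np.int8), 0]) == 1)
            ends = np.flatnonzero(np.diff(np.r_[0, trans.view(np.int8), 0]) == -1)
            for s_, e_ in zip(runs, ends):
                frac = np.linspace(0, 1, e_ - s_)
                origin = home if (s_ % MIN_PER_DAY) < 12 * 60 else work
                dest = work if origin is home else home
                x[s_:e_] = origin[0] + frac * (dest[0] - origin[0])
                y[s_:e_] = origin[1] + frac * (dest[1] - origin[1])
        # small GPS wander
        x = x + rng.normal(0, 20, n_min)
        y = y + rng.normal(0, 20, n_min)
        step = scn.track_cadence_min
        tracks.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "timestamp": start + pd.to_timedelta(t_all[::step], unit="m"),
                    "x_m": x[::step],
                    "y_m": y[::step],
                }
            )
        )

        # home monitor: infiltration baseline + full-strength peaks
        out_home = field(np.full(n_min, home[0]), np.full(n_min, home[1]), t_all)
        peaks = _peak_series(
            rng, n_min, scn.peak_events_per_day, scn.peak_magnitude_ugm3, scn.peak_decay_per_h
        )
        base_house = a["house"] * out_home + b["house"]
        monitor = np.clip(
            base_house + peaks + rng.normal(0, scn.monitor_noise_sd, n_min), 0, None
        )
        cad = scn.sensor_cadence_min
        home_rows.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "timestamp": start + pd.to_timedelta(t_all[::cad], unit="m"),
                    "pm25": monitor[::cad],
                }
            )
        )

        # breathing-zone truth: occupied microenvironment's concentration;
        # at home the episodic-peak component is attenuated (monitor sits
        # next to the sources)
        out_here = field(x, y, t_all)
        truth = np.empty(n_min)
        truth[at_home_anchor] = (
            base_house + scn.peak_personal_attenuation * peaks
        )[at_home_anchor]
        outdoor_m = lab_min == "outdoor"
        truth[outdoor_m] = out_here[outdoor_m]
        for lab in ("office", "educational_facility", "transportation", "other_indoor"):
            m = lab_min == lab
            truth[m] = a[lab] * out_here[m] + b[lab]
        truth = np.clip(truth + rng.normal(0, scn.monitor_noise_sd, n_min), 0, None)
        personal_rows.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "timestamp": start + pd.to_timedelta(t_all, unit="m"),
                    "pm25": truth,
                }
            )
        )

    return (
        pd.concat(diaries, ignore_index=True),
        pd.concat(tracks, ignore_index=True),
        pd.concat(home_rows, ignore_index=True),
        pd.concat(personal_rows, ignore_index=True),
        pd.DataFrame(homes_rows),
    )


def simulate_training_table(
    scn: SimScenario, field: OutdoorField, met: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Hourly model-development table per indoor microenvironment.

    Emulates the measurement campaign behind the indoor prediction models:
    several instrumented sites per label, hourly indoor concentration plus
    the six outdoor/meteorological features. House sites include the
    episodic source process at full monitor strength.
    """
    n_min = scn.n_days * MIN_PER_DAY
    n_hours = scn.n_days * 24
    t_hour_min = np.arange(n_hours) * 60.0
    w, h = scn.domain_extent_m
    frames = []
    for lab, (a, b) in scn.infiltration.items():
        for s in range(scn.n_train_sites):
            sx, sy = rng.uniform(0, w), rng.uniform(0, h)
            out_h = field(np.full(n_hours, sx), np.full(n_hours, sy), t_hour_min)
            target = a * out_h + b
            if lab == "house":
                pk = _peak_series(
                    rng, n_min, scn.peak_events_per_day, scn.peak_magnitude_ugm3,
                    scn.peak_decay_per_h,
                )
                target = target + pk.reshape(n_hours, 60).mean(axis=1)
            target = np.clip(target + rng.normal(0, scn.monitor_noise_sd, n_hours), 0, None)
            frames.append(
                pd.DataFrame(
                    {
                        "microenv": lab,
                        "site": f"{lab}_{s}",
                        "timestamp": met["timestamp"].to_numpy(),
                        "outdoor_pm25": out_h,
                        "ratio_pm25_pm10": field.ratio_pm25_pm10(t_hour_min),
                        "temp_c": met["temp_c"].to_numpy(),
                        "wind_ms": met["wind_ms"].to_numpy(),
                        "rh_pct": met["rh_pct"].to_numpy(),
                        "precip_mm": met["precip_mm"].to_numpy(),
                        "indoor_pm25": target,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def simulate_study(scn: SimScenario | None = None, seed: int | None = None) -> SimulatedStudy:
    """Generate a complete synthetic study. Fixed seed => identical output."""
    if scn is None:
        scn = SimScenario()
    if seed is not None:
        scn = scn.model_copy(update={"rng_seed": seed})
    rng = np.random.default_rng(scn.rng_seed)
    field = simulate_outdoor_field(scn, rng)
    met = simulate_met(scn, rng)
    sensors = simulate_sensors(scn, field, rng)
    diary, tracks, home_monitor, personal, homes = simulate_participants(scn, field, rng)
    training = simulate_training_table(scn, field, met, rng)
    return SimulatedStudy(
        scenario=scn,
        sensors=sensors,
        home_monitor=home_monitor,
        tracks=tracks,
        diary=diary,
        met=met,
        personal=personal,
        microenv_training=training,
        homes=homes,
        field=field,
    )
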