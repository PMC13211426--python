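"""Ordinary kriging of sensor-network observations onto a regular grid.

The workflow mirrors how hourly pollutant surfaces are produced from a
dense low-cost sensor network: sub-hourly readings are averaged to hourly
station means, an isotropic spherical semivariogram is fitted to each
hour's empirical (Matheron) variogram by weighted least squares, and the
ordinary-kriging (OK) system — weights constrained to sum to one via a
Lagrange multiplier — is solved for every cell center of a regular grid
(500 m by default). Negative predictions are clipped to zero and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, nnls
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist, pdist, squareform

logger = logging.getLogger("pmexposure.kriging")

MIN_STATIONS_VARIOGRAM = 10
MIN_STATIONS_KRIGE = 3


class KrigingError(ValueError):
    pass


class OutOfDomainError(KrigingError):
    pass


@dataclass(frozen=True)
class VariogramModel:
    """Spherical semivariogram: nugget, total sill and range in meters."""

    nugget: float
    sill: float
    range_m: float
    model_form: str = "spherical"

    def __post_init__(self):
        if not (0 <= self.nugget <= self.sill):
            raise ValueError("need 0 <= nugget <= sill")
        if self.range_m <= 0:
            raise ValueError("range_m must be positive")

    def __call__(self, h: np.ndarray) -> np.ndarray:
        """Semivariance at separation distance(s) h (meters)."""
        h = np.asarray(h, dtype=float)
        psill = self.sill - self.nugget
        hr = np.clip(h / self.range_m, 0.0, 1.0)
        gamma = self.nugget + psill * (1.5 * hr - 0.5 * hr**3)
        return np.where(h > 0, gamma, 0.0)


@dataclass(frozen=True)
class GridGeometry:
    """Regular grid; cell (col, row) covers the half-open square
    [x0 + col*s, x0 + (col+1)*s) x [y0 + row*s, y0 + (row+1)*s)."""

    x0: float
    y0: float
    cell_size_m: float
    n_cols: int
    n_rows: int

    @classmethod
    def from_points(cls, x, y, cell_size_m: float, pad_cells: int = 1) -> "GridGeometry":
        """Smallest grid covering the points, snapped to cell_size multiples."""
        s = cell_size_m
        x0 = np.floor(np.min(x) / s) * s - pad_cells * s
        y0 = np.floor(np.min(y) / s) * s - pad_cells * s
        n_cols = int(np.ceil((np.max(x) - x0) / s)) + pad_cells
        n_rows = int(np.ceil((np.max(y) - y0) / s)) + pad_cells
        return cls(x0, y0, s, n_cols, n_rows)

    def locate(self, x, y):
        """Cell indices (col, row) of point(s); lower-left edge inclusive."""
        col = np.floor((np.asarray(x) - self.x0) / self.cell_size_m).astype(int)
        row = np.floor((np.asarray(y) - self.y0) / self.cell_size_m).astype(int)
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        if np.any(bad):
            raise OutOfDomainError("point outside grid extent")
        return col, row

    def clip_locate(self, x, y):
        """Like :meth:`locate` but snapping outside points to the nearest
        boundary cell; returns (col, row, n_clipped)."""
        col = np.floor((np.asarray(x) - self.x0) / self.cell_size_m).astype(int)
        row = np.floor((np.asarray(y) - self.y0) / self.cell_size_m).astype(int)
        n_out = int(np.sum((col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)))
        return (
            np.clip(col, 0, self.n_cols - 1),
            np.clip(row, 0, self.n_rows - 1),
            n_out,
        )

    def cell_centers(self):
        """Arrays (X, Y), each shaped (n_rows, n_cols)."""
        xs = self.x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size_m
        ys = self.y0 + (np.arange(self.n_rows) + 0.5) * self.cell_size_m
        return np.meshgrid(xs, ys)


@dataclass
class GridField:
    """One time step of a kriged concentration surface."""

    geom: GridGeometry
    timestamp: pd.Timestamp
    values: np.ndarray  # shape (n_rows, n_cols), ug/m3, >= 0

    diagnostics: dict = field(default_factory=dict)

    def lookup(self, x, y):
        col, row = self.geom.locate(x, y)
        return self.values[row, col]

    def to_long_frame(self, value_name: str = "pm25") -> pd.DataFrame:
        X, Y = self.geom.cell_centers()
        rows, cols = np.meshgrid(
            np.arange(self.geom.n_rows), np.arange(self.geom.n_cols), indexing="ij"
        )
        return pd.DataFrame(
            {
                "timestamp": self.timestamp,
                "col": cols.ravel(),
                "row": rows.ravel(),
                "x_center": X.ravel(),
                "y_center": Y.ravel(),
                value_name: self.values.ravel(),
            }
        )


def lookup_cell(grid: GridField, x_m: float, y_m: float):
    """Cell index and value at a point (half-open membership, lower-left
    inclusive); raises :class:`OutOfDomainError` outside the extent."""
    col, row = grid.geom.locate(x_m, y_m)
    return (int(col), int(row)), float(grid.values[row, col])


def empirical_variogram(x, y, z, n_bins: int = 12):
    """Matheron estimator on equal-width distance bins.

    Returns (bin centers, semivariances, pair counts); empty bins dropped.
    """
    pts = np.column_stack([x, y])
    d = pdist(pts)
    gamma_pairs = 0.5 * pdist(np.asarray(z, dtype=float)[:, None], "sqeuclidean")
    max_d = d.max() / 2.0  # classical cutoff: half the maximum separation
    edges = np.linspace(0, max_d, n_bins + 1)
    idx = np.digitize(d, edges) - 1
    centers, gammas, counts = [], [], []
    for b in range(n_bins):
        m = idx == b
        if m.sum() == 0:
            continue
        centers.append(d[m].mean())
        gammas.append(gamma_pairs[m].mean())
        counts.append(int(m.sum()))
    return np.array(centers), np.array(gammas), np.array(counts)


def fit_variogram(x, y, z, n_bins: int = 12) -> VariogramModel:
    """Fit a spherical model to the empirical variogram by weighted least
    squares (weights = bin pair counts).

    Requires at least 10 stations; with fewer, raises :class:`KrigingError`
    advising the caller to widen the time window.
    """
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    ok = np.isfinite(z)
    x, y, z = x[ok], y[ok], z[ok]
    if len(z) < MIN_STATIONS_VARIOGRAM:
        raise KrigingError(
            f"variogram fitting needs >= {MIN_STATIONS_VARIOGRAM} stations with "
            f"finite values (got {len(z)}); widen the averaging time window"
        )
    h, gamma, counts = empirical_variogram(x, y, z, n_bins=n_bins)
    var = float(np.var(z))
    if var < 1e-12 or np.all(gamma < 1e-12):
        # flat variogram: a constant field
        return VariogramModel(nugget=0.0, sill=1e-12, range_m=max(h.max(), 1.0))
    # short lags carry the information kriging uses; weight bins by
    # pair count over squared distance (gstat-style N_j / h_j^2)
    w = np.sqrt(counts / np.square(h))
    w = w / w.sum()

    def sph(hh, rng_m):
        hr = np.clip(hh / rng_m, 0.0, 1.0)
        return 1.5 * hr - 0.5 * hr**3

    def profile_fit(rng_m):
        # for a fixed range the model is linear in (nugget, partial sill)
        A = np.column_stack([np.ones_like(h), sph(h, rng_m)]) * w[:, None]
        coef, _ = nnls(A, gamma * w)
        resid = A @ coef - gamma * w
        return float(resid @ resid), coef

    # profiled grid search over the range avoids the local optima a joint
    # 3-parameter descent falls into on noisy empirical variograms
    candidates = np.geomspace(max(h.min(), 1.0), 2.0 * h.max(), 40)
    fits = [profile_fit(r) for r in candidates]
    best = int(np.argmin([f[0] for f in fits]))
    rng_m = float(candidates[best])
    nugget, psill = fits[best][1]

    def resid3(p):
        return w * (p[0] + max(p[1], 1e-12) * sph(h, max(p[2], 1.0)) - gamma)

    sol = least_squares(
        resid3,
        np.array([nugget, max(psill, 1e-9), rng_m]),
        bounds=([0.0, 1e-12, 1.0], [np.inf, np.inf, 4.0 * h.max()]),
        method="trf",
    )
    nugget, psill, rng_m = sol.x
    return VariogramModel(nugget=float(nugget), sill=float(nugget + psill), range_m=float(rng_m))


def _dedup_stations(x, y, z):
    """Average observations sharing identical coordinates (singular-system
    guard); returns arrays plus the number of merged duplicates."""
    df = pd.DataFrame({"x": x, "y": y, "z": z})
    g = df.groupby(["x", "y"], as_index=False, sort=False)["z"].mean()
    n_dup = len(df) - len(g)
    if n_dup:
        logger.warning("kriging: averaged %d duplicate station location(s)", n_dup)
    return g["x"].to_numpy(), g["y"].to_numpy(), g["z"].to_numpy(), n_dup


def ok_weights(stations_xy: np.ndarray, vg: VariogramModel, targets_xy: np.ndarray):
    """Solve the OK system for each target point.

    Returns (weights (n_stations, n_targets), lagrange multipliers). The
    full system is solved once per call: [Gamma 1; 1' 0] [w; mu] = [g; 1].
    """
    n = len(stations_xy)
    K = np.empty((n + 1, n + 1))
    K[:n, :n] = vg(squareform(pdist(stations_xy)))
    K[n, :n] = K[:n, n] = 1.0
    K[n, n] = 0.0
    B = np.empty((n + 1, targets_xy.shape[0]))
    B[:n] = vg(cdist(stations_xy, targets_xy))
    B[n] = 1.0
    try:
        sol = np.linalg.solve(K, B)
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(K, B, rcond=None)[0]
    return sol[:n], sol[n]


def krige_points(x, y, z, vg: VariogramModel, targets_xy, max_neighbors: int = 64):
    """OK prediction at arbitrary target points; returns (pred, diag)."""
    x, y, z, n_dup = _dedup_stations(np.asarray(x, float), np.asarray(y, float), np.asarray(z, float))
    if len(z) < MIN_STATIONS_KRIGE:
        raise KrigingError(f"kriging needs >= {MIN_STATIONS_KRIGE} distinct stations")
    stations = np.column_stack([x, y])
    targets_xy = np.asarray(targets_xy, float)
    if len(stations) <= max_neighbors:
        w, _ = ok_weights(stations, vg, targets_xy)
        pred = w.T @ z
        wsum_err = float(np.abs(w.sum(axis=0) - 1.0).max())
    else:
        # bounded neighborhood: nearest stations per target, grouped so each
        # distinct neighbor set is solved once
        tree = cKDTree(stations)
        _, nbr = tree.query(targets_xy, k=max_neighbors)
        pred = np.empty(len(targets_xy))
        wsum_err = 0.0
        order = np.lexsort(nbr.T)
        groups: dict[bytes, list[int]] = {}
        for i in order:
            groups.setdefault(np.sort(nbr[i]).tobytes(), []).append(i)
        for key, members in groups.items():
            idx = np.frombuffer(key, dtype=nbr.dtype)
            w, _ = ok_weights(stations[idx], vg, targets_xy[members])
            pred[members] = w.T @ z[idx]
            wsum_err = max(wsum_err, float(np.abs(w.sum(axis=0) - 1.0).max()))
    n_neg = int(np.sum(pred < 0))
    diag = {"weight_sum_max_err": wsum_err, "n_clipped": n_neg, "n_duplicates_merged": n_dup}
    if n_neg:
        logger.info("kriging: clipped %d negative prediction(s) to 0", n_neg)
    return np.clip(pred, 0.0, None), diag


def krige_grid(
    x, y, z, vg: VariogramModel, geom: GridGeometry, timestamp=None, max_neighbors: int = 64
) -> GridField:
    """Krige one snapshot onto the cell centers of a regular grid."""
    X, Y = geom.cell_centers()
    targets = np.column_stack([X.ravel(), Y.ravel()])
    pred, diag = krige_points(x, y, z, vg, targets, max_neighbors=max_neighbors)
    return GridField(
        geom=geom,
        timestamp=pd.Timestamp(timestamp) if timestamp is not None else pd.NaT,
        values=pred.reshape(geom.n_rows, geom.n_cols),
        diagnostics=diag,
    )


def hourly_station_means(sensors: pd.DataFrame, value_col: str = "pm25") -> pd.DataFrame:
    """Average sub-hourly sensor readings to hourly station means."""
    df = sensors.copy()
    df["hour"] = df["timestamp"].dt.floor("h")
    return (
        df.groupby(["hour", "station_id"], as_index=False)
        .agg(x_m=("x_m", "first"), y_m=("y_m", "first"), value=(value_col, "mean"))
        .rename(columns={"hour": "timestamp"})
    )


def krige_sensor_series(
    sensors: pd.DataFrame,
    geom: GridGeometry,
    value_col: str = "pm25",
    n_bins: int = 12,
    max_neighbors: int = 64,
) -> dict[pd.Timestamp, GridField]:
    """Full hourly pipeline: hourly means -> per-hour variogram -> OK grid."""
    hourly = hourly_station_means(sensors, value_col=value_col)
    fields: dict[pd.Timestamp, GridField] = {}
    for ts, snap in hourly.groupby("timestamp"):
        vg = fit_variogram(snap["x_m"], snap["y_m"], snap["value"], n_bins=n_bins)
        fields[ts] = krige_grid(
            snap["x_m"], snap["y_m"], snap["value"], vg, geom,
            timestamp=ts, max_neighbors=max_neighbors,
        )
    return fields
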