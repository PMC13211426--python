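"""Hourly indoor PM2.5 prediction per microenvironment.

One tree-ensemble regressor per indoor label, trained on six features:
outdoor PM2.5, the outdoor PM2.5/PM10 ratio, temperature, wind speed,
relative humidity and precipitation. Following common practice for this
problem, the house model uses extremely randomized trees and the other
indoor labels use gradient-boosted trees; both are trained with an
absolute-error (median) objective, so on right-skewed indoor series the
fit tracks the infiltration baseline rather than episodic source peaks —
hour-scale models cannot resolve minute-scale events, and the median
objective makes that smoothing explicit and robust.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesRegressor
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score
from sklearn.model_selection import train_test_split

from .config import INDOOR_MICROENVS, SLOT_MINUTES

FEATURES = ["outdoor_pm25", "ratio_pm25_pm10", "temp_c", "wind_ms", "rh_pct", "precip_mm"]

MIN_TRAIN_ROWS = 100


class DataSizeError(ValueError):
    pass


class FeatureError(ValueError):
    pass


def validate_features(df: pd.DataFrame) -> pd.DataFrame:
    """Check the six-feature frame: presence, no missing values, ratio in
    (0, 1], relative humidity in [0, 100]."""
    for c in FEATURES:
        if c not in df.columns:
            raise FeatureError(f"missing feature column: {c}")
        if df[c].isna().any():
            raise FeatureError(f"feature column {c} contains missing values")
    r = df["ratio_pm25_pm10"]
    if ((r <= 0) | (r > 1)).any():
        raise FeatureError("ratio_pm25_pm10 must lie in (0, 1]")
    if ((df["rh_pct"] < 0) | (df["rh_pct"] > 100)).any():
        raise FeatureError("rh_pct must lie in [0, 100]")
    return df[FEATURES]


def _make_backend(backend: str, seed: int):
    if backend == "extratrees":
        return ExtraTreesRegressor(
            n_estimators=80,
            criterion="absolute_error",
            min_samples_leaf=10,
            random_state=seed,
            n_jobs=1,
        )
    if backend == "xgboost":
        from xgboost import XGBRegressor

        return XGBRegressor(
            n_estimators=200,
            max_depth=5,
            learning_rate=0.1,
            objective="reg:absoluteerror",
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
    raise ValueError(f"unknown backend {backend!r}; use 'extratrees' or 'xgboost'")


def default_backend(label: str) -> str:
    return "extratrees" if label == "house" else "xgboost"


@dataclass
class MicroenvPredictor:
    """A fitted hourly indoor-concentration model for one label."""

    label: str
    backend: str
    model: object
    metrics: dict = field(default_factory=dict)
    seed: int = 0

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        X = validate_features(features)
        return np.clip(self.model.predict(X.to_numpy()), 0.0, None)


def train_predictor(
    features: pd.DataFrame,
    target,
    label: str,
    backend: str | None = None,
    seed: int = 0,
    holdout_fraction: float = 0.2,
) -> MicroenvPredictor:
    """Fit one label's regressor; holdout metrics (R2/RMSE/MAE) recorded.

    Refuses to train on fewer than 100 aligned hourly rows.
    """
    X = validate_features(features).to_numpy()
    y = np.asarray(target, dtype=float)
    if len(X) != len(y):
        raise FeatureError("features and target have different lengths")
    if len(X) < MIN_TRAIN_ROWS:
        raise DataSizeError(
            f"need >= {MIN_TRAIN_ROWS} aligned hourly rows to train {label!r} (got {len(X)})"
        )
    backend = backend or default_backend(label)
    Xtr, Xte, ytr, yte = train_test_split(X, y, test_size=holdout_fraction, random_state=seed)
    model = _make_backend(backend, seed)
    model.fit(Xtr, ytr)
    pred = np.clip(model.predict(Xte), 0.0, None)
    metrics = {
        "r2": float(r2_score(yte, pred)) if np.var(yte) > 0 else float("nan"),
        "rmse": float(np.sqrt(mean_squared_error(yte, pred))),
        "mae": float(mean_absolute_error(yte, pred)),
        "n_train": int(len(ytr)),
        "n_holdout": int(len(yte)),
    }
    return MicroenvPredictor(label=label, backend=backend, model=model, metrics=metrics, seed=seed)


def predict_indoor(pred: MicroenvPredictor, features: pd.DataFrame) -> np.ndarray:
    """Non-negative hourly indoor concentration predictions."""
    return pred.predict(features)


def hourly_to_slots(hourly: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """Forward-fill an hourly series onto the 30-min slot lattice (each
    hour covers its two half-hour slots)."""
    df = hourly.sort_values("timestamp").reset_index(drop=True)
    a = df.copy()
    b = df.copy()
    b["timestamp"] = b["timestamp"] + pd.Timedelta(minutes=SLOT_MINUTES)
    out = pd.concat([a, b], ignore_index=True).sort_values("timestamp")
    return out.rename(columns={"timestamp": "slot_start"}).reset_index(drop=True)[
        ["slot_start", value_col]
    ]


def train_all(
    training: pd.DataFrame,
    seed: int = 0,
    pooled_nonhouse: bool = False,
    backends: dict[str, str] | None = None,
) -> dict[str, MicroenvPredictor]:
    """Train one predictor per indoor label from a long training table
    with columns ``microenv``, ``indoor_pm25`` and the six features.

    With ``pooled_nonhouse=True`` all non-house labels share one pooled
    model (useful when per-label data are scarce).
    """
    backends = backends or {}
    out: dict[str, MicroenvPredictor] = {}
    house = training[training["microenv"] == "house"]
    if len(house):
        out["house"] = train_predictor(
            house, house["indoor_pm25"], "house",
            backend=backends.get("house"), seed=seed,
        )
    others = [m for m in INDOOR_MICROENVS if m != "house"]
    if pooled_nonhouse:
        sub = training[training["microenv"].isin(others)]
        if len(sub):
            pooled = train_predictor(
                sub, sub["indoor_pm25"], "pooled_indoor",
                backend=backends.get("pooled_indoor", "xgboost"), seed=seed,
            )
            for m in others:
                out[m] = pooled
    else:
        for m in others:
            sub = training[training["microenv"] == m]
            if len(sub):
                out[m] = train_predictor(
                    sub, sub["indoor_pm25"], m, backend=backends.get(m), seed=seed
                )
    return out
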