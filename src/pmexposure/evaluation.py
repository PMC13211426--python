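"""Scenario-versus-measured evaluation.

Per scenario, on matched participant-days: RMSE = sqrt(mean((y - yhat)^2))
and MAE = mean(|y - yhat|), Pearson r, and a summary table with Mean,
S.D., CV (%), Median, Max and the ratio of the scenario mean to the
measured mean (reported to 1 decimal place). CV is computed on the pooled
participant-day series per scenario, and Pearson r on pooled
participant-days. Paired t-tests compare each scenario with the measured
series; one-way ANOVA compares concentration groups across
microenvironments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SCENARIOS = ("s1", "s2", "s3")


class PairingError(ValueError):
    pass


def rmse_mae(pred, meas) -> tuple[float, float]:
    """Root-mean-square and mean absolute error of matched series."""
    pred = np.asarray(pred, dtype=float)
    meas = np.asarray(meas, dtype=float)
    if pred.shape != meas.shape:
        raise PairingError(f"length mismatch: {pred.shape} vs {meas.shape}")
    if pred.size == 0:
        raise PairingError("empty series")
    d = pred - meas
    return float(np.sqrt(np.mean(d**2))), float(np.mean(np.abs(d)))


@dataclass
class EvalMetrics:
    scenario: str
    n_days: int
    mean: float
    sd: float
    cv_pct: float
    median: float
    max: float
    rmse: float | None
    mae: float | None
    pearson_r: float | None
    mean_ratio_to_measured: float | None


def _series_stats(x: np.ndarray) -> dict:
    return {
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
        "cv_pct": float(100.0 * np.std(x, ddof=1) / np.mean(x))
        if len(x) > 1 and np.mean(x) != 0
        else float("nan"),
        "median": float(np.median(x)),
        "max": float(np.max(x)),
    }


def summarize_scenarios(daily: pd.DataFrame) -> pd.DataFrame:
    """One row per scenario plus the measured series.

    Error metrics and r use days where both the scenario and the measured
    value are present; distribution statistics use all finite days of the
    series itself. The mean ratio is rounded to 1 decimal place.
    """
    rows = []
    meas_all = daily["measured"].to_numpy(dtype=float)
    meas_ok = meas_all[np.isfinite(meas_all)]
    if len(meas_ok) == 0:
        raise PairingError("no measured days available")
    rows.append(
        {"scenario": "measured", "n_days": len(meas_ok), **_series_stats(meas_ok),
         "rmse": np.nan, "mae": np.nan, "pearson_r": np.nan,
         "mean_ratio_to_measured": 1.0}
    )
    for s in SCENARIOS:
        x = daily[s].to_numpy(dtype=float)
        ok = np.isfinite(x)
        matched = ok & np.isfinite(meas_all)
        rec = {"scenario": s, "n_days": int(ok.sum()), **_series_stats(x[ok])}
        if matched.sum() >= 1:
            rec["rmse"], rec["mae"] = rmse_mae(x[matched], meas_all[matched])
        else:
            rec["rmse"] = rec["mae"] = np.nan
        if matched.sum() >= 2 and np.var(x[matched]) > 0 and np.var(meas_all[matched]) > 0:
            rec["pearson_r"] = float(stats.pearsonr(x[matched], meas_all[matched])[0])
        else:
            rec["pearson_r"] = np.nan  # undefined under zero variance
        rec["mean_ratio_to_measured"] = (
            round(float(np.mean(x[matched]) / np.mean(meas_all[matched])), 1)
            if matched.sum() else np.nan
        )
        rows.append(rec)
    return pd.DataFrame(rows)


def mean_ratio(scenario_mean: float, measured_mean: float, ndigits: int = 1) -> float:
    """Scenario-to-measured mean ratio, reported to 1 d.p."""
    if measured_mean == 0:
        raise ZeroDivisionError("measured mean is zero")
    return round(scenario_mean / measured_mean, ndigits)


def paired_comparisons(daily: pd.DataFrame, groups: pd.DataFrame | None = None) -> pd.DataFrame:
    """Two-sided paired t-tests (scenario vs measured) and, when ``groups``
    is given (columns: group, value), a one-way ANOVA across groups.

    Degenerate pairs (all differences zero) are reported as no-difference
    with p = 1. Tests with insufficient data are reported with a reason.
    """
    rows = []
    meas = daily["measured"].to_numpy(dtype=float)
    for s in SCENARIOS:
        x = daily[s].to_numpy(dtype=float)
        m = np.isfinite(x) & np.isfinite(meas)
        if m.sum() < 3:
            rows.append({"test": f"paired_t_{s}_vs_measured", "statistic": np.nan,
                         "p_value": np.nan, "n": int(m.sum()),
                         "note": "skipped: fewer than 3 pairs"})
            continue
        d = x[m] - meas[m]
        if np.allclose(d, 0):
            rows.append({"test": f"paired_t_{s}_vs_measured", "statistic": 0.0,
                         "p_value": 1.0, "n": int(m.sum()), "note": "identical series"})
            continue
        t, p = stats.ttest_rel(x[m], meas[m])
        rows.append({"test": f"paired_t_{s}_vs_measured", "statistic": float(t),
                     "p_value": float(p), "n": int(m.sum()), "note": ""})
    if groups is not None:
        samples = [g["value"].to_numpy(dtype=float) for _, g in groups.groupby("group")]
        if len(samples) >= 2 and all(len(s_) >= 2 for s_ in samples):
            f, p = stats.f_oneway(*samples)
            rows.append({"test": "anova_microenv_groups", "statistic": float(f),
                         "p_value": float(p), "n": int(sum(map(len, samples))), "note": ""})
        else:
            rows.append({"test": "anova_microenv_groups", "statistic": np.nan,
                         "p_value": np.nan, "n": 0, "note": "skipped: need >= 2 groups of >= 2"})
    return pd.DataFrame(rows)
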