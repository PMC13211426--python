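"""Indoor/outdoor contribution rates and their CTE/RME summaries.

The per-source contribution on a day is C_i * T_i / (C_TWA * 24) * 100 in
the literal convention. Whenever the day's TAD-accounted hours fall short
of 24 the literal percentages cannot sum to 100, so the normalized
convention — dividing by the accounted hours sum(T_i) instead of 24 — is
also computed and is the headline output. CTE (central tendency) and RME
(reasonable maximum) are the contribution profiles on the days at the
50th and 95th percentile of the pooled daily TWA distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import INDOOR_MICROENVS, StudyConfig


@dataclass
class ContributionResult:
    scenario: str
    level: str  # "CTE", "RME" or "day"
    convention: str  # "normalized" or "literal24"
    indoor_pct: float
    outdoor_pct: float
    by_source: dict[str, float]
    day_ref: tuple  # (participant_id, date)


def _scenario_pairs(day: pd.Series, scenario: str, cfg: StudyConfig) -> dict[str, tuple[float, float]]:
    """(C_i, T_i) per source actually used by a scenario on one day."""
    if scenario == "s1":
        return {
            "house": (day["s1_c_house"], cfg.s1_time_house_h),
            "outdoor": (day["s1_c_outdoor"], cfg.s1_time_outdoor_h),
        }
    if scenario == "s2":
        return {
            "house": (day["s2_c_house"], day["s2_t_house"]),
            "outdoor": (day["s2_c_outdoor"], day["s2_t_outdoor"]),
        }
    if scenario == "s3":
        pairs = {
            m: (day[f"s3_c_{m}"], day[f"t_{m}"])
            for m in INDOOR_MICROENVS
            if day[f"t_{m}"] > 0 and np.isfinite(day[f"s3_c_{m}"])
        }
        pairs["outdoor"] = (day["s3_c_outdoor"], day["t_outdoor"])
        return pairs
    raise ValueError(f"unknown scenario {scenario!r}")


def contribution_rates(
    day: pd.Series,
    scenario: str,
    cfg: StudyConfig,
    convention: str = "normalized",
    level: str = "day",
) -> ContributionResult:
    """Per-source percent contributions for one participant-day."""
    if convention not in ("normalized", "literal24"):
        raise ValueError("convention must be 'normalized' or 'literal24'")
    c_twa = day[scenario]
    if not np.isfinite(c_twa) or c_twa <= 0:
        raise ValueError(f"{scenario} TWA is undefined or zero on this day")
    pairs = {
        k: v for k, v in _scenario_pairs(day, scenario, cfg).items()
        if np.isfinite(v[0]) and v[1] > 0
    }
    hours = 24.0 if convention == "literal24" else sum(t for _, t in pairs.values())
    by_source = {k: 100.0 * c * t / (c_twa * hours) for k, (c, t) in pairs.items()}
    outdoor = by_source.get("outdoor", 0.0)
    return ContributionResult(
        scenario=scenario,
        level=level,
        convention=convention,
        indoor_pct=sum(v for k, v in by_source.items() if k != "outdoor"),
        outdoor_pct=outdoor,
        by_source=by_source,
        day_ref=(day["participant_id"], day["date"]),
    )


def select_percentile_day(daily: pd.DataFrame, value_col: str, p: float) -> pd.Series:
    """The participant-day at the nearest-rank percentile of the pooled
    daily distribution: the ceil(p*n)-th order statistic, ties broken by
    earliest date then participant id."""
    sub = daily[np.isfinite(daily[value_col])]
    if not len(sub):
        raise ValueError(f"no finite values of {value_col}")
    if not 0 < p <= 1:
        raise ValueError("percentile fraction must lie in (0, 1]")
    ranked = sub.sort_values([value_col, "date", "participant_id"], kind="mergesort")
    k = max(math.ceil(p * len(ranked)), 1)
    return ranked.iloc[k - 1]


def cte_rme_table(daily: pd.DataFrame, cfg: StudyConfig) -> pd.DataFrame:
    """CTE and RME contribution profiles per scenario, both conventions.

    Percentile days are selected on the pooled participant-day TWA
    distribution of each scenario (not per participant).
    """
    rows = []
    for scenario in ("s1", "s2", "s3"):
        for level, p in (("CTE", cfg.cte_percentile), ("RME", cfg.rme_percentile)):
            day = select_percentile_day(daily, scenario, p)
            for convention in ("normalized", "literal24"):
                r = contribution_rates(day, scenario, cfg, convention=convention, level=level)
                rows.append(
                    {
                        "scenario": scenario,
                        "level": level,
                        "convention": convention,
                        "indoor_pct": r.indoor_pct,
                        "outdoor_pct": r.outdoor_pct,
                        "participant_id": r.day_ref[0],
                        "date": r.day_ref[1],
                    }
                )
    return pd.DataFrame(rows)
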