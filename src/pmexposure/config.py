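"""Run configuration for the exposure-assessment pipeline.

All times are timezone-naive local clock times; a participant-day is the
half-open interval [00:00, 24:00). Coordinates are planar metric x/y in
meters (pre-projected); kriging distances and the 500 m grid assume this.
"""

from __future__ import annotations

from pydantic import BaseModel, Field, model_validator

#: The closed set of microenvironment labels a time-activity diary may use.
MICROENVS = (
    "house",
    "office",
    "educational_facility",
    "transportation",
    "other_indoor",
    "outdoor",
)

#: Indoor labels (everything except "outdoor"). "transportation" is treated
#: as an indoor microenvironment by default; see StudyConfig.transport_uses_gps.
INDOOR_MICROENVS = tuple(m for m in MICROENVS if m != "outdoor")

SLOT_MINUTES = 30
SLOTS_PER_DAY = 24 * 60 // SLOT_MINUTES


class StudyConfig(BaseModel):
    """Parameters of the exposure study design.

    The S1 occupancy times are national exposure-factors handbook averages:
    15.86 h/day indoors at home and 3.34 h/day outdoors. CTE/RME are the
    contribution profiles on the days at the 50th / 95th percentile of the
    daily TWA distribution.
    """

    grid_cell_size_m: float = Field(500.0, gt=0)
    s1_time_house_h: float = Field(15.86, ge=0)
    s1_time_outdoor_h: float = Field(3.34, ge=0)
    cte_percentile: float = Field(0.50, gt=0, lt=1)
    rme_percentile: float = Field(0.95, gt=0, lt=1)
    rng_seed: int = 0

    #: minimum hours of valid personal-monitor minutes for a measured day
    min_personal_coverage_h: float = Field(18.0, gt=0, le=24)
    #: diary gaps longer than this exclude the participant-day from TWA;
    #: shorter gaps inherit the previous slot's label
    max_diary_gap_h: float = Field(4.0, ge=0)
    #: S3: if True, slots labeled "transportation" take the GPS outdoor
    #: concentration instead of the transportation indoor model
    transport_uses_gps: bool = False
    #: S2 sensitivity variant: fold office/educational/transportation/
    #: other_indoor hours into the house term instead of dropping them
    s2_fold_indoor_into_house: bool = False
    #: contribution-rate convention reported as the headline number
    contribution_convention: str = "normalized"
    #: kriging neighborhood bound (nearest stations used per prediction)
    kriging_max_neighbors: int = Field(64, ge=3)

    @model_validator(mode="after")
    def _check(self) -> "StudyConfig":
        if self.s1_time_house_h + self.s1_time_outdoor_h <= 0:
            raise ValueError("S1 occupancy times must sum to a positive total")
        if not self.cte_percentile < self.rme_percentile:
            raise ValueError("cte_percentile must be below rme_percentile")
        if self.contribution_convention not in ("normalized", "literal24"):
            raise ValueError("contribution_convention must be 'normalized' or 'literal24'")
        return self
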