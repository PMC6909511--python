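"""Core record types: one ICU admission-day of raw physiology, baseline
covariates, the admission outcome, and the panel observation sequence."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional, Sequence

import numpy as np

from .states import DiseaseState

#: Days of the 2-day observation grid used for model fitting.
GRID_DAYS: tuple[int, ...] = (1, 3, 5, 7, 9, 11, 13, 15)
HORIZON_DAY = 15

_HOUR_FIELDS = (
    "coma_hours_past24h",
    "sbp_lt90_hours",
    "high_dose_pressor_hours",
    "food_intolerance_hours",
)
_NONNEG_FIELDS = (
    "norepi_rate", "lactate", "pf_ratio", "peep", "urine_24h_ml",
    "creatinine", "creatinine_baseline", "platelets", "inr", "aptt",
    "bilirubin", "albumin", "ast", "alt", "caloric_intake_pct",
    "crp", "wbc", "resp_rate", "heart_rate",
)


@dataclass
class PatientDayRecord:
    """Raw measurements for one admission-day (day 1 = first 24 h).

    Hour-duration fields record how long the criterion condition held
    within the past 24 h and therefore live in [0, 24].  Missing lab
    values are ``nan`` (floats) or ``None`` (booleans) until imputed.
    """

    admission_id: str
    day: int
    # central nervous system
    cam_icu_positive: Optional[bool] = None
    continuous_sedation: Optional[bool] = None
    coma_hours_past24h: float = 0.0
    # cardiovascular
    sbp_lt90_hours: float = 0.0
    vasopressor_any: Optional[bool] = None
    norepi_rate: float = 0.0
    high_dose_pressor_hours: float = 0.0
    vasopressin: Optional[bool] = None
    lactate: float = np.nan
    fluid_balance_24h: float = 0.0
    inotrope_any: Optional[bool] = None
    # respiratory
    mech_vent: Optional[bool] = None
    pf_ratio: float = np.nan
    peep: float = 0.0
    # renal
    urine_6h_lt_0_5mlkgh: Optional[bool] = None
    urine_24h_ml: float = np.nan
    creatinine: float = np.nan
    creatinine_baseline: float = np.nan
    rrt: Optional[bool] = None
    acute_creatinine_rise_gt44: Optional[bool] = None
    # coagulation
    platelets: float = np.nan
    inr: float = np.nan
    aptt: float = np.nan
    # liver
    bilirubin: float = np.nan
    albumin: float = np.nan
    ast: float = np.nan
    alt: float = np.nan
    # gastro-intestinal
    caloric_intake_pct: float = np.nan
    food_intolerance_hours: float = 0.0
    # systemic response
    crp: float = np.nan
    wbc: float = np.nan
    temperature: float = np.nan
    resp_rate: float = np.nan
    heart_rate: float = np.nan
    new_onset_af: Optional[bool] = None
    bacteremia: Optional[bool] = None
    icu_acquired_infection: Optional[bool] = None
    corticosteroids: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.day < 1:
            raise ValueError(f"day must be >= 1, got {self.day}")
        for name in _HOUR_FIELDS:
            v = getattr(self, name)
            if np.isfinite(v) and not (0.0 <= v <= 24.0):
                raise ValueError(f"{name}={v} outside [0, 24]")
        for name in _NONNEG_FIELDS:
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValueError(f"{name}={v} must be nonnegative")
        if self.mech_vent and np.isfinite(self.pf_ratio) and self.pf_ratio <= 0:
            raise ValueError("pf_ratio must be > 0 under mechanical ventilation")

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]


INFECTION_SITES = ("pulmonary", "abdominal", "urinary", "other")


@dataclass
class BaselineCovariates:
    """Time-fixed admission covariates (PIRO predisposition + infection)."""

    age: float
    sex: str  # {male, female}
    bmi: float
    immunodeficiency: bool = False
    cardiovascular_disease: bool = False
    respiratory_insufficiency: bool = False
    renal_insufficiency: bool = False
    diabetes: bool = False
    corticosteroid_use_baseline: bool = False
    infection_site: str = "pulmonary"
    hospital_acquired: bool = False
    admission_type: str = "medical"  # {medical, surgical}

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.bmi <= 0:
            raise ValueError("bmi must be positive")
        if self.infection_site not in INFECTION_SITES:
            raise ValueError(f"unknown infection_site {self.infection_site!r}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.admission_type not in ("medical", "surgical"):
            raise ValueError(f"unknown admission_type {self.admission_type!r}")


TERMINAL_EVENTS = ("discharged_alive", "died", "in_icu_at_day15")


@dataclass
class AdmissionOutcome:
    """Terminal event of one admission within the 15-day window.

    ``palliative_start_day``: day end-of-life care began, if any.  For
    patients discharged alive after this point, observation time is
    censored from that day; deaths are never censored.
    """

    terminal_event: str
    event_day: int
    palliative_start_day: Optional[int] = None

    def __post_init__(self) -> None:
        if self.terminal_event not in TERMINAL_EVENTS:
            raise ValueError(f"unknown terminal_event {self.terminal_event!r}")
        if self.event_day < 1:
            raise ValueError("event_day must be >= 1")
        if (
            self.palliative_start_day is not None
            and self.palliative_start_day > self.event_day
        ):
            raise ValueError("palliative_start_day after event_day")


@dataclass
class PanelSequence:
    """One admission's states and covariates on the observation grid.

    States are sampled at days 1, 3, ..., 15; an absorbing event is
    recorded at its exact day and terminates the sequence.  ``covariates``
    holds one dict per observation (baseline + time-varying values at
    that day); model code extracts the design vector it needs.
    """

    admission_id: str
    observation_days: list[int]
    states: list[DiseaseState]
    covariates: list[dict] = field(default_factory=list)
    censored_from: Optional[int] = None

    def __post_init__(self) -> None:
        days = self.observation_days
        if len(days) != len(self.states):
            raise ValueError("observation_days and states length mismatch")
        if days and days[0] != 1:
            raise ValueError("first observation must be at day 1")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("observation_days must be strictly increasing")
        for k, s in enumerate(self.states[:-1]):
            if DiseaseState(s).is_absorbing:
                raise ValueError("observations recorded after an absorbing state")
        if self.censored_from is not None and days and days[-1] > self.censored_from:
            raise ValueError("observations recorded after censored_from")
        if self.covariates and len(self.covariates) != len(days):
            raise ValueError("covariates length mismatch")

    @property
    def n_obs(self) -> int:
        return len(self.observation_days)

    @property
    def final_state(self) -> DiseaseState:
        return DiseaseState(self.states[-1])

    def intervals(self) -> list[tuple[int, int, DiseaseState, DiseaseState, dict]]:
        """Consecutive observation pairs (t0, t1, s0, s1, x_at_t0)."""
        out = []
        for k in range(self.n_obs - 1):
            x = self.covariates[k] if self.covariates else {}
            out.append(
                (
                    self.observation_days[k],
                    self.observation_days[k + 1],
                    DiseaseState(self.states[k]),
                    DiseaseState(self.states[k + 1]),
                    x,
                )
            )
        return out


def state_array(sequences: Sequence[PanelSequence]) -> np.ndarray:
    """Stack final states of a collection, for quick summaries."""
    return np.array([int(s.final_state) for s in sequences])
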