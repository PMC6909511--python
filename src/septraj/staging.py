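"""Daily organ-failure staging.

Seven organ systems (CNS, cardiovascular, respiratory, renal,
coagulation, liver, gastro-intestinal) are each classified daily as
NONE / MODERATE / SEVERE dysfunction from raw physiology, using
SOFA-like thresholds extended with symptom-duration criteria.  The
patient-level stage then follows from the organ counts:

* multiple-organ failure (MOF)  -- severe dysfunction in >= 3 systems;
* at risk                        -- no severe dysfunction and moderate
                                    dysfunction in <= 2 systems;
* limited organ failure          -- everything in between.

Where criteria overlap, the worst satisfied level wins.  Criteria that
require persistence for more than 24 h (prolonged coma, prolonged
oliguria, prolonged food intolerance) are evaluated from consecutive-day
records and can therefore never fire on ICU day 1: patients cannot be
*admitted* with CNS, renal-duration or abdominal organ failure.

Missing inputs are handled upstream by imputation; any value still
missing here is treated as "criterion not met" (conservative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional, Sequence

import numpy as np

from .records import PatientDayRecord
from .states import DiseaseState


class OrganLevel(IntEnum):
    NONE = 0
    MODERATE = 1
    SEVERE = 2


ORGAN_SYSTEMS = (
    "cns",
    "cardiovascular",
    "respiratory",
    "renal",
    "coagulation",
    "liver",
    "gastrointestinal",
)


@dataclass(frozen=True)
class StagingConfig:
    """Tunable readings of ambiguous clinical criteria.

    ``lactate_standalone``: whether lactate > 2 mmol/L alone (without a
    vasopressor infusion) marks moderate cardiovascular dysfunction.
    The default requires the infusion, i.e. lactate qualifies the drug
    criterion rather than standing alone.
    """

    lactate_standalone: bool = False


DEFAULT_CONFIG = StagingConfig()

#: Every criterion the classifier can fire, for coverage audits.
ALL_RULE_IDS = frozenset(
    {
        "cns.moderate.delirium",
        "cns.moderate.sedation",
        "cns.moderate.coma_onset",
        "cns.severe.coma_gt24h",
        "cardio.moderate.hypotension_gt2h",
        "cardio.moderate.pressor_or_inotrope",
        "cardio.moderate.lactate_gt2",
        "cardio.moderate.fluid_balance_gt2L",
        "cardio.severe.refractory_shock",
        "resp.moderate.pf_lt300_peep_gt5",
        "resp.severe.pf_lt200_peep_gt8",
        "renal.moderate.oliguria_6h",
        "renal.moderate.urine_lt500",
        "renal.moderate.creatinine_gt1.5x",
        "renal.severe.oliguria_gt24h",
        "renal.severe.creatinine_gt3x",
        "renal.severe.creatinine_gt350_acute_rise",
        "renal.severe.rrt",
        "coag.moderate.platelets_lt100",
        "coag.moderate.inr_gt1.5",
        "coag.moderate.aptt_gt60",
        "coag.severe.platelets_lt50",
        "liver.moderate.bilirubin_gt30",
        "liver.moderate.albumin_lt20",
        "liver.moderate.transaminases_gt500",
        "liver.severe.bilirubin_gt100",
        "liver.severe.transaminases_gt1000",
        "liver.severe.albumin_lt15",
        "gi.moderate.caloric_intake_lt50pct",
        "gi.moderate.food_intolerance_onset",
        "gi.severe.food_intolerance_gt24h",
    }
)


@dataclass
class OrganProfile:
    """Per-organ dysfunction levels for one patient-day."""

    levels: dict[str, OrganLevel]

    def __post_init__(self) -> None:
        if set(self.levels) != set(ORGAN_SYSTEMS):
            missing = set(ORGAN_SYSTEMS) - set(self.levels)
            raise ValueError(f"profile missing organ systems: {sorted(missing)}")

    def count(self, level: OrganLevel) -> int:
        return sum(1 for v in self.levels.values() if v == level)


@dataclass
class StageRuleTrace:
    """Audit trail: which criteria fired, with their triggering values."""

    fired: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    stage: Optional[DiseaseState] = None

    def add(self, system: str, rule: str, value: float) -> None:
        self.fired.setdefault(system, []).append((rule, float(value)))

    def rules(self) -> set[str]:
        return {r for rs in self.fired.values() for r, _ in rs}


def _v(x) -> float:
    """Missing-safe numeric view: nan when absent."""
    if x is None:
        return np.nan
    return float(x)


def _b(x) -> bool:
    return bool(x) if x is not None else False


def _span_gt24(today_hours: float, history: Sequence[PatientDayRecord],
               attr: str) -> bool:
    """True when a duration criterion has persisted for > 24 h in total,
    i.e. today's hours plus the previous day's hours exceed 24."""
    if not history:
        return False
    prev = _v(getattr(history[-1], attr))
    t = _v(today_hours)
    if np.isnan(prev) or np.isnan(t):
        return False
    return t + prev > 24.0


def classify_organ(
    system: str,
    today: PatientDayRecord,
    history: Sequence[PatientDayRecord] = (),
    config: StagingConfig = DEFAULT_CONFIG,
    trace: Optional[StageRuleTrace] = None,
) -> OrganLevel:
    """Classify one organ system for one day; worst satisfied level wins.

    ``history`` holds the prior days' records (ascending), used only by
    the > 24-h persistence criteria.  Fired criteria are appended to
    ``trace`` when given.
    """
    if system not in ORGAN_SYSTEMS:
        raise ValueError(f"unknown organ system {system!r}")
    t = trace if trace is not None else StageRuleTrace()
    r = today
    level = OrganLevel.NONE

    def fire(lvl: OrganLevel, rule: str, value: float) -> None:
        nonlocal level
        t.add(system, rule, value)
        level = max(level, lvl)

    if system == "cns":
        if _b(r.cam_icu_positive):
            fire(OrganLevel.MODERATE, "cns.moderate.delirium", 1)
        if _b(r.continuous_sedation):
            fire(OrganLevel.MODERATE, "cns.moderate.sedation", 1)
        if _v(r.coma_hours_past24h) > 0:
            fire(OrganLevel.MODERATE, "cns.moderate.coma_onset", r.coma_hours_past24h)
        if _span_gt24(r.coma_hours_past24h, history, "coma_hours_past24h"):
            fire(OrganLevel.SEVERE, "cns.severe.coma_gt24h", r.coma_hours_past24h)

    elif system == "cardiovascular":
        if _v(r.sbp_lt90_hours) > 2:
            fire(OrganLevel.MODERATE, "cardio.moderate.hypotension_gt2h",
                 r.sbp_lt90_hours)
        infusion = _b(r.vasopressor_any) or _b(r.inotrope_any) or _b(r.vasopressin)
        if infusion:
            fire(OrganLevel.MODERATE, "cardio.moderate.pressor_or_inotrope", 1)
        if config.lactate_standalone and _v(r.lactate) > 2:
            fire(OrganLevel.MODERATE, "cardio.moderate.lactate_gt2", r.lactate)
        if _v(r.fluid_balance_24h) > 2:
            fire(OrganLevel.MODERATE, "cardio.moderate.fluid_balance_gt2L",
                 r.fluid_balance_24h)
        high_dose = _v(r.norepi_rate) > 0.1 or _b(r.vasopressin)
        if (
            high_dose
            and _v(r.high_dose_pressor_hours) > 12
            and _v(r.fluid_balance_24h) > 2
            and _v(r.lactate) > 2
        ):
            fire(OrganLevel.SEVERE, "cardio.severe.refractory_shock", r.norepi_rate)

    elif system == "respiratory":
        if _b(r.mech_vent):
            pf, peep = _v(r.pf_ratio), _v(r.peep)
            if pf < 300 and peep > 5:
                fire(OrganLevel.MODERATE, "resp.moderate.pf_lt300_peep_gt5", pf)
            if pf < 200 and peep > 8:
                fire(OrganLevel.SEVERE, "resp.severe.pf_lt200_peep_gt8", pf)

    elif system == "renal":
        if _b(r.urine_6h_lt_0_5mlkgh):
            fire(OrganLevel.MODERATE, "renal.moderate.oliguria_6h", 1)
        urine = _v(r.urine_24h_ml)
        if urine < 500:
            fire(OrganLevel.MODERATE, "renal.moderate.urine_lt500", urine)
        creat, creat0 = _v(r.creatinine), _v(r.creatinine_baseline)
        if np.isnan(creat0) and history:
            creat0 = _v(history[0].creatinine)
        if creat > 1.5 * creat0:
            fire(OrganLevel.MODERATE, "renal.moderate.creatinine_gt1.5x", creat)
        prev_urine = _v(history[-1].urine_24h_ml) if history else np.nan
        if urine < 200 and prev_urine < 500:
            fire(OrganLevel.SEVERE, "renal.severe.oliguria_gt24h", urine)
        if creat > 3.0 * creat0:
            fire(OrganLevel.SEVERE, "renal.severe.creatinine_gt3x", creat)
        if creat > 350 and _b(r.acute_creatinine_rise_gt44):
            fire(OrganLevel.SEVERE, "renal.severe.creatinine_gt350_acute_rise", creat)
        if _b(r.rrt):
            fire(OrganLevel.SEVERE, "renal.severe.rrt", 1)

    elif system == "coagulation":
        plt = _v(r.platelets)
        if plt < 100:
            fire(OrganLevel.MODERATE, "coag.moderate.platelets_lt100", plt)
        if _v(r.inr) > 1.5:
            fire(OrganLevel.MODERATE, "coag.moderate.inr_gt1.5", r.inr)
        if _v(r.aptt) > 60:
            fire(OrganLevel.MODERATE, "coag.moderate.aptt_gt60", r.aptt)
        if plt < 50:
            fire(OrganLevel.SEVERE, "coag.severe.platelets_lt50", plt)

    elif system == "liver":
        bili = _v(r.bilirubin)
        alb = _v(r.albumin)
        _tas = [x for x in (_v(r.ast), _v(r.alt)) if not np.isnan(x)]
        ta = max(_tas) if _tas else np.nan
        if bili > 30:
            fire(OrganLevel.MODERATE, "liver.moderate.bilirubin_gt30", bili)
        if alb < 20:
            fire(OrganLevel.MODERATE, "liver.moderate.albumin_lt20", alb)
        if ta > 500:
            fire(OrganLevel.MODERATE, "liver.moderate.transaminases_gt500", ta)
        if bili > 100:
            fire(OrganLevel.SEVERE, "liver.severe.bilirubin_gt100", bili)
        if ta > 1000:
            fire(OrganLevel.SEVERE, "liver.severe.transaminases_gt1000", ta)
        if alb < 15:
            fire(OrganLevel.SEVERE, "liver.severe.albumin_lt15", alb)

    elif system == "gastrointestinal":
        intake = _v(r.caloric_intake_pct)
        if intake < 50:
            fire(OrganLevel.MODERATE, "gi.moderate.caloric_intake_lt50pct", intake)
        if _v(r.food_intolerance_hours) > 0:
            fire(OrganLevel.MODERATE, "gi.moderate.food_intolerance_onset",
                 r.food_intolerance_hours)
        if _span_gt24(r.food_intolerance_hours, history, "food_intolerance_hours"):
            fire(OrganLevel.SEVERE, "gi.severe.food_intolerance_gt24h",
                 r.food_intolerance_hours)

    return level


def classify_day(
    today: PatientDayRecord,
    history: Sequence[PatientDayRecord] = (),
    config: StagingConfig = DEFAULT_CONFIG,
    trace: Optional[StageRuleTrace] = None,
) -> OrganProfile:
    """Classify all seven organ systems for one day."""
    levels = {
        sys: classify_organ(sys, today, history, config, trace)
        for sys in ORGAN_SYSTEMS
    }
    return OrganProfile(levels=levels)


def stage_patient(
    profile: OrganProfile, trace: Optional[StageRuleTrace] = None
) -> DiseaseState:
    """Patient-level stage from the organ-level counts.

    MOF requires severe dysfunction in >= 3 systems.  "At risk" is the
    least severe stage compatible with the profile: no severe
    dysfunction and at most 2 moderate ones.  Profiles with >= 4
    moderate but < 3 severe dysfunctions fall to limited organ failure,
    since MOF is exclusively defined by the severe count.
    """
    n_sev = profile.count(OrganLevel.SEVERE)
    n_mod = profile.count(OrganLevel.MODERATE)
    if n_sev >= 3:
        stage = DiseaseState.MOF
    elif n_sev == 0 and n_mod <= 2:
        stage = DiseaseState.AT_RISK
    else:
        stage = DiseaseState.LIMITED_OF
    if trace is not None:
        trace.stage = stage
    return stage


def stage_series(
    records: Sequence[PatientDayRecord],
    config: StagingConfig = DEFAULT_CONFIG,
    with_traces: bool = False,
):
    """Stage every ICU day of one admission.

    Records must be consecutive days starting at the first record's day;
    a gap raises ``ValueError``.  Returns a list of transient
    :class:`~septraj.states.DiseaseState`, plus traces when requested.
    """
    records = list(records)
    for prev, cur in zip(records, records[1:]):
        if cur.day != prev.day + 1:
            raise ValueError(
                f"gap in day numbering: day {prev.day} followed by {cur.day}"
            )
    states, traces = [], []
    for k, rec in enumerate(records):
        trace = StageRuleTrace()
        profile = classify_day(rec, records[:k], config, trace)
        states.append(stage_patient(profile, trace))
        traces.append(trace)
    return (states, traces) if with_traces else states
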