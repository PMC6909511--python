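"""Organ-level and patient-level staging rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hs

import septraj as st
from septraj.staging import (
    ALL_RULE_IDS,
    OrganLevel,
    StageRuleTrace,
    StagingConfig,
    classify_day,
    classify_organ,
    stage_patient,
    stage_series,
)
from septraj.states import DiseaseState

from conftest import healthy_record


# --- organ-level criteria -------------------------------------------------

CARDIO_CASES = [
    # hypotension > 2 h is moderate
    (dict(sbp_lt90_hours=3.0, lactate=1.0), OrganLevel.MODERATE),
    # brief hypotension alone does not fire
    (dict(sbp_lt90_hours=1.5), OrganLevel.NONE),
    # high-dose norepinephrine > 12 h with fluid overload and lactataemia
    (
        dict(norepi_rate=0.15, high_dose_pressor_hours=14.0,
             fluid_balance_24h=3.0, lactate=3.1, vasopressor_any=True),
        OrganLevel.SEVERE,
    ),
    # same picture but only 10 h of high-dose support: moderate (infusion)
    (
        dict(norepi_rate=0.15, high_dose_pressor_hours=10.0,
             fluid_balance_24h=3.0, lactate=3.1, vasopressor_any=True),
        OrganLevel.MODERATE,
    ),
    (dict(fluid_balance_24h=2.5), OrganLevel.MODERATE),
]


@pytest.mark.parametrize("overrides,expected", CARDIO_CASES)
def test_cardiovascular_criteria(overrides, expected):
    rec = healthy_record(**overrides)
    assert classify_organ("cardiovascular", rec) == expected


@pytest.mark.parametrize(
    "overrides,expected",
    [
        (dict(platelets=40.0), OrganLevel.SEVERE),
        (dict(platelets=80.0), OrganLevel.MODERATE),
        (dict(platelets=150.0, inr=1.2), OrganLevel.NONE),
        (dict(inr=1.8), OrganLevel.MODERATE),
        (dict(aptt=75.0), OrganLevel.MODERATE),
        # boundaries are strict as printed: exactly 100 is not < 100
        (dict(platelets=100.0), OrganLevel.NONE),
        (dict(platelets=50.0), OrganLevel.MODERATE),
    ],
)
def test_coagulation_criteria(overrides, expected):
    assert classify_organ("coagulation", healthy_record(**overrides)) == expected


@pytest.mark.parametrize(
    "overrides,expected",
    [
        (dict(mech_vent=True, pf_ratio=180.0, peep=10.0), OrganLevel.SEVERE),
        (dict(mech_vent=True, pf_ratio=250.0, peep=6.0), OrganLevel.MODERATE),
        (dict(mech_vent=False, pf_ratio=400.0), OrganLevel.NONE),
        # severe needs PEEP > 8 despite ventilation
        (dict(mech_vent=True, pf_ratio=180.0, peep=7.0), OrganLevel.MODERATE),
    ],
)
def test_respiratory_criteria(overrides, expected):
    assert classify_organ("respiratory", healthy_record(**overrides)) == expected


def test_renal_creatinine_fold_rise():
    rec = healthy_record(creatinine=3.2 * 80.0, creatinine_baseline=80.0)
    assert classify_organ("renal", rec) == OrganLevel.SEVERE
    rec = healthy_record(creatinine=1.8 * 80.0, creatinine_baseline=80.0)
    assert classify_organ("renal", rec) == OrganLevel.MODERATE
    # baseline falls back to the first ICU value when absent
    day1 = healthy_record(day=1, creatinine=100.0, creatinine_baseline=np.nan)
    day2 = healthy_record(day=2, creatinine=380.0, creatinine_baseline=np.nan)
    assert classify_organ("renal", day2, [day1]) == OrganLevel.SEVERE


def test_renal_rrt_and_acute_rise():
    assert classify_organ("renal", healthy_record(rrt=True)) == OrganLevel.SEVERE
    rec = healthy_record(creatinine=360.0, acute_creatinine_rise_gt44=True,
                         creatinine_baseline=300.0)
    assert classify_organ("renal", rec) == OrganLevel.SEVERE


def test_lactate_reading_is_configurable():
    rec = healthy_record(lactate=3.0)
    assert classify_organ("cardiovascular", rec) == OrganLevel.NONE
    cfg = StagingConfig(lactate_standalone=True)
    assert classify_organ("cardiovascular", rec, config=cfg) == OrganLevel.MODERATE


def test_unknown_system_rejected():
    with pytest.raises(ValueError, match="unknown organ system"):
        classify_organ("cardiac", healthy_record())


# --- duration criteria spanning days --------------------------------------

def test_coma_needs_persistence_beyond_day1():
    day1 = healthy_record(day=1, coma_hours_past24h=24.0)
    assert classify_organ("cns", day1) == OrganLevel.MODERATE
    day2 = healthy_record(day=2, coma_hours_past24h=24.0)
    assert classify_organ("cns", day2, [day1]) == OrganLevel.SEVERE
    # coma that resolved yesterday does not persist
    day2b = healthy_record(day=2, coma_hours_past24h=24.0)
    prior = healthy_record(day=1, coma_hours_past24h=0.0)
    assert classify_organ("cns", day2b, [prior]) == OrganLevel.MODERATE


def test_food_intolerance_gt24h():
    day1 = healthy_record(day=1, food_intolerance_hours=20.0)
    day2 = healthy_record(day=2, food_intolerance_hours=10.0)
    assert classify_organ("gastrointestinal", day1) == OrganLevel.MODERATE
    assert classify_organ("gastrointestinal", day2, [day1]) == OrganLevel.SEVERE


def test_prolonged_oliguria():
    day1 = healthy_record(day=1, urine_24h_ml=400.0)
    day2 = healthy_record(day=2, urine_24h_ml=150.0)
    assert classify_organ("renal", day1) == OrganLevel.MODERATE
    assert classify_organ("renal", day2, [day1]) == OrganLevel.SEVERE
    # without the prior oliguric day it stays moderate
    assert classify_organ("renal", day2, [healthy_record(day=1)]) == OrganLevel.MODERATE


# --- patient-level stage ---------------------------------------------------

def _profile(n_severe, n_moderate):
    organs = ("cns", "cardiovascular", "respiratory", "renal",
              "coagulation", "liver", "gastrointestinal")
    levels = {}
    for k, o in enumerate(organs):
        if k < n_severe:
            levels[o] = OrganLevel.SEVERE
        elif k < n_severe + n_moderate:
            levels[o] = OrganLevel.MODERATE
        else:
            levels[o] = OrganLevel.NONE
    return st.OrganProfile(levels=levels)


@pytest.mark.parametrize(
    "n_severe,n_moderate,expected",
    [
        (3, 0, DiseaseState.MOF),
        (4, 2, DiseaseState.MOF),
        (0, 2, DiseaseState.AT_RISK),
        (0, 0, DiseaseState.AT_RISK),
        (0, 3, DiseaseState.LIMITED_OF),
        (2, 5, DiseaseState.LIMITED_OF),
        (1, 0, DiseaseState.LIMITED_OF),
        (0, 4, DiseaseState.LIMITED_OF),  # >= 4 moderate, < 3 severe
        (2, 0, DiseaseState.LIMITED_OF),
    ],
)
def test_stage_patient_boundaries(n_severe, n_moderate, expected):
    assert stage_patient(_profile(n_severe, n_moderate)) == expected


def test_stage_patient_is_pure():
    p = _profile(1, 2)
    assert stage_patient(p) == stage_patient(_profile(1, 2))


# --- daily series ----------------------------------------------------------

def test_stage_series_crosses_mof_boundary_on_day4():
    # three severe systems appear on day 4; stage must change exactly then
    base = dict(platelets=40.0, bilirubin=150.0)  # 2 severe organs
    recs = [
        healthy_record(day=1),
        healthy_record(day=2, **base),
        healthy_record(day=3, **base),
        healthy_record(day=4, **base, rrt=True),
        healthy_record(day=5, **base, rrt=True),
    ]
    states = stage_series(recs)
    assert states == [
        DiseaseState.AT_RISK,
        DiseaseState.LIMITED_OF,
        DiseaseState.LIMITED_OF,
        DiseaseState.MOF,
        DiseaseState.MOF,
    ]


def test_stage_series_healthy_is_at_risk():
    recs = [healthy_record(day=d) for d in range(1, 6)]
    assert stage_series(recs) == [DiseaseState.AT_RISK] * 5


def test_stage_series_rejects_day_gap():
    recs = [healthy_record(day=1), healthy_record(day=3)]
    with pytest.raises(ValueError, match="gap in day numbering"):
        stage_series(recs)


def test_traces_nonempty_when_dysfunction():
    trace = StageRuleTrace()
    classify_day(healthy_record(platelets=40.0), trace=trace)
    assert "coag.severe.platelets_lt50" in trace.rules()


# --- full criterion coverage ----------------------------------------------

COVERAGE_FIXTURES = [
    (dict(cam_icu_positive=True), None),
    (dict(continuous_sedation=True), None),
    (dict(coma_hours_past24h=12.0), None),
    (dict(coma_hours_past24h=24.0), dict(coma_hours_past24h=24.0)),
    (dict(sbp_lt90_hours=4.0), None),
    (dict(vasopressor_any=True), None),
    (dict(lactate=2.5), None),  # needs lactate_standalone config
    (dict(fluid_balance_24h=3.0), None),
    (dict(norepi_rate=0.2, high_dose_pressor_hours=14.0,
          fluid_balance_24h=3.0, lactate=4.0), None),
    (dict(mech_vent=True, pf_ratio=250.0, peep=6.0), None),
    (dict(mech_vent=True, pf_ratio=150.0, peep=10.0), None),
    (dict(urine_6h_lt_0_5mlkgh=True), None),
    (dict(urine_24h_ml=400.0), None),
    (dict(creatinine=130.0), None),
    (dict(urine_24h_ml=150.0), dict(urine_24h_ml=300.0)),
    (dict(creatinine=300.0), None),
    (dict(creatinine=360.0, acute_creatinine_rise_gt44=True), None),
    (dict(rrt=True), None),
    (dict(platelets=80.0), None),
    (dict(inr=2.0), None),
    (dict(aptt=70.0), None),
    (dict(platelets=30.0), None),
    (dict(bilirubin=50.0), None),
    (dict(albumin=18.0), None),
    (dict(ast=600.0), None),
    (dict(bilirubin=150.0), None),
    (dict(alt=1500.0), None),
    (dict(albumin=12.0), None),
    (dict(caloric_intake_pct=30.0), None),
    (dict(food_intolerance_hours=6.0), None),
    (dict(food_intolerance_hours=20.0), dict(food_intolerance_hours=20.0)),
]


def test_every_criterion_fires_at_least_once():
    fired = set()
    cfg = StagingConfig(lactate_standalone=True)
    for today_kw, prior_kw in COVERAGE_FIXTURES:
        history = [healthy_record(day=1, **prior_kw)] if prior_kw else []
        rec = healthy_record(day=2 if history else 1, **today_kw)
        trace = StageRuleTrace()
        classify_day(rec, history, cfg, trace)
        fired |= trace.rules()
    assert fired == ALL_RULE_IDS


# --- monotonicity property -------------------------------------------------

#: (field, direction of clinical worsening)
WORSEN = [
    ("sbp_lt90_hours", +1), ("norepi_rate", +1), ("high_dose_pressor_hours", +1),
    ("lactate", +1), ("fluid_balance_24h", +1), ("pf_ratio", -1), ("peep", +1),
    ("urine_24h_ml", -1), ("creatinine", +1), ("platelets", -1), ("inr", +1),
    ("aptt", +1), ("bilirubin", +1), ("albumin", -1), ("ast", +1), ("alt", +1),
    ("caloric_intake_pct", -1), ("food_intolerance_hours", +1),
    ("coma_hours_past24h", +1),
]

_BOUNDS = {
    "sbp_lt90_hours": (0, 24), "high_dose_pressor_hours": (0, 24),
    "food_intolerance_hours": (0, 24), "coma_hours_past24h": (0, 24),
    "pf_ratio": (40, 500), "peep": (0, 18), "norepi_rate": (0, 0.5),
    "lactate": (0.5, 12), "fluid_balance_24h": (-2, 6),
    "urine_24h_ml": (50, 3000), "creatinine": (40, 500),
    "platelets": (5, 400), "inr": (0.9, 4), "aptt": (20, 120),
    "bilirubin": (3, 300), "albumin": (8, 45), "ast": (10, 2500),
    "alt": (10, 2500), "caloric_intake_pct": (0, 120),
}


@settings(max_examples=300, derandomize=True, deadline=None)
@given(data=hs.data())
def test_worsening_any_measurement_never_lowers_stage(data):
    rng = np.random.default_rng(data.draw(hs.integers(0, 2**31 - 1)))
    overrides = {}
    for f, (lo, hi) in _BOUNDS.items():
        overrides[f] = float(rng.uniform(lo, hi))
    for f in ("mech_vent", "vasopressor_any", "rrt", "cam_icu_positive"):
        overrides[f] = bool(rng.random() < 0.4)
    rec = healthy_record(day=2, **overrides)
    history = [healthy_record(day=1, **overrides)]
    before_profile = classify_day(rec, history)
    before = stage_patient(before_profile)

    f, direction = WORSEN[data.draw(hs.integers(0, len(WORSEN) - 1))]
    lo, hi = _BOUNDS[f]
    worse_val = overrides[f] + direction * float(rng.uniform(0, hi - lo))
    worse_val = float(np.clip(worse_val, lo, hi))
    worse = healthy_record(day=2, **{**overrides, f: worse_val})
    after_profile = classify_day(worse, history)
    after = stage_patient(after_profile)
    assert int(after) >= int(before)
    for organ in before_profile.levels:
        assert after_profile.levels[organ] >= before_profile.levels[organ]
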