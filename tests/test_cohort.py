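"""Cohort I/O, readmission merging, censoring, and panel construction."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import septraj as st
from septraj.cohort import (
    Admission,
    DataError,
    SchemaError,
    apply_palliative_censoring,
    build_panel,
    merge_readmissions,
    read_cohort,
    write_cohort,
)
from septraj.records import AdmissionOutcome, PanelSequence
from septraj.states import DiseaseState

from conftest import healthy_record


@pytest.fixture()
def cohort_files(tmp_path):
    cfg = st.SimulationConfig(n_admissions=12, seed=5)
    _, admissions = st.simulate_cohort(cfg)
    paths = (tmp_path / "d.csv", tmp_path / "b.csv", tmp_path / "o.csv")
    write_cohort(admissions, *paths)
    return admissions, paths


def _records_equal(r0, r1):
    for f in dataclasses.fields(r0):
        a, b = getattr(r0, f.name), getattr(r1, f.name)
        if a != b and not (
            isinstance(a, float) and isinstance(b, float)
            and np.isnan(a) and np.isnan(b)
        ):
            return False
    return True


def test_read_write_round_trip_bit_exact(cohort_files, tmp_path):
    admissions, paths = cohort_files
    back = read_cohort(*paths)
    assert len(back) == len(admissions)
    for a0, a1 in zip(admissions, back):
        assert a0.admission_id == a1.admission_id
        assert a0.outcome == a1.outcome
        assert a0.baseline == a1.baseline
        assert all(_records_equal(r0, r1) for r0, r1 in zip(a0.records, a1.records))
    # writing the re-read cohort reproduces the files byte for byte
    paths2 = (tmp_path / "d2.csv", tmp_path / "b2.csv", tmp_path / "o2.csv")
    write_cohort(back, *paths2)
    for p1, p2 in zip(paths, paths2):
        assert p1.read_bytes() == p2.read_bytes()


def test_missing_required_column_is_schema_error(cohort_files, tmp_path):
    _, (d, b, o) = cohort_files
    df = pd.read_csv(d).drop(columns=["lactate"])
    bad = tmp_path / "bad.csv"
    df.to_csv(bad, index=False)
    with pytest.raises(SchemaError, match="lactate"):
        read_cohort(bad, b, o)


def test_duplicate_admission_day_is_data_error(cohort_files, tmp_path):
    _, (d, b, o) = cohort_files
    df = pd.read_csv(d)
    df = pd.concat([df, df.iloc[[0]]])
    bad = tmp_path / "dup.csv"
    df.to_csv(bad, index=False)
    with pytest.raises(DataError, match="duplicate"):
        read_cohort(bad, b, o)


def test_schema_mapping_renames_columns(cohort_files, tmp_path):
    _, (d, b, o) = cohort_files
    df = pd.read_csv(d).rename(columns={"lactate": "LACTATE_MMOL"})
    renamed = tmp_path / "ren.csv"
    df.to_csv(renamed, index=False)
    back = read_cohort(renamed, b, o, schema={"LACTATE_MMOL": "lactate"})
    assert len(back) == 12


# --- readmission merging ---------------------------------------------------

def _admission(aid, pid, cal_day, n_days, event="discharged_alive"):
    recs = [healthy_record(admission_id=aid, day=i + 1) for i in range(n_days)]
    baseline = st.BaselineCovariates(age=60, sex="male", bmi=25)
    return Admission(aid, pid, recs, baseline,
                     AdmissionOutcome(event, n_days), admit_calendar_day=cal_day)


def test_merge_same_day_readmission():
    merged = merge_readmissions(
        [_admission("a1", "p1", 0, 5), _admission("a2", "p1", 4, 3, "died")]
    )
    assert len(merged) == 1
    adm = merged[0]
    assert [r.day for r in adm.records] == list(range(1, 9))
    assert adm.outcome.terminal_event == "died"
    assert adm.outcome.event_day == 8


def test_readmission_after_gap_stays_separate():
    merged = merge_readmissions(
        [_admission("a1", "p1", 0, 5), _admission("a2", "p1", 8, 3)]
    )
    assert len(merged) == 2


def test_merge_is_identity_without_readmissions():
    adms = [_admission("a1", "p1", 0, 4), _admission("a2", "p2", 0, 6)]
    assert merge_readmissions(adms) == sorted(adms, key=lambda a: a.admission_id)


def test_merge_is_idempotent():
    adms = [_admission("a1", "p1", 0, 5), _admission("a2", "p1", 5, 3)]
    once = merge_readmissions(adms)
    assert merge_readmissions(once) == once


def test_overlapping_stays_rejected():
    with pytest.raises(DataError, match="overlapping"):
        merge_readmissions(
            [_admission("a1", "p1", 0, 6), _admission("a2", "p1", 2, 3)]
        )


# --- palliative censoring --------------------------------------------------

def _seq(days, states):
    return PanelSequence("x", days, [DiseaseState(s) for s in states],
                         [{} for _ in days])


def test_palliative_censoring_drops_later_observations():
    seq = _seq([1, 3, 5, 7, 9, 10], [2, 2, 2, 2, 2, 4])
    out = AdmissionOutcome("discharged_alive", 10, palliative_start_day=7)
    c = apply_palliative_censoring(seq, out)
    assert c.observation_days == [1, 3, 5, 7]
    assert c.censored_from == 7
    assert all(DiseaseState(s).is_transient for s in c.states)


def test_no_palliative_decision_is_identity():
    seq = _seq([1, 3, 5], [2, 2, 2])
    out = AdmissionOutcome("in_icu_at_day15", 15)
    assert apply_palliative_censoring(seq, out) == seq


def test_death_after_palliative_decision_is_kept():
    seq = _seq([1, 3, 5, 7, 9], [2, 2, 3, 3, 5])
    out = AdmissionOutcome("died", 9, palliative_start_day=7)
    assert apply_palliative_censoring(seq, out) == seq


# --- panel construction ----------------------------------------------------

def test_panel_death_day6():
    states = [DiseaseState.LIMITED_OF] * 5
    seq = build_panel("a", states, None, AdmissionOutcome("died", 6))
    assert seq.observation_days == [1, 3, 5, 6]
    assert seq.states[-1] == DiseaseState.DEAD
    assert all(DiseaseState(s).is_transient for s in seq.states[:-1])


def test_panel_still_in_icu_at_horizon():
    states = [DiseaseState.MOF] * 20
    seq = build_panel("a", states, None, AdmissionOutcome("in_icu_at_day15", 15))
    assert seq.observation_days == [1, 3, 5, 7, 9, 11, 13, 15]
    assert seq.final_state == DiseaseState.MOF


def test_panel_early_discharge():
    states = [DiseaseState.AT_RISK]
    seq = build_panel("a", states, None, AdmissionOutcome("discharged_alive", 2))
    assert seq.observation_days == [1, 2]
    assert seq.states == [DiseaseState.AT_RISK, DiseaseState.DISCHARGED]


def test_panel_absorbing_on_grid_snaps():
    states = [DiseaseState.LIMITED_OF] * 5
    seq = build_panel(
        "a", states, None, AdmissionOutcome("died", 6), absorbing_on_grid=True
    )
    assert seq.observation_days == [1, 3, 5, 7]


def test_panel_requires_day1_state():
    with pytest.raises(DataError, match="day-1"):
        build_panel("a", [], None, AdmissionOutcome("died", 6))


def test_panel_size_bounds(small_sims):
    for sim in small_sims:
        seq = build_panel(sim.admission_id, sim.daily_states, None, sim.outcome)
        transient = [s for s in seq.states if DiseaseState(s).is_transient]
        absorbing = [s for s in seq.states if DiseaseState(s).is_absorbing]
        assert len(transient) <= 8
        assert len(absorbing) <= 1
        assert seq.observation_days[0] == 1
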