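"""Cohort container, patient-day table I/O, admission preprocessing and
panel construction.

The canonical on-disk layout is three UTF-8 comma-separated tables:

* ``patient_days.csv`` -- one row per admission-day, columns as in
  :class:`~septraj.records.PatientDayRecord` (booleans as 1/0, missing
  values as empty cells);
* ``baseline.csv`` -- one row per admission with ``admission_id``,
  ``patient_id``, ``admit_calendar_day`` and the
  :class:`~septraj.records.BaselineCovariates` fields;
* ``outcomes.csv`` -- one row per admission with the terminal event.

A YAML mapping file may rename arbitrary source columns onto this schema.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import yaml

from .records import (
    GRID_DAYS,
    HORIZON_DAY,
    AdmissionOutcome,
    BaselineCovariates,
    PanelSequence,
    PatientDayRecord,
)
from .states import DiseaseState


class SchemaError(ValueError):
    """A required column is absent or misnamed."""


class DataError(ValueError):
    """The table contents violate cohort invariants."""


_BOOL_FIELDS = {
    f.name
    for f in dataclasses.fields(PatientDayRecord)
    if f.type == "Optional[bool]"
}
_BASE_BOOL_FIELDS = {
    f.name for f in dataclasses.fields(BaselineCovariates) if f.type == "bool"
}

#: Columns that must be present in a patient-day table.
REQUIRED_DAY_COLUMNS = tuple(PatientDayRecord.field_names())


@dataclass
class Admission:
    """All information for one (possibly merged) ICU admission."""

    admission_id: str
    patient_id: str
    records: list[PatientDayRecord]
    baseline: BaselineCovariates
    outcome: AdmissionOutcome
    admit_calendar_day: int = 0
    extras: dict = field(default_factory=dict)

    @property
    def discharge_calendar_day(self) -> int:
        return self.admit_calendar_day + self.outcome.event_day - 1

    def n_days(self) -> int:
        return len(self.records)


def _parse_bool(v) -> Optional[bool]:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    if isinstance(v, str):
        return v.strip().lower() in ("1", "true", "t", "yes")
    return bool(int(v))


def _records_from_frame(df: pd.DataFrame) -> list[PatientDayRecord]:
    recs = []
    names = set(PatientDayRecord.field_names())
    for row in df.itertuples(index=False):
        kw = {}
        for name, value in zip(df.columns, row):
            if name not in names:
                continue
            if name in _BOOL_FIELDS:
                kw[name] = _parse_bool(value)
            elif name in ("admission_id",):
                kw[name] = str(value)
            elif name == "day":
                kw[name] = int(value)
            else:
                kw[name] = float(value) if value not in ("", None) else np.nan
        recs.append(PatientDayRecord(**kw))
    return recs


def load_schema(path: str | Path) -> dict:
    """Read a YAML column-rename mapping {source_name: canonical_name}."""
    with open(path) as fh:
        schema = yaml.safe_load(fh) or {}
    if not isinstance(schema, dict):
        raise SchemaError("schema file must contain a mapping")
    return schema


def read_cohort(
    days_path: str | Path,
    baseline_path: str | Path,
    outcomes_path: str | Path,
    schema: Optional[dict] = None,
) -> list[Admission]:
    """Read the three canonical tables into :class:`Admission` objects.

    ``schema`` optionally renames source columns; unknown columns are
    preserved in ``Admission.extras['day_columns']``.  Raises
    :class:`SchemaError` for absent required columns and
    :class:`DataError` for duplicated (admission_id, day) rows.
    """
    days = pd.read_csv(days_path, float_precision="round_trip")
    base = pd.read_csv(baseline_path, float_precision="round_trip")
    outc = pd.read_csv(outcomes_path, float_precision="round_trip")
    if schema:
        days = days.rename(columns=schema)
        base = base.rename(columns=schema)
        outc = outc.rename(columns=schema)

    for col in REQUIRED_DAY_COLUMNS:
        if col not in days.columns:
            raise SchemaError(f"patient-day table is missing column {col!r}")
    for col in ("admission_id", "terminal_event", "event_day"):
        if col not in outc.columns:
            raise SchemaError(f"outcome table is missing column {col!r}")

    if days.duplicated(subset=["admission_id", "day"]).any():
        dup = days[days.duplicated(subset=["admission_id", "day"], keep=False)]
        key = dup.iloc[0]
        raise DataError(
            f"duplicate (admission_id, day) = ({key['admission_id']}, {key['day']})"
        )

    extra_cols = [c for c in days.columns if c not in REQUIRED_DAY_COLUMNS]
    base = base.set_index(base["admission_id"].astype(str))
    outc = outc.set_index(outc["admission_id"].astype(str))

    admissions = []
    for aid, group in days.groupby(days["admission_id"].astype(str), sort=True):
        group = group.sort_values("day")
        brow = base.loc[aid]
        orow = outc.loc[aid]
        baseline = BaselineCovariates(
            age=float(brow["age"]),
            sex=str(brow["sex"]),
            bmi=float(brow["bmi"]),
            **{
                name: bool(_parse_bool(brow[name]))
                for name in _BASE_BOOL_FIELDS
                if name in brow.index
            },
            infection_site=str(brow.get("infection_site", "pulmonary")),
            admission_type=str(brow.get("admission_type", "medical")),
        )
        pall = orow.get("palliative_start_day")
        outcome = AdmissionOutcome(
            terminal_event=str(orow["terminal_event"]),
            event_day=int(orow["event_day"]),
            palliative_start_day=None if pd.isna(pall) else int(pall),
        )
        admissions.append(
            Admission(
                admission_id=aid,
                patient_id=str(brow.get("patient_id", aid)),
                records=_records_from_frame(group),
                baseline=baseline,
                outcome=outcome,
                admit_calendar_day=int(brow.get("admit_calendar_day", 0)),
                extras={"day_columns": group[extra_cols].reset_index(drop=True)}
                if extra_cols
                else {},
            )
        )
    return admissions


def days_frame(admissions: Iterable[Admission]) -> pd.DataFrame:
    """Flatten admissions back into the canonical patient-day table."""
    rows = []
    for adm in admissions:
        for rec in adm.records:
            d = dataclasses.asdict(rec)
            for name in _BOOL_FIELDS:
                v = d[name]
                d[name] = "" if v is None else int(v)
            rows.append(d)
    return pd.DataFrame(rows, columns=PatientDayRecord.field_names())


def write_cohort(
    admissions: Iterable[Admission],
    days_path: str | Path,
    baseline_path: str | Path,
    outcomes_path: str | Path,
) -> None:
    admissions = list(admissions)
    days_frame(admissions).to_csv(days_path, index=False, float_format="%.17g")
    brows, orows = [], []
    for adm in admissions:
        b = dataclasses.asdict(adm.baseline)
        for name in _BASE_BOOL_FIELDS:
            b[name] = int(b[name])
        b["admission_id"] = adm.admission_id
        b["patient_id"] = adm.patient_id
        b["admit_calendar_day"] = adm.admit_calendar_day
        brows.append(b)
        o = dataclasses.asdict(adm.outcome)
        o["admission_id"] = adm.admission_id
        if o["palliative_start_day"] is None:
            o["palliative_start_day"] = ""
        orows.append(o)
    pd.DataFrame(brows).to_csv(baseline_path, index=False, float_format="%.17g")
    pd.DataFrame(orows).to_csv(outcomes_path, index=False, float_format="%.17g")


def merge_readmissions(
    admissions: list[Admission], gap_days: int = 1
) -> list[Admission]:
    """Merge readmissions occurring within 24 h of ICU discharge.

    Time resolution is whole calendar days, so the 24-h rule reads
    "readmitted on the same or next calendar day" (``gap_days=1``).
    Merged stays get continuous day numbering and take the later
    admission's outcome.  Idempotent; raises :class:`DataError` on
    overlapping stays of one patient.
    """
    by_patient: dict[str, list[Admission]] = {}
    for adm in admissions:
        by_patient.setdefault(adm.patient_id, []).append(adm)

    merged: list[Admission] = []
    for pid, stays in by_patient.items():
        stays = sorted(stays, key=lambda a: a.admit_calendar_day)
        current = stays[0]
        for nxt in stays[1:]:
            gap = nxt.admit_calendar_day - current.discharge_calendar_day
            if gap < 0:
                raise DataError(f"overlapping ICU stays for patient {pid}")
            if gap <= gap_days:
                offset = current.outcome.event_day
                new_records = list(current.records)
                for rec in nxt.records:
                    new_records.append(
                        dataclasses.replace(
                            rec,
                            admission_id=current.admission_id,
                            day=offset + rec.day,
                        )
                    )
                pall = nxt.outcome.palliative_start_day
                current = Admission(
                    admission_id=current.admission_id,
                    patient_id=pid,
                    records=new_records,
                    baseline=current.baseline,
                    outcome=AdmissionOutcome(
                        terminal_event=nxt.outcome.terminal_event,
                        event_day=offset + nxt.outcome.event_day,
                        palliative_start_day=None if pall is None else offset + pall,
                    ),
                    admit_calendar_day=current.admit_calendar_day,
                    extras=current.extras,
                )
            else:
                merged.append(current)
                current = nxt
        merged.append(current)
    merged.sort(key=lambda a: a.admission_id)
    return merged


def apply_palliative_censoring(
    sequence: PanelSequence, outcome: AdmissionOutcome
) -> PanelSequence:
    """Censor observation time after start of end-of-life care.

    Only admissions *discharged alive* after a palliative decision are
    censored: observations beyond ``palliative_start_day`` (including
    the discharge itself) are dropped and ``censored_from`` is set.
    Days up to that point remain usable for fitting; deaths are kept.
    """
    pall = outcome.palliative_start_day
    if pall is None or outcome.terminal_event != "discharged_alive":
        return sequence
    keep = [k for k, d in enumerate(sequence.observation_days) if d <= pall]
    return PanelSequence(
        admission_id=sequence.admission_id,
        observation_days=[sequence.observation_days[k] for k in keep],
        states=[sequence.states[k] for k in keep],
        covariates=[sequence.covariates[k] for k in keep]
        if sequence.covariates
        else [],
        censored_from=pall,
    )


def build_panel(
    admission_id: str,
    daily_states: list[DiseaseState],
    daily_covariates: Optional[list[dict]],
    outcome: AdmissionOutcome,
    horizon_day: int = HORIZON_DAY,
    absorbing_on_grid: bool = False,
) -> PanelSequence:
    """Sample daily stages onto the 2-day grid (days 1, 3, ..., 15).

    ``daily_states[d-1]`` is the transient stage on ICU day ``d``.  An
    absorbing event before the horizon is recorded at its exact day
    (discharge and death days are completely observed); with
    ``absorbing_on_grid`` it is snapped to the next grid day instead.
    Admissions still in ICU at the horizon end with their day-15 stage
    and are treated as right-censored there.
    """
    if not daily_states:
        raise DataError(f"admission {admission_id}: no day-1 state")
    absorbing: Optional[DiseaseState] = None
    if outcome.terminal_event == "died":
        absorbing = DiseaseState.DEAD
    elif outcome.terminal_event == "discharged_alive":
        absorbing = DiseaseState.DISCHARGED

    event_day = outcome.event_day
    has_event = absorbing is not None and event_day <= horizon_day

    grid = [d for d in GRID_DAYS if d <= horizon_day]
    last_transient_day = min(
        len(daily_states),
        (event_day - 1) if has_event else horizon_day,
    )
    days = [d for d in grid if d <= last_transient_day]
    if not days:
        raise DataError(
            f"admission {admission_id}: no transient observation at day 1"
        )
    states = [DiseaseState(daily_states[d - 1]) for d in days]
    covs = [daily_covariates[d - 1] for d in days] if daily_covariates else []

    if has_event:
        obs_day = event_day
        if absorbing_on_grid:
            obs_day = next(d for d in grid if d >= min(event_day, horizon_day))
        days.append(obs_day)
        states.append(absorbing)
        if covs:
            covs.append(covs[-1])  # align to last grid observation before event
    return PanelSequence(
        admission_id=admission_id,
        observation_days=days,
        states=states,
        covariates=covs,
    )
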