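"""Synthetic ICU sepsis cohort generator.

Emulates the derivation cohort's study conditions: ~1371 admissions
staged on admission as 4% at risk / 84% limited organ failure / 12%
multiple-organ failure, continuous-time state trajectories over the
first 15 ICU days driven by epoch- and covariate-dependent intensities,
time-varying response markers (CRP, WBC, fever, new-onset atrial
fibrillation, ICU-acquired infection, bacteremia, corticosteroids),
~17% missingness in daily labs, and rare palliative-care censoring
(~0.8% of admissions discharged alive under end-of-life care).

The generator and the estimator share the same log-linear intensity
form, so parameter recovery is well-posed.  Baseline intensities were
chosen so that the marginal 14-day outcome mix matches the cohort's
published flow fractions (e.g. 40% of MOF admissions dead by day 14);
each transition's baseline is compensated for the average covariate
multiplier so those marginals survive the covariate effects.

Latent daily stages are exported alongside the emitted raw records, and
emission is constructed so that staging the records reproduces the
latent stage exactly (the round-trip invariant).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cohort import Admission, build_panel
from .records import (
    HORIZON_DAY,
    AdmissionOutcome,
    BaselineCovariates,
    PanelSequence,
    PatientDayRecord,
)
from .states import DiseaseState, TransitionStructure
from .multistate import IntensityModel, validate_generator

# ---------------------------------------------------------------------------
# default truth

#: Baseline per-day intensities for a covariate-average patient,
#: calibrated so the marginal 14-day flows match the cohort's published
#: fractions (admission mix 4/84/12%; of limited-OF starters 17% worse /
#: 70% better; of MOF starters 40% dead / 54% better by day 14).
_BASE_RATES = {
    (1, 2): 0.10,
    (1, 4): 0.12,
    (2, 1): 0.04,
    (2, 3): 0.028,
    (2, 4): 0.088,
    (2, 5): 0.017,
    (3, 2): 0.16,
    (3, 5): 0.080,
}
#: Epoch multipliers: acute deterioration dominates early, recovery and
#: discharge later.  Epochs are ICU-day pieces [1,3), [3,7), [7,15].
_EPOCH_MULT = [
    {(1, 2): 1.3, (2, 3): 1.4, (3, 5): 1.3},
    {},
    {(2, 1): 1.2, (2, 4): 1.2, (2, 3): 0.7, (3, 5): 0.8},
]

#: Design covariates of the true model. ``gauss`` entries are standard
#: normal on the design scale; ``bern`` entries carry their prevalence.
COVARIATE_KINDS: dict[str, tuple[str, float]] = {
    "age_std": ("gauss", 1.0),
    "bmi_std": ("gauss", 1.0),
    "immunodeficiency": ("bern", 0.28),
    "renal_insufficiency": ("bern", 0.16),
    "respiratory_insufficiency": ("bern", 0.15),
    "site_abdominal": ("bern", 0.11),
    "site_urinary": ("bern", 0.06),
    "site_other": ("bern", 0.26),
    "log_crp_std": ("gauss", 1.0),
    "wbc_std": ("gauss", 1.0),
    # prevalences are the stationary values of the persistence processes
    "fever": ("bern", 0.33),
    "new_onset_af": ("bern", 0.06),
    "icu_acquired_infection": ("bern", 0.09),
    "bacteremia": ("bern", 0.11),
    "corticosteroids": ("bern", 0.20),
    # covariates with no true effect (screened out downstream)
    "sex_male": ("bern", 0.61),
    "cardiovascular_disease": ("bern", 0.27),
    "diabetes": ("bern", 0.19),
    "hospital_acquired": ("bern", 0.44),
}

NULL_COVARIATES = ("sex_male", "cardiovascular_disease", "diabetes",
                   "hospital_acquired")

#: True log hazard-ratio effects, per covariate per transition.
TRUE_EFFECTS: dict[str, dict[tuple[int, int], float]] = {
    "age_std": {(2, 5): 0.35, (3, 5): 0.30, (2, 4): -0.15},
    "bmi_std": {(2, 3): 0.15},
    "immunodeficiency": {(2, 3): 0.40, (2, 5): 0.30},
    "renal_insufficiency": {(2, 3): 0.30},
    "respiratory_insufficiency": {(2, 3): 0.25, (2, 4): -0.20},
    "site_abdominal": {(2, 3): 0.45},
    "site_urinary": {(2, 4): 0.30},
    "site_other": {(2, 5): 0.20},
    "log_crp_std": {(2, 3): 0.35, (3, 2): -0.25, (2, 4): -0.20},
    "wbc_std": {(2, 3): 0.20},
    "fever": {(2, 3): 0.25},
    "new_onset_af": {(2, 3): 0.50, (2, 5): 0.40},
    "icu_acquired_infection": {(2, 3): 0.60, (2, 4): -0.30},
    "bacteremia": {(2, 3): 0.35, (2, 5): 0.30},
    "corticosteroids": {(2, 5): 0.25},
}

#: Mean log-CRP by latent state (log mg/L), matching the published
#: admission medians (118 / 189 / 225 mg/L by stage).
_CRP_LOGMEAN = {1: np.log(118.0), 2: np.log(189.0), 3: np.log(225.0)}
_CRP_RHO, _CRP_SIGMA = 0.7, 0.40
_CRP_STD_CENTER, _CRP_STD_SCALE = 5.2, 0.6
_WBC_LOGMEAN = {1: np.log(11.0), 2: np.log(13.0), 3: np.log(14.0)}
_WBC_SIGMA = 0.35
_WBC_STD_CENTER, _WBC_STD_SCALE = 2.55, 0.4
#: Binary time-varying covariates follow two-state Markov processes:
#: state-linked daily onset probability plus a persistence probability,
#: because infections, arrhythmia and treatment courses last days rather
#: than resolving overnight.  Day-1 values are drawn at the stationary
#: prevalence onset/(onset + 1 - persist).
_BIN_PROCS: dict[str, tuple[dict[int, float], float]] = {
    "fever": ({1: 0.20, 2: 0.30, 3: 0.40}, 0.40),
    "new_onset_af": ({1: 0.015, 2: 0.03, 3: 0.07}, 0.50),
    "icu_acquired_infection": ({1: 0.01, 2: 0.025, 3: 0.04}, 0.75),
    "bacteremia": ({1: 0.03, 2: 0.05, 3: 0.08}, 0.60),
    "corticosteroids": ({1: 0.02, 2: 0.03, 3: 0.04}, 0.88),
}


def default_true_model(
    covariate_names: Optional[Sequence[str]] = None,
    compensate: bool = True,
) -> IntensityModel:
    """The generator's default truth as an :class:`IntensityModel`.

    ``compensate`` subtracts each transition's expected covariate
    multiplier (log E[exp(beta.x)] under independent marginals) from its
    baseline so the population-average rates stay at the calibrated
    values.
    """
    structure = TransitionStructure()
    names = tuple(covariate_names if covariate_names is not None
                  else COVARIATE_KINDS)
    K = structure.n_transitions
    beta = np.zeros((K, len(names)))
    for c, name in enumerate(names):
        for pair, b in TRUE_EFFECTS.get(name, {}).items():
            beta[structure.index(*pair), c] = b

    log_base = np.empty((3, K))
    for k, pair in enumerate(structure.allowed):
        base = np.log(_BASE_RATES[pair])
        if compensate:
            comp = 0.0
            for c, name in enumerate(names):
                kind, par = COVARIATE_KINDS[name]
                b = beta[k, c]
                if b == 0.0:
                    continue
                if kind == "gauss":
                    comp += 0.5 * b * b
                else:
                    comp += np.log1p(par * (np.exp(b) - 1.0))
            base -= comp
        for e in range(3):
            log_base[e, k] = base + np.log(_EPOCH_MULT[e].get(pair, 1.0))
    return IntensityModel(
        structure=structure,
        epochs=(1.0, 3.0, 7.0),
        log_baseline=log_base,
        beta=beta,
        covariate_names=names,
    )


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions."""

    n_admissions: int = 1371
    seed: int = 0
    initial_state_probs: tuple[float, float, float] = (0.04, 0.84, 0.12)
    true_model: Optional[IntensityModel] = None
    missingness_rate: float = 0.17
    palliative_prob: float = 0.008
    horizon_day: int = HORIZON_DAY

    def __post_init__(self) -> None:
        p = np.asarray(self.initial_state_probs, float)
        if (p < 0).any() or (p > 1).any() or abs(p.sum() - 1) > 1e-9:
            raise ValueError("initial_state_probs must be a probability vector")
        if self.n_admissions < 1:
            raise ValueError("n_admissions must be >= 1")
        if not (0 <= self.missingness_rate < 1):
            raise ValueError("missingness_rate must be in [0, 1)")
        if self.true_model is None:
            self.true_model = default_true_model()
        for e in range(self.true_model.n_epochs):
            validate_generator(
                self.true_model.generator(e), self.true_model.structure
            )


@dataclass
class SimulatedAdmission:
    """Ground truth for one simulated admission."""

    admission_id: str
    baseline: BaselineCovariates
    daily_states: list[DiseaseState]     # transient stage on days 1..last
    daily_covariates: list[dict]         # design covariates per day
    outcome: AdmissionOutcome


def _draw_baseline(rng: np.random.Generator) -> tuple[BaselineCovariates, dict]:
    site = rng.choice(
        ["pulmonary", "abdominal", "urinary", "other"], p=[0.57, 0.11, 0.06, 0.26]
    )
    base = BaselineCovariates(
        age=float(np.clip(rng.normal(62, 14), 18, 95)),
        sex="male" if rng.random() < 0.61 else "female",
        bmi=float(np.clip(rng.normal(26, 5), 15, 50)),
        immunodeficiency=bool(rng.random() < 0.28),
        cardiovascular_disease=bool(rng.random() < 0.27),
        respiratory_insufficiency=bool(rng.random() < 0.15),
        renal_insufficiency=bool(rng.random() < 0.16),
        diabetes=bool(rng.random() < 0.19),
        corticosteroid_use_baseline=bool(rng.random() < 0.10),
        infection_site=str(site),
        hospital_acquired=bool(rng.random() < 0.44),
        admission_type="medical" if rng.random() < 0.74 else "surgical",
    )
    design = {
        "age_std": (base.age - 62.0) / 14.0,
        "bmi_std": (base.bmi - 26.0) / 5.0,
        "immunodeficiency": float(base.immunodeficiency),
        "renal_insufficiency": float(base.renal_insufficiency),
        "respiratory_insufficiency": float(base.respiratory_insufficiency),
        "site_abdominal": float(site == "abdominal"),
        "site_urinary": float(site == "urinary"),
        "site_other": float(site == "other"),
        "sex_male": float(base.sex == "male"),
        "cardiovascular_disease": float(base.cardiovascular_disease),
        "diabetes": float(base.diabetes),
        "hospital_acquired": float(base.hospital_acquired),
    }
    return base, design


def _daily_response(
    rng: np.random.Generator, state: int, prev: Optional[dict]
) -> dict:
    """Time-varying covariates for one day, state-linked."""
    mu = _CRP_LOGMEAN[state]
    if prev is None:
        log_crp = rng.normal(mu, _CRP_SIGMA / np.sqrt(1 - _CRP_RHO**2))
    else:
        log_crp = mu + _CRP_RHO * (prev["_log_crp"] - prev["_crp_mu"]) + rng.normal(
            0, _CRP_SIGMA
        )
    log_wbc = rng.normal(_WBC_LOGMEAN[state], _WBC_SIGMA)
    out = {
        "_log_crp": log_crp,
        "_crp_mu": mu,
        "log_crp_std": (log_crp - _CRP_STD_CENTER) / _CRP_STD_SCALE,
        "wbc_std": (log_wbc - _WBC_STD_CENTER) / _WBC_STD_SCALE,
    }
    for name, (onset, persist) in _BIN_PROCS.items():
        if prev is None:
            p = onset[state] / (onset[state] + 1.0 - persist)
        elif prev[name]:
            p = persist
        else:
            p = onset[state]
        out[name] = float(rng.random() < p)
    return out


def simulate_trajectories(config: SimulationConfig) -> list[SimulatedAdmission]:
    """Simulate latent daily disease states and covariate paths.

    Within each ICU day the chain evolves by competing exponential
    clocks under the day's covariate-updated generator; the latent
    daily stage is the state occupied at the start of the day.  An
    absorption during day interval (d, d+1] is recorded at day d+1.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    model = config.true_model
    structure = model.structure
    sims: list[SimulatedAdmission] = []
    init_states = rng.choice(
        [1, 2, 3], size=config.n_admissions, p=config.initial_state_probs
    )
    exits: dict[int, list[tuple[int, int]]] = {}
    for i, j in structure.allowed:
        exits.setdefault(i, []).append((j, structure.index(i, j)))

    for n in range(config.n_admissions):
        base, design = _draw_baseline(rng)
        s = int(init_states[n])
        states: list[DiseaseState] = []
        covs: list[dict] = []
        resp: Optional[dict] = None
        outcome: Optional[AdmissionOutcome] = None
        day = 1
        while day <= config.horizon_day:
            resp = _daily_response(rng, s, resp)
            cov = {**design, **{k: v for k, v in resp.items() if not k.startswith("_")}}
            cov["_log_crp"], cov["_crp_mu"] = resp["_log_crp"], resp["_crp_mu"]
            states.append(DiseaseState(s))
            covs.append(cov)
            # evolve over (day, day+1]
            x = model.x_vector(cov)
            epoch = model.epoch_index(day)
            rates = model.rates(epoch, x)
            tau = float(day)
            while tau < day + 1:
                out = exits.get(s, [])
                lam = np.array([rates[k] for _, k in out])
                total = lam.sum()
                if total <= 0:
                    break
                step = rng.exponential(1.0 / total)
                if tau + step >= day + 1:
                    break
                tau += step
                s = out[int(rng.choice(len(out), p=lam / total))][0]
                if DiseaseState(s).is_absorbing:
                    outcome = AdmissionOutcome(
                        terminal_event="died"
                        if s == DiseaseState.DEAD
                        else "discharged_alive",
                        event_day=day + 1,
                    )
                    break
            if outcome is not None:
                break
            day += 1
        if outcome is None:
            outcome = AdmissionOutcome(
                terminal_event="in_icu_at_day15", event_day=config.horizon_day
            )
        if (
            outcome.terminal_event == "discharged_alive"
            and outcome.event_day > 2
            and rng.random() < config.palliative_prob
        ):
            outcome = dataclasses.replace(
                outcome,
                palliative_start_day=int(rng.integers(1, outcome.event_day)),
            )
        sims.append(
            SimulatedAdmission(
                admission_id=f"A{n:05d}",
                baseline=base,
                daily_states=states,
                daily_covariates=covs,
                outcome=outcome,
            )
        )
    return sims


# ---------------------------------------------------------------------------
# raw-record emission (inverse of the staging rules)

#: Severe dysfunction is emitted only through criteria that fire from a
#: single day's values; CNS and gut severe failure require > 24 h
#: persistence and are not used as emission targets.
_INSTANT_SEVERE = ("cardiovascular", "respiratory", "renal", "coagulation", "liver")
_ALL_ORGANS = ("cns", "cardiovascular", "respiratory", "renal", "coagulation",
               "liver", "gastrointestinal")


def _healthy_record_kwargs(aid: str, day: int) -> dict:
    return dict(
        admission_id=aid, day=day,
        cam_icu_positive=False, continuous_sedation=False, coma_hours_past24h=0.0,
        sbp_lt90_hours=0.0, vasopressor_any=False, norepi_rate=0.0,
        high_dose_pressor_hours=0.0, vasopressin=False, lactate=1.2,
        fluid_balance_24h=0.5, inotrope_any=False,
        mech_vent=False, pf_ratio=400.0, peep=0.0,
        urine_6h_lt_0_5mlkgh=False, urine_24h_ml=2000.0,
        creatinine=80.0, creatinine_baseline=80.0, rrt=False,
        acute_creatinine_rise_gt44=False,
        platelets=250.0, inr=1.1, aptt=35.0,
        bilirubin=10.0, albumin=30.0, ast=40.0, alt=40.0,
        caloric_intake_pct=90.0, food_intolerance_hours=0.0,
        new_onset_af=False, bacteremia=False, icu_acquired_infection=False,
        corticosteroids=False,
    )


def _emit_moderate(organ: str, kw: dict, rng: np.random.Generator) -> None:
    if organ == "cns":
        if rng.random() < 0.6:
            kw["cam_icu_positive"] = True
        else:
            kw["continuous_sedation"] = True
    elif organ == "cardiovascular":
        arm = rng.integers(3)
        if arm == 0:
            kw["sbp_lt90_hours"] = float(rng.uniform(2.5, 8))
        elif arm == 1:
            kw["vasopressor_any"] = True
            kw["norepi_rate"] = float(rng.uniform(0.02, 0.08))
        else:
            kw["fluid_balance_24h"] = float(rng.uniform(2.2, 4))
    elif organ == "respiratory":
        kw["mech_vent"] = True
        kw["pf_ratio"] = float(rng.uniform(210, 290))
        kw["peep"] = float(rng.uniform(5.5, 8))
    elif organ == "renal":
        if rng.random() < 0.5:
            kw["creatinine"] = float(kw["creatinine_baseline"] * rng.uniform(1.6, 2.8))
        else:
            kw["urine_6h_lt_0_5mlkgh"] = True
    elif organ == "coagulation":
        arm = rng.integers(3)
        if arm == 0:
            kw["platelets"] = float(rng.uniform(55, 95))
        elif arm == 1:
            kw["inr"] = float(rng.uniform(1.6, 2.5))
        else:
            kw["aptt"] = float(rng.uniform(65, 90))
    elif organ == "liver":
        arm = rng.integers(3)
        if arm == 0:
            kw["bilirubin"] = float(rng.uniform(35, 90))
        elif arm == 1:
            kw["albumin"] = float(rng.uniform(15.5, 19))
        else:
            kw["ast"] = float(rng.uniform(550, 900))
    elif organ == "gastrointestinal":
        kw["caloric_intake_pct"] = float(rng.uniform(10, 45))


def _emit_severe(organ: str, kw: dict, rng: np.random.Generator) -> None:
    if organ == "cardiovascular":
        kw["vasopressor_any"] = True
        kw["norepi_rate"] = float(rng.uniform(0.12, 0.4))
        kw["high_dose_pressor_hours"] = float(rng.uniform(13, 20))
        kw["fluid_balance_24h"] = float(rng.uniform(2.5, 5))
        kw["lactate"] = float(rng.uniform(2.5, 8))
    elif organ == "respiratory":
        kw["mech_vent"] = True
        kw["pf_ratio"] = float(rng.uniform(80, 190))
        kw["peep"] = float(rng.uniform(9, 14))
    elif organ == "renal":
        if rng.random() < 0.5:
            kw["rrt"] = True
        else:
            kw["creatinine"] = float(kw["creatinine_baseline"] * rng.uniform(3.2, 5))
    elif organ == "coagulation":
        kw["platelets"] = float(rng.uniform(10, 45))
    elif organ == "liver":
        if rng.random() < 0.6:
            kw["bilirubin"] = float(rng.uniform(110, 250))
        else:
            kw["ast"] = float(rng.uniform(1100, 2000))


def _organ_targets(
    state: DiseaseState, rng: np.random.Generator
) -> tuple[list[str], list[str]]:
    """Draw (severe organs, moderate organs) compatible with a stage."""
    if state == DiseaseState.AT_RISK:
        n_sev, n_mod = 0, int(rng.integers(0, 3))
    elif state == DiseaseState.LIMITED_OF:
        if rng.random() < 0.75:
            n_sev = int(rng.integers(1, 3))
            n_mod = int(rng.integers(0, 4))
        else:
            n_sev, n_mod = 0, int(rng.integers(3, 5))
    else:  # MOF
        n_sev = int(rng.integers(3, 5))
        n_mod = int(rng.integers(0, 3))
    severe = list(rng.choice(_INSTANT_SEVERE, size=n_sev, replace=False))
    rest = [o for o in _ALL_ORGANS if o not in severe]
    moderate = list(rng.choice(rest, size=min(n_mod, len(rest)), replace=False))
    return severe, moderate


def emit_daily_records(
    sim: SimulatedAdmission, rng: np.random.Generator
) -> list[PatientDayRecord]:
    """Emit raw patient-day records whose staging equals the latent path.

    For each day, organ dysfunction levels compatible with the latent
    stage are drawn, then raw values are written that fire exactly those
    criteria.  Response covariates (CRP, temperature, ...) are written
    from the simulated covariate path.
    """
    records = []
    for day, (state, cov) in enumerate(
        zip(sim.daily_states, sim.daily_covariates), start=1
    ):
        kw = _healthy_record_kwargs(sim.admission_id, day)
        severe, moderate = _organ_targets(state, rng)
        for organ in severe:
            _emit_severe(organ, kw, rng)
        for organ in moderate:
            _emit_moderate(organ, kw, rng)
        # systemic response markers from the covariate path
        kw["crp"] = float(np.exp(cov["_log_crp"]))
        kw["wbc"] = float(np.exp(cov["wbc_std"] * _WBC_STD_SCALE + _WBC_STD_CENTER))
        kw["temperature"] = float(
            rng.uniform(38.4, 40.0) if cov["fever"] else rng.uniform(36.2, 38.0)
        )
        kw["resp_rate"] = float(np.clip(rng.normal(22 + 2 * (int(state) - 1), 4), 8, 60))
        kw["heart_rate"] = float(np.clip(rng.normal(95 + 5 * (int(state) - 1), 15), 40, 220))
        kw["new_onset_af"] = bool(cov["new_onset_af"])
        kw["bacteremia"] = bool(cov["bacteremia"])
        kw["icu_acquired_infection"] = bool(cov["icu_acquired_infection"])
        kw["corticosteroids"] = bool(cov["corticosteroids"])
        records.append(PatientDayRecord(**kw))
    return records


#: Daily lab/physiology fields eligible for missingness masking.
MASKABLE_FIELDS = (
    "lactate", "pf_ratio", "urine_24h_ml", "creatinine", "platelets", "inr",
    "aptt", "bilirubin", "albumin", "ast", "alt", "caloric_intake_pct",
    "crp", "wbc", "temperature", "resp_rate", "heart_rate",
)

#: Labs that are ordered sparingly in routine ICU care and therefore
#: dominate daily missingness (> 50% missing), as opposed to the
#: near-complete vital signs and standard chemistry.
HIGH_MISSING_FIELDS = ("aptt", "albumin", "alt", "ast", "lactate")


def apply_missingness(
    records: Sequence[PatientDayRecord],
    rate: float,
    rng: np.random.Generator,
    high_missing_fields: Sequence[str] = HIGH_MISSING_FIELDS,
) -> list[PatientDayRecord]:
    """Mask daily lab values completely at random.

    The per-variable profile is strongly skewed to match routine ICU
    documentation: a handful of sparingly-ordered labs carry most of the
    missingness (drawn around 45-75%) while the rest stay nearly
    complete (0.5-6%); all rates are then rescaled so their mean equals
    the overall ``rate``.  Outcome fields (state, discharge, death) are
    never masked.
    """
    if not (0 <= rate < 1):
        raise ValueError("rate must be in [0, 1)")
    if rate == 0 or not records:
        return list(records)
    raw = np.array(
        [
            rng.uniform(0.45, 0.75) if f in high_missing_fields
            else rng.uniform(0.005, 0.06)
            for f in MASKABLE_FIELDS
        ]
    )
    var_rates = np.clip(rate * raw / raw.mean(), 0.0, 0.95)
    k = len(MASKABLE_FIELDS)
    out = []
    for rec in records:
        d = dataclasses.asdict(rec)
        mask = rng.random(k) < var_rates
        for name, m in zip(MASKABLE_FIELDS, mask):
            if m:
                d[name] = np.nan
        out.append(PatientDayRecord(**d))
    return out


# ---------------------------------------------------------------------------
# convenience assembly


def panels_from_latent(
    sims: Sequence[SimulatedAdmission], horizon_day: int = HORIZON_DAY
) -> list[PanelSequence]:
    """Panel sequences straight from the latent daily stages."""
    panels = []
    for sim in sims:
        covs = [
            {k: v for k, v in c.items() if not k.startswith("_")}
            for c in sim.daily_covariates
        ]
        panels.append(
            build_panel(sim.admission_id, sim.daily_states, covs, sim.outcome,
                        horizon_day=horizon_day)
        )
    return panels


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[SimulatedAdmission], list[Admission]]:
    """Full generator: latent truth plus emitted raw admissions.

    The emitted records carry the configured missingness; the latent
    paths are returned untouched for ground-truth checks.
    """
    sims = simulate_trajectories(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    admissions = []
    for n, sim in enumerate(sims):
        records = emit_daily_records(sim, rng)
        if config.missingness_rate > 0:
            records = apply_missingness(records, config.missingness_rate, rng)
        admissions.append(
            Admission(
                admission_id=sim.admission_id,
                patient_id=f"P{n:05d}",
                records=records,
                baseline=sim.baseline,
                outcome=sim.outcome,
            )
        )
    return sims, admissions
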