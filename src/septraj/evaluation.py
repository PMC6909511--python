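"""Discrimination and accuracy of occupation-probability forecasts.

Two metrics are computed from predicted occupation probabilities:

* A multi-state concordance statistic: for every ordered state pair
  (i, j) and evaluation time, the fraction of patients observed in
  state i whose predicted probability of i exceeds their predicted
  probability of j (ties count one half).  The two directions of a
  pair are averaged, and the overall c is the mean over pairs and
  times -- including never-co-occurring pairs such as discharge versus
  death.  Patient-level bootstrap gives the confidence interval.

* A multi-category Brier score: mean squared distance between the
  5-state forecast vector and the one-hot observed state, averaged
  over patients and times; proper, lower is better.

``compare_models`` contrasts a baseline-information-only model with one
that is updated every grid day with time-varying information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .multistate import FitResult, IntensityModel, occupation_probs, transition_matrix
from .records import GRID_DAYS, PanelSequence
from .states import DiseaseState

DEFAULT_EVAL_TIMES = (3, 5, 7, 9, 11, 13, 15)
N_STATES = 5


@dataclass
class CStatReport:
    overall: float
    ci_lower: float
    ci_upper: float
    per_pair: dict[tuple[int, int], float]
    per_time: dict[float, float]
    n_patients: int
    n_bootstrap: int
    seed: int
    excluded_states: list[int] = field(default_factory=list)


@dataclass
class BrierReport:
    brier_baseline: float
    brier_dynamic: float

    @property
    def relative_reduction(self) -> float:
        return (self.brier_baseline - self.brier_dynamic) / self.brier_baseline


def _pair_time_scores(
    predictions: np.ndarray, observed: np.ndarray
) -> dict[tuple[int, int, int], float]:
    """Directional fraction P(i) > P(j) among occupants of i, keyed by
    (time index, i, j); absent key = no occupants of i at that time."""
    n, T, S = predictions.shape
    out: dict[tuple[int, int, int], float] = {}
    for t in range(T):
        obs_t = observed[:, t]
        for i in range(1, S + 1):
            rows = np.where(obs_t == i)[0]
            if len(rows) == 0:
                continue
            pi = predictions[rows, t, i - 1]
            for j in range(1, S + 1):
                if j == i:
                    continue
                pj = predictions[rows, t, j - 1]
                wins = (pi > pj).sum() + 0.5 * (pi == pj).sum()
                out[(t, i, j)] = wins / len(rows)
    return out


def _overall_from_scores(
    scores: dict[tuple[int, int, int], float], T: int
) -> tuple[float, dict[tuple[int, int], float], dict[int, float]]:
    pair_vals: dict[tuple[int, int], list[float]] = {}
    time_vals: dict[int, list[float]] = {}
    for t in range(T):
        for i in range(1, N_STATES + 1):
            for j in range(i + 1, N_STATES + 1):
                d1 = scores.get((t, i, j))
                d2 = scores.get((t, j, i))
                vals = [v for v in (d1, d2) if v is not None]
                if not vals:
                    continue
                v = float(np.mean(vals))
                pair_vals.setdefault((i, j), []).append(v)
                time_vals.setdefault(t, []).append(v)
    per_pair = {k: float(np.mean(v)) for k, v in pair_vals.items()}
    per_time = {t: float(np.mean(v)) for t, v in time_vals.items()}
    allv = [v for vs in pair_vals.values() for v in vs]
    overall = float(np.mean(allv)) if allv else np.nan
    return overall, per_pair, per_time


def multistate_cstat(
    predictions: np.ndarray,
    observed: np.ndarray,
    eval_times: Sequence[float] = DEFAULT_EVAL_TIMES,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> CStatReport:
    """Multi-state concordance of occupation-probability forecasts.

    ``predictions``: (n_patients, n_times, 5) probability vectors;
    ``observed``: (n_patients, n_times) state codes 1..5, 0 where the
    state is unknown (censored).  States never occupied contribute no
    pairs and are reported in ``excluded_states``.
    """
    predictions = np.asarray(predictions, float)
    observed = np.asarray(observed, int)
    n, T, S = predictions.shape
    if S != N_STATES or observed.shape != (n, T):
        raise ValueError("predictions/observed shape mismatch")
    occupied = set(np.unique(observed[observed > 0]))
    excluded = sorted(set(range(1, S + 1)) - occupied)

    scores = _pair_time_scores(predictions, observed)
    overall, per_pair, per_time = _overall_from_scores(scores, T)

    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        s = _pair_time_scores(predictions[idx], observed[idx])
        boots.append(_overall_from_scores(s, T)[0])
    lo, hi = (
        (float(np.nanpercentile(boots, 2.5)), float(np.nanpercentile(boots, 97.5)))
        if boots
        else (np.nan, np.nan)
    )
    return CStatReport(
        overall=overall,
        ci_lower=lo,
        ci_upper=hi,
        per_pair=per_pair,
        per_time={float(eval_times[t]): v for t, v in per_time.items()},
        n_patients=n,
        n_bootstrap=n_bootstrap,
        seed=seed,
        excluded_states=excluded,
    )


def multistate_brier(predictions: np.ndarray, observed: np.ndarray) -> float:
    """Mean squared distance between forecasts and one-hot outcomes.

    Unknown observations (code 0) are excluded.  A uniform 1/5 forecast
    scores 0.8 per patient-time on the 5-state space.
    """
    predictions = np.asarray(predictions, float)
    observed = np.asarray(observed, int)
    mask = observed > 0
    if not mask.any():
        return np.nan
    onehot = np.zeros_like(predictions)
    rows, times = np.where(mask)
    onehot[rows, times, observed[mask] - 1] = 1.0
    sq = ((predictions - onehot) ** 2).sum(axis=2)
    return float(sq[mask].mean())


# ---------------------------------------------------------------------------
# building forecasts from a fitted model


def observed_state_matrix(
    panels: Sequence[PanelSequence], eval_times: Sequence[float] = DEFAULT_EVAL_TIMES
) -> np.ndarray:
    """Observed state of each patient at each evaluation time.

    Absorbing states persist after their event day; 0 marks times where
    the state is unknown (after censoring or beyond follow-up).
    """
    out = np.zeros((len(panels), len(eval_times)), int)
    for p, seq in enumerate(panels):
        days = np.asarray(seq.observation_days, float)
        states = [int(s) for s in seq.states]
        final = seq.final_state
        for t_idx, t in enumerate(eval_times):
            if seq.censored_from is not None and t > seq.censored_from:
                continue
            if final.is_absorbing and t >= days[-1]:
                out[p, t_idx] = int(final)
                continue
            before = np.where(days <= t)[0]
            if len(before) and days[before[-1]] == t:
                out[p, t_idx] = states[before[-1]]
            # state between grid days or beyond follow-up: unknown
    return out


def predict_matrix(
    model_or_fit,
    panels: Sequence[PanelSequence],
    eval_times: Sequence[float] = DEFAULT_EVAL_TIMES,
    dynamic: bool = False,
    covariate_overrides: Optional[dict] = None,
) -> np.ndarray:
    """Occupation-probability forecasts for every patient and time.

    Static mode predicts every time from the day-1 state and
    covariates.  Dynamic mode re-predicts each evaluation time from the
    patient's most recent *transient* observation before it, carrying
    that observation's covariates forward.
    """
    model: IntensityModel = getattr(model_or_fit, "model", model_or_fit)
    preds = np.zeros((len(panels), len(eval_times), N_STATES))
    for p, seq in enumerate(panels):
        days = seq.observation_days
        covs = seq.covariates or [{}] * len(days)
        transient_idx = [
            k for k, s in enumerate(seq.states) if DiseaseState(s).is_transient
        ]
        for t_idx, t in enumerate(eval_times):
            if dynamic:
                cands = [k for k in transient_idx if days[k] < t]
                k = cands[-1] if cands else 0
            else:
                k = 0
            cov = dict(covs[k])
            if covariate_overrides:
                cov.update(covariate_overrides)
            surf = occupation_probs(
                model, DiseaseState(seq.states[k]), float(days[k]), cov, horizon=t
            )
            preds[p, t_idx] = surf.at(t)
    return preds


def per_transition_cstat(
    model_or_fit,
    panels: Sequence[PanelSequence],
) -> dict[str, float]:
    """Concordance of predicted 2-day transition probabilities.

    For each allowed transition i->j, pools every grid step where a
    patient sat in state i, scoring the predicted probability of being
    in j at the next grid day against the indicator of that move.
    Transitions without both an event and a non-event are undefined
    (nan).
    """
    model: IntensityModel = getattr(model_or_fit, "model", model_or_fit)
    probs: dict[tuple[int, int], list[float]] = {
        pair: [] for pair in model.structure.allowed
    }
    events: dict[tuple[int, int], list[int]] = {
        pair: [] for pair in model.structure.allowed
    }
    # evaluate on the regular 2-day grid so every comparison uses the
    # same horizon; destination states come from the occupation rule
    # (absorbing states persist past their event day)
    grid = list(GRID_DAYS)
    obs = observed_state_matrix(panels, grid)
    for p, seq in enumerate(panels):
        day_index = {d: k for k, d in enumerate(seq.observation_days)}
        for g in range(len(grid) - 1):
            t0, t1 = grid[g], grid[g + 1]
            s0 = obs[p, g]
            s1 = obs[p, g + 1]
            if s0 not in (1, 2, 3) or s1 == 0:
                continue
            cov = {}
            if seq.covariates and t0 in day_index:
                cov = seq.covariates[day_index[t0]]
            P = transition_matrix(model, model.x_vector(cov), t0, t1)
            for pair in model.structure.allowed:
                if pair[0] != s0:
                    continue
                probs[pair].append(P[pair[0] - 1, pair[1] - 1])
                events[pair].append(int(s1 == pair[1]))
    out = {}
    for pair in model.structure.allowed:
        y = np.asarray(events[pair])
        x = np.asarray(probs[pair])
        if len(y) == 0 or y.min() == y.max():
            out[f"{pair[0]}->{pair[1]}"] = np.nan
            continue
        out[f"{pair[0]}->{pair[1]}"] = _auc(x, y)
    return out


def _auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based concordance (ties handled as one half)."""
    from scipy.stats import rankdata

    r = rankdata(scores)
    n1 = labels.sum()
    n0 = len(labels) - n1
    u = r[labels == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def compare_models(
    fit_baseline: FitResult | IntensityModel,
    fit_dynamic: FitResult | IntensityModel,
    panels: Sequence[PanelSequence],
    eval_times: Sequence[float] = DEFAULT_EVAL_TIMES,
) -> BrierReport:
    """Brier-score comparison of baseline-only vs dynamic predictions.

    The baseline model predicts every horizon from day-1 information;
    the dynamic model is re-applied at each grid day with the current
    state and time-varying covariates.  A negative reduction (dynamic
    worse) is possible and reported as such.
    """
    observed = observed_state_matrix(panels, eval_times)
    pb = predict_matrix(fit_baseline, panels, eval_times, dynamic=False)
    pd_ = predict_matrix(fit_dynamic, panels, eval_times, dynamic=True)
    return BrierReport(
        brier_baseline=multistate_brier(pb, observed),
        brier_dynamic=multistate_brier(pd_, observed),
    )
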