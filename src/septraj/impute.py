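"""Missing-data handling for daily ICU variables.

Two stages, mirroring routine practice for longitudinal ICU labs:

1. *Trend imputation* fills short gaps (<= 2 days) in each patient's
   daily series by extrapolating the last observed trend, because
   consecutive ICU lab values are strongly autocorrelated.  Longer runs
   and leading gaps stay missing.
2. *Multiple imputation* by chained equations completes what remains,
   drawing from approximate posterior predictive distributions
   (Bayesian linear regression for continuous variables, logistic
   draws for binaries), producing ``m`` completed datasets whose
   between-dataset spread propagates imputation uncertainty.

Per-dataset model fits are combined with Rubin's rules.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import Admission, days_frame
from .simulate import MASKABLE_FIELDS


@dataclass
class ImputationReport:
    fraction_missing_before: float
    fraction_missing_after_trend: float
    m: int
    seed: int

    def __post_init__(self) -> None:
        if self.fraction_missing_after_trend > self.fraction_missing_before + 1e-12:
            raise ValueError("trend imputation cannot increase missingness")
        if self.m < 1:
            raise ValueError("m must be >= 1")


def trend_impute(
    series: Sequence[float],
    max_gap_days: int = 2,
    mode: str = "linear",
    floor: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fill short gaps in one daily series; returns (filled, imputed mask).

    A missing run immediately following >= 2 observed values is filled
    for at most ``max_gap_days`` days by linear extrapolation of the
    last two *observed* points (clamped at ``floor``); after a single
    observed value the last observation is carried forward instead.
    ``mode='locf'`` always carries forward.  Observed entries are never
    altered; leading gaps stay missing.
    """
    if mode not in ("linear", "locf"):
        raise ValueError(f"unknown trend mode {mode!r}")
    y = np.asarray(series, float).copy()
    imputed = np.zeros(len(y), bool)
    obs_idx: list[int] = []
    gap_run = 0
    for k in range(len(y)):
        if not np.isnan(y[k]):
            obs_idx.append(k)
            gap_run = 0
            continue
        gap_run += 1
        if gap_run > max_gap_days or not obs_idx:
            continue
        if mode == "linear" and len(obs_idx) >= 2:
            k1, k2 = obs_idx[-2], obs_idx[-1]
            slope = (y[k2] - y[k1]) / (k2 - k1)
            val = y[k2] + slope * (k - k2)
        else:
            val = y[obs_idx[-1]]
        y[k] = max(val, floor)
        imputed[k] = True
    return y, imputed


#: Physiologic floors used when extrapolation or regression draws
#: undershoot; everything else is clamped at zero.
FIELD_FLOORS: dict[str, float] = {
    "pf_ratio": 30.0,
    "temperature": 32.0,
    "heart_rate": 20.0,
    "resp_rate": 4.0,
}


def trend_impute_admission(
    admission: Admission,
    fields: Sequence[str] = MASKABLE_FIELDS,
    max_gap_days: int = 2,
    mode: str = "linear",
) -> Admission:
    """Apply :func:`trend_impute` to every daily variable of one admission."""
    cols = {f: [getattr(r, f) for r in admission.records] for f in fields}
    filled = {
        f: trend_impute(v, max_gap_days, mode, floor=FIELD_FLOORS.get(f, 0.0))[0]
        for f, v in cols.items()
    }
    new_records = []
    for k, rec in enumerate(admission.records):
        updates = {f: float(filled[f][k]) for f in fields}
        new_records.append(dataclasses.replace(rec, **updates))
    return dataclasses.replace(admission, records=new_records)


def _is_binary(col: pd.Series) -> bool:
    vals = col.dropna().unique()
    return len(vals) > 0 and set(np.unique(vals)).issubset({0.0, 1.0})


def _draw_linear(X: np.ndarray, y: np.ndarray, Xmis: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Bayesian-linear-regression posterior predictive draw.

    Columns are standardised internally and the normal equations are
    ridge-stabilised, so near-constant or collinear predictors cannot
    break the draw.
    """
    n, p = X.shape
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd < 1e-12] = 1.0
    Xs = (X - mu) / sd
    Xs[:, 0] = 1.0  # intercept column stays
    Xm = (Xmis - mu) / sd
    Xm[:, 0] = 1.0
    XtX = Xs.T @ Xs + 1e-4 * n * np.eye(p)
    beta = np.linalg.solve(XtX, Xs.T @ y)
    resid = y - Xs @ beta
    dof = max(n - p, 2)
    sigma2 = float(resid @ resid) / rng.chisquare(dof)
    cov = sigma2 * np.linalg.inv(XtX)
    # eigen-based sampling tolerates numerically semi-definite cov
    w, V = np.linalg.eigh(0.5 * (cov + cov.T))
    half = V * np.sqrt(np.clip(w, 0.0, None))
    beta_draw = beta + half @ rng.standard_normal(p)
    return Xm @ beta_draw + rng.normal(0, np.sqrt(sigma2), len(Xm))

def _draw_logistic(X: np.ndarray, y: np.ndarray, Xmis: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    import statsmodels.api as sm

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=50)
        beta = rng.multivariate_normal(res.params, res.cov_params(),
                                       method="cholesky")
        p = 1.0 / (1.0 + np.exp(-(Xmis @ beta)))
    except Exception:  # separation or non-convergence: marginal draw
        p = np.full(len(Xmis), max(min(y.mean(), 1 - 1e-6), 1e-6))
    return (rng.random(len(Xmis)) < p).astype(float)


def multiple_impute(
    df: pd.DataFrame,
    m: int = 5,
    seed: int = 0,
    predictors: Optional[Sequence[str]] = None,
    n_cycles: int = 5,
) -> list[pd.DataFrame]:
    """Chained-equations multiple imputation of a patient-day table.

    ``predictors`` are the columns used both as imputation targets and
    regressors (default: all numeric columns).  Columns that are
    entirely missing are dropped from the predictor set with a warning.
    Returns ``m`` stochastically completed copies; reproducible given
    ``seed``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    num_cols = [
        c for c in (predictors or df.columns)
        if c in df.columns and pd.api.types.is_numeric_dtype(df[c])
    ]
    all_missing = [c for c in num_cols if df[c].isna().all()]
    if all_missing:
        warnings.warn(
            f"columns entirely missing, excluded from imputation: {all_missing}"
        )
        num_cols = [c for c in num_cols if c not in all_missing]
    targets = [c for c in num_cols if df[c].isna().any()]
    if not targets:
        return [df.copy() for _ in range(m)]

    base = df[num_cols].to_numpy(float)
    miss = np.isnan(base)
    out = []
    root = np.random.SeedSequence(seed)
    for rep, ss in enumerate(root.spawn(m)):
        rng = np.random.default_rng(ss)
        work = base.copy()
        # initial fill: random draws from each column's observed values
        for j, c in enumerate(num_cols):
            obs = base[~miss[:, j], j]
            if miss[:, j].any():
                work[miss[:, j], j] = rng.choice(obs, size=miss[:, j].sum())
        for _ in range(n_cycles):
            for j, c in enumerate(num_cols):
                if not miss[:, j].any():
                    continue
                others = [k for k in range(len(num_cols)) if k != j]
                X = np.column_stack([np.ones(len(work)), work[:, others]])
                rows_obs = ~miss[:, j]
                drawer = _draw_logistic if _is_binary(df[c]) else _draw_linear
                vals = drawer(
                    X[rows_obs], base[rows_obs, j], X[miss[:, j]], rng
                )
                work[miss[:, j], j] = vals
        done = df.copy()
        for j, c in enumerate(num_cols):
            done[c] = work[:, j]
        out.append(done)
    return out


def impute_cohort(
    admissions: Sequence[Admission],
    m: int = 5,
    seed: int = 0,
    fields: Sequence[str] = MASKABLE_FIELDS,
    max_gap_days: int = 2,
    trend_mode: str = "linear",
) -> tuple[list[list[Admission]], ImputationReport]:
    """Trend-impute then multiply-impute a whole cohort.

    Returns ``m`` completed admission lists plus a report of the
    missing fractions before and after the trend pass.
    """
    before = missing_fraction(admissions, fields)
    trended = [
        trend_impute_admission(a, fields, max_gap_days, trend_mode)
        for a in admissions
    ]
    after = missing_fraction(trended, fields)
    table = days_frame(trended)
    predictors = ["day", *fields]
    completed_tables = multiple_impute(table, m=m, seed=seed, predictors=predictors)

    completed: list[list[Admission]] = []
    for tab in completed_tables:
        arrs = {
            f: np.clip(tab[f].to_numpy(float), FIELD_FLOORS.get(f, 0.0), None)
            for f in fields
        }
        cohort = []
        pos = 0
        for adm in trended:
            recs = []
            for rec in adm.records:
                updates = {f: float(arrs[f][pos]) for f in fields}
                recs.append(dataclasses.replace(rec, **updates))
                pos += 1
            cohort.append(dataclasses.replace(adm, records=recs))
        completed.append(cohort)
    report = ImputationReport(
        fraction_missing_before=before,
        fraction_missing_after_trend=after,
        m=m,
        seed=seed,
    )
    return completed, report


def missing_fraction(
    admissions: Sequence[Admission], fields: Sequence[str] = MASKABLE_FIELDS
) -> float:
    total = n_missing = 0
    for adm in admissions:
        for rec in adm.records:
            for f in fields:
                total += 1
                v = getattr(rec, f)
                if v is None or (isinstance(v, float) and np.isnan(v)):
                    n_missing += 1
    return n_missing / total if total else 0.0


def pool_estimates(
    estimates: np.ndarray, variances: np.ndarray, alpha: float = 0.05
) -> dict[str, np.ndarray]:
    """Rubin's rules for combining multiply-imputed fits.

    ``estimates`` and ``variances`` have shape (m, p).  The pooled point
    is the mean; total variance is the mean within-variance plus
    (1 + 1/m) times the between-imputation variance.  The interval uses
    the Barnard-Rubin small-sample degrees of freedom.
    """
    est = np.atleast_2d(np.asarray(estimates, float))
    var = np.atleast_2d(np.asarray(variances, float))
    if est.shape != var.shape:
        raise ValueError("estimates and variances must have matching shapes")
    m = est.shape[0]
    if m < 2:
        raise ValueError("pooling requires m >= 2 fits")
    if not np.all(np.isfinite(var)):
        raise ValueError("non-finite variances")
    point = est.mean(axis=0)
    within = var.mean(axis=0)
    between = est.var(axis=0, ddof=1)
    total = within + (1 + 1 / m) * between
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (1 + 1 / m) * between / within
        df = (m - 1) * (1 + 1 / r) ** 2
    df = np.where(between > 0, df, np.inf)
    from scipy.stats import t as tdist

    crit = np.where(np.isinf(df), 1.959963984540054,
                    tdist.ppf(1 - alpha / 2, np.clip(df, 1, None)))
    half = crit * np.sqrt(total)
    return {
        "estimate": point,
        "total_variance": total,
        "within_variance": within,
        "between_variance": between,
        "ci_lower": point - half,
        "ci_upper": point + half,
        "df": df,
    }
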