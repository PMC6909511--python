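"""Continuous-time Markov multi-state model for panel-observed ICU data.

The disease process is a five-state continuous-time Markov chain whose
transition intensities are piecewise constant over ICU-day epochs and
depend log-linearly on covariates:

    q_ij(t, x) = q0_ij(epoch(t)) * exp(beta_ij . x)

for allowed transitions i->j (structural zeros stay at rate 0).  States
are observed on a 2-day grid (panel data); the transition probability
over an interval is the product of matrix exponentials exp(Q dt) across
the epoch segments it crosses.  Discharge and death days are completely
recorded, so absorbing events can contribute exact-day density terms
instead of plain panel terms.

Fitting maximises the panel likelihood over (log q0, beta) by
quasi-Newton iterations; standard errors come from the inverse observed
information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize
from statsmodels.tools.numdiff import approx_hess

from .records import HORIZON_DAY, PanelSequence
from .states import DiseaseState, TransitionStructure

DEFAULT_EPOCHS = (1.0, 3.0, 7.0)
RATE_FLOOR_LOG = np.log(1e-8)
_LOGQ_BOUNDS = (-12.0, 2.5)
_BETA_BOUNDS = (-6.0, 6.0)


@dataclass
class IntensityModel:
    """Epoch-wise baseline intensities plus log-linear covariate effects.

    ``log_baseline`` has shape (n_epochs, n_transitions) following the
    ordering of ``structure.allowed``; ``beta`` has shape
    (n_transitions, n_covariates).
    """

    structure: TransitionStructure = field(default_factory=TransitionStructure)
    epochs: tuple[float, ...] = DEFAULT_EPOCHS
    log_baseline: Optional[np.ndarray] = None
    beta: Optional[np.ndarray] = None
    covariate_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        E, K, C = len(self.epochs), self.structure.n_transitions, len(self.covariate_names)
        if self.log_baseline is None:
            self.log_baseline = np.full((E, K), np.log(0.05))
        self.log_baseline = np.asarray(self.log_baseline, float)
        if self.log_baseline.shape != (E, K):
            raise ValueError(f"log_baseline must have shape {(E, K)}")
        if self.beta is None:
            self.beta = np.zeros((K, C))
        self.beta = np.asarray(self.beta, float)
        if self.beta.shape != (K, C):
            raise ValueError(f"beta must have shape {(K, C)}")
        if tuple(self.epochs) != tuple(sorted(self.epochs)):
            raise ValueError("epochs must be increasing")

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)

    def epoch_index(self, t: float) -> int:
        return int(np.searchsorted(np.asarray(self.epochs), t, side="right") - 1)

    def x_vector(self, covariates: dict) -> np.ndarray:
        return np.array(
            [float(covariates.get(name, 0.0)) for name in self.covariate_names]
        )

    def rates(self, epoch: int, x: Optional[np.ndarray] = None) -> np.ndarray:
        """Per-transition intensities q_ij for one epoch and covariate vector."""
        lr = self.log_baseline[epoch].copy()
        if x is not None and self.beta.shape[1]:
            lr = lr + self.beta @ np.asarray(x, float)
        # cap keeps extreme covariate values from overflowing to inf;
        # e^30/day is already an instantaneous transition
        return np.exp(np.clip(lr, None, 30.0))

    def generator(self, epoch: int, x: Optional[np.ndarray] = None) -> np.ndarray:
        """5x5 generator matrix Q; rows sum to zero, absorbing rows zero."""
        return build_generator(self.structure, self.rates(epoch, x))

    def segments(self, t_from: float, t_to: float) -> list[tuple[int, float]]:
        """Decompose [t_from, t_to) into (epoch index, duration) pieces."""
        if t_to <= t_from:
            raise ValueError("t_from must precede t_to")
        cuts = list(self.epochs) + [np.inf]
        out = []
        for e in range(self.n_epochs):
            a, b = max(t_from, cuts[e]), min(t_to, cuts[e + 1])
            if b > a:
                out.append((e, b - a))
        return out


def build_generator(structure: TransitionStructure, rates: np.ndarray) -> np.ndarray:
    n = structure.n_states
    Q = np.zeros((n, n))
    for k, (i, j) in enumerate(structure.allowed):
        Q[i - 1, j - 1] = rates[k]
    Q[np.arange(n), np.arange(n)] = -Q.sum(axis=1)
    validate_generator(Q, structure)
    return Q


def validate_generator(Q: np.ndarray, structure: TransitionStructure) -> None:
    off = Q.copy()
    np.fill_diagonal(off, 0.0)
    if (off < 0).any():
        raise ValueError("negative off-diagonal intensity")
    tol = 1e-10 * max(1.0, float(np.abs(Q).max()))
    if np.abs(Q.sum(axis=1)).max() > tol:
        raise ValueError("generator rows must sum to zero")
    for i, j in (
        (a, b)
        for a in range(1, structure.n_states + 1)
        for b in range(1, structure.n_states + 1)
        if a != b and (a, b) not in structure.allowed
    ):
        if Q[i - 1, j - 1] != 0.0:
            raise ValueError(f"structural zero ({i},{j}) has nonzero rate")
    for a in structure.absorbing:
        if np.abs(Q[a - 1]).max() > 0:
            raise ValueError(f"absorbing state {a} has exits")


def transition_matrix(
    model: IntensityModel,
    x: Optional[np.ndarray | dict],
    t_from: float,
    t_to: float,
) -> np.ndarray:
    """Transition probability matrix P(t_from, t_to | x).

    Product of ``exp(Q(epoch, x) * dt)`` over the epoch segments the
    interval crosses; covariates are held fixed at ``x`` throughout.
    """
    if isinstance(x, dict):
        x = model.x_vector(x)
    if x is not None and not np.all(np.isfinite(x)):
        raise ValueError("non-finite covariate values")
    P = np.eye(model.structure.n_states)
    for e, dt in model.segments(t_from, t_to):
        P = P @ expm(model.generator(e, x) * dt)
    return P


# ---------------------------------------------------------------------------
# panel data preprocessing and likelihood


@dataclass
class _PanelArrays:
    """Vectorised view of all consecutive observation pairs.

    Intervals are grouped by unique (covariate row, epoch segmentation):
    the transition matrix is computed once per group and gathered per
    interval, which collapses the covariate-free likelihood to a handful
    of matrix exponentials.
    """

    i0: np.ndarray  # 0-based origin states
    j0: np.ndarray  # 0-based destination states
    t0: np.ndarray
    t1: np.ndarray
    xid: np.ndarray  # index into Xu
    Xu: np.ndarray  # (U, C) unique covariate rows
    exact: np.ndarray  # absorbing event observed at exact day
    e_end: np.ndarray  # epoch index at interval end
    gid: np.ndarray  # interval -> group
    gid_pre: np.ndarray  # group of [t0, t1-1) for exact intervals (-1: empty)
    groups: list[tuple[int, tuple[tuple[int, float], ...]]]  # (xid, segments)
    tasks: dict[tuple[int, int, float], int]  # (xid, epoch, dt) -> index
    n_sequences: int


def _prepare_panels(
    panels: Sequence[PanelSequence],
    covariate_names: Sequence[str],
    absorbing_exact: bool,
    epochs: Sequence[float] = DEFAULT_EPOCHS,
) -> _PanelArrays:
    probe = IntensityModel(epochs=tuple(epochs))
    i0, j0, t0, t1, exact, X = [], [], [], [], [], []
    for seq in panels:
        for a, b, s0, s1, cov in seq.intervals():
            i0.append(int(s0) - 1)
            j0.append(int(s1) - 1)
            t0.append(float(a))
            t1.append(float(b))
            exact.append(absorbing_exact and s1.is_absorbing)
            X.append([float(cov.get(n, 0.0)) for n in covariate_names])
    X = np.asarray(X, float) if covariate_names else np.zeros((len(i0), 0))
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite covariate values in panel data")
    Xu, xid = np.unique(X, axis=0, return_inverse=True)
    seg_cache: dict[tuple[float, float], tuple[tuple[int, float], ...]] = {}
    group_index: dict[tuple[int, tuple], int] = {}
    groups: list[tuple[int, tuple[tuple[int, float], ...]]] = []
    tasks: dict[tuple[int, int, float], int] = {}
    gid = np.empty(len(i0), int)
    gid_pre = np.full(len(i0), -1, int)
    e_end = np.empty(len(i0), int)

    def group_of(u: int, a: float, b: float) -> int:
        key = (a, b)
        segs = seg_cache.get(key)
        if segs is None:
            segs = tuple(probe.segments(a, b))
            seg_cache[key] = segs
        gkey = (u, segs)
        g = group_index.get(gkey)
        if g is None:
            g = len(groups)
            group_index[gkey] = g
            groups.append(gkey)
            for e, dt in segs:
                tasks.setdefault((u, e, float(dt)), len(tasks))
        return g

    for m, (u, a, b) in enumerate(zip(xid, t0, t1)):
        gid[m] = group_of(int(u), a, b)
        e_end[m] = probe.epoch_index(b)
        if exact[m] and b - 1.0 > a:
            gid_pre[m] = group_of(int(u), a, b - 1.0)
    return _PanelArrays(
        i0=np.asarray(i0),
        j0=np.asarray(j0),
        t0=np.asarray(t0),
        t1=np.asarray(t1),
        xid=np.asarray(xid),
        Xu=Xu,
        exact=np.asarray(exact, bool),
        e_end=e_end,
        gid=gid,
        gid_pre=gid_pre,
        groups=groups,
        tasks=tasks,
        n_sequences=len(panels),
    )


def _rate_table(model: IntensityModel, Xu: np.ndarray) -> np.ndarray:
    """Intensities per (unique covariate row, epoch, transition)."""
    lr = model.log_baseline[None, :, :] + (Xu @ model.beta.T)[:, None, :]
    return np.exp(np.clip(lr, None, 30.0))


def _group_matrices(model: IntensityModel, pa: _PanelArrays,
                    rates: np.ndarray) -> np.ndarray:
    """Transition matrix per interval group."""
    n = model.structure.n_states
    U = pa.Xu.shape[0]
    Qall = np.zeros((U, model.n_epochs, n, n))
    for k, (i, j) in enumerate(model.structure.allowed):
        Qall[:, :, i - 1, j - 1] = rates[:, :, k]
    Qall[:, :, np.arange(n), np.arange(n)] = -Qall.sum(axis=3)
    Qdt = np.empty((len(pa.tasks), n, n))
    for (u, e, dt), idx in pa.tasks.items():
        Qdt[idx] = Qall[u, e] * dt
    Pseg = expm(Qdt)
    Pg = np.empty((len(pa.groups), n, n))
    for g, (u, segs) in enumerate(pa.groups):
        acc = Pseg[pa.tasks[(u, segs[0][0], float(segs[0][1]))]]
        for e, dt in segs[1:]:
            acc = acc @ Pseg[pa.tasks[(u, e, float(dt))]]
        Pg[g] = acc
    return Pg


def panel_loglik(
    model: IntensityModel,
    panels: Sequence[PanelSequence],
    absorbing_exact: bool | str = True,
    _prepared: Optional[_PanelArrays] = None,
    on_zero: str = "warn",
) -> float:
    """Log-likelihood of panel sequences under ``model``.

    Each consecutive pair contributes ``log P_{s_k, s_{k+1}}(t_k,
    t_{k+1}; x_k)`` with covariates held at their interval-start value.
    Discharge and death days are completely recorded but only at whole-
    day resolution, so with the default ``absorbing_exact=True`` (mode
    ``"day"``) an absorbing observation at day ``t_d`` contributes the
    probability of absorption *during* day ``t_d``, i.e.
    ``P_{s_k,abs}(t_k, t_d) - P_{s_k,abs}(t_k, t_d - 1)``.  Mode
    ``"density"`` instead treats the event time as exactly ``t_d`` and
    uses the transition density ``sum_r P_{s_k, r}(t_k, t_d) *
    q_{r, abs}(t_d)`` (appropriate when true event times are known to
    the minute); ``False`` falls back to plain panel terms.  Pairs that
    are impossible under the transition structure get probability ~0; a
    diagnostic warning lists them (``on_zero='raise'`` escalates).
    """
    pa = _prepared or _prepare_panels(
        panels, model.covariate_names, bool(absorbing_exact), model.epochs
    )
    rates = _rate_table(model, pa.Xu)  # (U, E, K)
    Pg = _group_matrices(model, pa, rates)
    terms = Pg[pa.gid, pa.i0, pa.j0]
    if pa.exact.any():
        terms = terms.copy()
        sel = np.where(pa.exact)[0]
        if absorbing_exact == "density":
            n = model.structure.n_states
            for jdest in np.unique(pa.j0[sel]):
                sub = sel[pa.j0[sel] == jdest]
                # selector: transitions r -> jdest, laid out per origin state
                M = np.zeros((n, len(model.structure.allowed)))
                for k, (i, j) in enumerate(model.structure.allowed):
                    if j - 1 == jdest:
                        M[i - 1, k] = 1.0
                qv = rates[pa.xid[sub], pa.e_end[sub]] @ M.T  # (n_sub, n)
                terms[sub] = np.einsum(
                    "mr,mr->m", Pg[pa.gid[sub], pa.i0[sub], :], qv
                )
        else:  # "day": absorption within the recorded day
            pre = np.where(
                pa.gid_pre[sel] >= 0,
                Pg[np.clip(pa.gid_pre[sel], 0, None), pa.i0[sel], pa.j0[sel]],
                0.0,
            )
            terms[sel] = terms[sel] - pre
    bad = terms <= 0
    if bad.any():
        pairs = sorted(
            {(int(a) + 1, int(b) + 1) for a, b in zip(pa.i0[bad], pa.j0[bad])}
        )
        msg = f"zero-probability observation pairs under structure: {pairs}"
        if on_zero == "raise":
            raise ValueError(msg)
        warnings.warn(msg)
    return float(np.log(np.clip(terms, 1e-300, None)).sum())


# ---------------------------------------------------------------------------
# analytic score
#
# The likelihood is a product of entries of matrix exponentials
# P = exp(Q dt); its gradient uses the eigendecomposition form of the
# Frechet derivative, d exp(A)[E] = V ((V^-1 E V) o Phi) V^-1 with
# Phi_ab = (e^wa - e^wb)/(wa - wb).  Each free parameter perturbs one
# transition's rate, so E is a rank-one-per-row sparse matrix and the
# whole computation batches over the unique (covariate, epoch, dt)
# tasks.  Tasks with an ill-conditioned eigenbasis fall back to
# scipy's expm_frechet.


def _task_P_and_derivs(model, pa, rates, need_derivs=True):
    """P = exp(Q dt) per task, plus dP/dlog q_k per transition k."""
    n = model.structure.n_states
    K = len(model.structure.allowed)
    T = len(pa.tasks)
    task_u = np.empty(T, int)
    task_e = np.empty(T, int)
    task_dt = np.empty(T)
    for (u, e, dt), idx in pa.tasks.items():
        task_u[idx], task_e[idx], task_dt[idx] = u, e, dt
    U = pa.Xu.shape[0]
    Qall = np.zeros((U, model.n_epochs, n, n))
    for k, (i, j) in enumerate(model.structure.allowed):
        Qall[:, :, i - 1, j - 1] = rates[:, :, k]
    Qall[:, :, np.arange(n), np.arange(n)] = -Qall.sum(axis=3)
    A = Qall[task_u, task_e] * task_dt[:, None, None]

    P = expm(A)
    if not need_derivs:
        return P, None, (task_u, task_e, task_dt)

    w, V = np.linalg.eig(A)
    with np.errstate(divide="ignore", invalid="ignore"):
        Vinv = np.linalg.inv(V)
    ew = np.exp(w)
    dwv = w[:, :, None] - w[:, None, :]
    close = np.abs(dwv) < 1e-9
    Phi = np.where(
        close,
        np.exp(0.5 * (w[:, :, None] + w[:, None, :])),
        (ew[:, :, None] - ew[:, None, :]) / np.where(close, 1.0, dwv),
    )
    # sanity: flag tasks where the eigenbasis is unreliable
    P_eig = np.real(V @ (ew[:, :, None] * Vinv))
    bad = (
        ~np.isfinite(P_eig).all(axis=(1, 2))
        | (np.abs(P_eig - P).max(axis=(1, 2)) > 1e-8)
    )
    D = np.empty((T, K, n, n))
    coef = rates[task_u, task_e] * task_dt[:, None]  # (T, K)
    for k, (i, j) in enumerate(model.structure.allowed):
        u_col = Vinv[:, :, i - 1]                      # (T, n)
        v_diff = V[:, j - 1, :] - V[:, i - 1, :]       # (T, n)
        M = u_col[:, :, None] * v_diff[:, None, :] * Phi
        D[:, k] = np.real(V @ M @ Vinv) * coef[:, k, None, None]
    if bad.any():
        from scipy.linalg import expm_frechet

        for t in np.where(bad)[0]:
            for k, (i, j) in enumerate(model.structure.allowed):
                E = np.zeros((n, n))
                E[i - 1, j - 1] = 1.0
                E[i - 1, i - 1] = -1.0
                D[t, k] = expm_frechet(A[t], E * coef[t, k], compute_expm=False)
    return P, D, (task_u, task_e, task_dt)


def _loglik_and_score(model, pa, absorbing_mode):
    """Panel log-likelihood with exact gradients in (log q0, beta).

    Supports plain panel terms and the day-censored absorbing terms;
    the "density" mode has no analytic score here (the fit falls back
    to finite differences for it).
    """
    E_, K = model.n_epochs, len(model.structure.allowed)
    C = len(model.covariate_names)
    rates = _rate_table(model, pa.Xu)
    P, D, (task_u, task_e, task_dt) = _task_P_and_derivs(model, pa, rates)

    G = len(pa.groups)
    n = model.structure.n_states
    Pg = np.empty((G, n, n))
    # per group and segment slot: derivative contribution and its epoch
    max_s = max(len(segs) for _, segs in pa.groups) if G else 1
    dPg = np.zeros((G, max_s, K, n, n))
    seg_epoch = np.full((G, max_s), -1, int)
    by_nseg: dict[int, list[int]] = {}
    for g, (_, segs) in enumerate(pa.groups):
        by_nseg.setdefault(len(segs), []).append(g)
    task_of = pa.tasks
    for nseg, gids in by_nseg.items():
        gids = np.asarray(gids)
        tids = np.array(
            [
                [task_of[(pa.groups[g][0], e, float(dt))]
                 for e, dt in pa.groups[g][1]]
                for g in gids
            ]
        )  # (Gn, nseg)
        for s in range(nseg):
            seg_epoch[gids, s] = [pa.groups[g][1][s][0] for g in gids]
        Ps = P[tids]  # (Gn, nseg, n, n)
        acc = Ps[:, 0]
        for s in range(1, nseg):
            acc = acc @ Ps[:, s]
        Pg[gids] = acc
        for s in range(nseg):
            pre = np.broadcast_to(np.eye(n), (len(gids), n, n))
            for a in range(s):
                pre = pre @ Ps[:, a]
            suf = np.broadcast_to(np.eye(n), (len(gids), n, n))
            for b in range(s + 1, nseg):
                suf = suf @ Ps[:, b]
            # pre @ D_s @ suf for all K directions
            dPg[gids, s] = np.einsum(
                "gab,gkbc,gcd->gkad", pre, D[tids[:, s]], suf
            )

    # contribution list: (interval, group, sign)
    m_idx = [np.arange(len(pa.i0))]
    g_idx = [pa.gid]
    sign = [np.ones(len(pa.i0))]
    terms = Pg[pa.gid, pa.i0, pa.j0].copy()
    if absorbing_mode and pa.exact.any():
        sel = np.where(pa.exact & (pa.gid_pre >= 0))[0]
        pre_vals = Pg[pa.gid_pre[sel], pa.i0[sel], pa.j0[sel]]
        terms[sel] -= pre_vals
        m_idx.append(sel)
        g_idx.append(pa.gid_pre[sel])
        sign.append(-np.ones(len(sel)))
    m_all = np.concatenate(m_idx)
    g_all = np.concatenate(g_idx)
    s_all = np.concatenate(sign)

    tsafe = np.clip(terms, 1e-300, None)
    ll = float(np.log(tsafe).sum())

    # the score weight 1/term is floored so extreme trial points during
    # optimisation yield large-but-finite gradients the line search can
    # back off from, instead of overflowing
    w_all = s_all / np.clip(terms, 1e-10, None)[m_all]
    grad_logq = np.zeros((E_, K))
    grad_beta = np.zeros((K, C))
    i_all, j_all = pa.i0[m_all], pa.j0[m_all]
    for s in range(dPg.shape[1]):
        eps = seg_epoch[g_all, s]
        act = eps >= 0
        if not act.any():
            continue
        vals = (
            dPg[g_all[act], s, :, i_all[act], j_all[act]]
            * w_all[act][:, None]
        )  # (n_act, K)
        np.add.at(grad_logq, eps[act], vals)
        if C:
            group_u = np.fromiter((u for u, _ in pa.groups), int, count=G)
            Xm = pa.Xu[group_u[g_all[act]]]
            grad_beta += np.einsum("mk,mc->kc", vals, Xm)
    grad_logq = np.nan_to_num(grad_logq, posinf=1e10, neginf=-1e10)
    grad_beta = np.nan_to_num(grad_beta, posinf=1e10, neginf=-1e10)
    return ll, grad_logq, grad_beta


@dataclass
class FitResult:
    """Maximum-likelihood fit of the panel multi-state model."""

    model: IntensityModel
    se_log_baseline: np.ndarray
    se_beta: np.ndarray
    cov_params: Optional[np.ndarray]
    loglik: float
    converged: bool
    n_intervals: int
    n_sequences: int
    not_estimable: list[tuple[int, int]]
    message: str = ""
    free_mask_baseline: Optional[np.ndarray] = None

    def hazard_ratios(self) -> dict[str, dict[str, float]]:
        """exp(beta) per covariate per transition, with Wald 95% CIs."""
        out: dict[str, dict[str, float]] = {}
        labels = self.model.structure.labels()
        for c, name in enumerate(self.model.covariate_names):
            for k, lab in enumerate(labels):
                b = self.model.beta[k, c]
                se = self.se_beta[k, c]
                out[f"{name}:{lab}"] = {
                    "hr": float(np.exp(b)),
                    "lo": float(np.exp(b - 1.96 * se)),
                    "hi": float(np.exp(b + 1.96 * se)),
                    "se_log": float(se),
                    "p": _wald_p(b, se),
                }
        return out


def _hessian_from_score(score, theta: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Observed information by central differences of the analytic score."""
    p = len(theta)
    H = np.empty((p, p))
    for i in range(p):
        step = h * max(1.0, abs(theta[i]))
        tp, tm = theta.copy(), theta.copy()
        tp[i] += step
        tm[i] -= step
        H[:, i] = (score(tp) - score(tm)) / (2 * step)
    return 0.5 * (H + H.T)


def _wald_p(b: float, se: float) -> float:
    from scipy.stats import norm

    if not np.isfinite(se) or se <= 0:
        return np.nan
    return float(2 * norm.sf(abs(b) / se))


def _observed_pair_counts(
    panels: Sequence[PanelSequence], structure: TransitionStructure
) -> dict[tuple[int, int], int]:
    counts = {pair: 0 for pair in structure.allowed}
    for seq in panels:
        for _, _, s0, s1, _ in seq.intervals():
            pair = (int(s0), int(s1))
            if pair in counts:
                counts[pair] += 1
    return counts


def _crude_init(
    panels: Sequence[PanelSequence], structure: TransitionStructure
) -> np.ndarray:
    """Occurrence/exposure starting values on the log scale."""
    counts = _observed_pair_counts(panels, structure)
    exposure = {i: 1e-9 for i in range(1, structure.n_states + 1)}
    for seq in panels:
        for a, b, s0, _, _ in seq.intervals():
            exposure[int(s0)] += b - a
    init = np.empty(structure.n_transitions)
    for k, (i, j) in enumerate(structure.allowed):
        rate = max(counts[(i, j)], 0.5) / exposure[i]
        init[k] = np.log(min(max(rate, 1e-4), 1.0))
    return init


def fit(
    panels: Sequence[PanelSequence],
    structure: Optional[TransitionStructure] = None,
    covariate_names: Sequence[str] = (),
    epochs: Sequence[float] = DEFAULT_EPOCHS,
    absorbing_exact: bool = True,
    maxiter: int = 500,
    gtol: float = 1e-6,
    compute_se: bool = True,
    x0: Optional[np.ndarray] = None,
) -> FitResult:
    """Fit the panel multi-state model by maximum likelihood.

    Transitions with no directly observed panel pair are not estimable
    from the data: their baseline log-intensity is pinned at a floor
    (rate 1e-8/day) with a warning, and reported in ``not_estimable``.
    Non-convergence is flagged on the result rather than raised.
    """
    structure = structure or TransitionStructure()
    covariate_names = tuple(covariate_names)
    epochs = tuple(float(e) for e in epochs)
    E, K, C = len(epochs), structure.n_transitions, len(covariate_names)
    pa = _prepare_panels(panels, covariate_names, absorbing_exact, epochs)

    counts = _observed_pair_counts(panels, structure)
    not_estimable = [pair for pair, c in counts.items() if c == 0]
    if not_estimable:
        warnings.warn(
            f"transitions with no observed panel events pinned at floor: {not_estimable}"
        )
    est_mask = np.array([counts[pair] > 0 for pair in structure.allowed])

    init_logq = x0 if x0 is not None else _crude_init(panels, structure)
    logq = np.tile(np.asarray(init_logq, float), (E, 1))
    logq[:, ~est_mask] = RATE_FLOOR_LOG

    free_b = np.repeat(est_mask[None, :], E, axis=0)  # (E, K)
    n_free_b = int(free_b.sum())
    n_par = n_free_b + K * C if C else n_free_b

    def unpack(theta: np.ndarray) -> IntensityModel:
        lb = logq.copy()
        lb[free_b] = theta[:n_free_b]
        beta = np.zeros((K, C))
        if C:
            beta = theta[n_free_b:].reshape(K, C).copy()
            beta[~est_mask, :] = 0.0
        return IntensityModel(
            structure=structure,
            epochs=epochs,
            log_baseline=lb,
            beta=beta,
            covariate_names=covariate_names,
        )

    use_score = absorbing_exact != "density"

    def negloglik(theta: np.ndarray) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ll = panel_loglik(unpack(theta), panels, absorbing_exact, _prepared=pa)
        return -ll if np.isfinite(ll) else 1e12

    def neg_score(theta: np.ndarray) -> np.ndarray:
        _, gl, gb = _loglik_and_score(
            unpack(theta), pa, bool(absorbing_exact)
        )
        pieces = [gl[free_b]]
        if C:
            gb = gb.copy()
            gb[~est_mask] = 0.0
            pieces.append(gb.ravel())
        return -np.concatenate(pieces)

    def negloglik_and_grad(theta: np.ndarray):
        ll, gl, gb = _loglik_and_score(
            unpack(theta), pa, bool(absorbing_exact)
        )
        if not np.isfinite(ll):
            return 1e12, np.zeros_like(theta)
        pieces = [gl[free_b]]
        if C:
            gb = gb.copy()
            gb[~est_mask] = 0.0
            pieces.append(gb.ravel())
        return -ll, -np.concatenate(pieces)

    theta0 = np.concatenate(
        [logq[free_b], np.zeros(K * C)] if C else [logq[free_b]]
    )
    if n_par == 0:  # nothing estimable: all intensities pinned at the floor
        model = unpack(theta0)
        return FitResult(
            model=model,
            se_log_baseline=np.full((E, K), np.nan),
            se_beta=np.full((K, C), np.nan),
            cov_params=None,
            loglik=panel_loglik(model, panels, absorbing_exact, _prepared=pa),
            converged=True,
            n_intervals=len(pa.i0),
            n_sequences=pa.n_sequences,
            not_estimable=not_estimable,
            message="no estimable transitions",
            free_mask_baseline=free_b,
        )
    bounds = [_LOGQ_BOUNDS] * n_free_b + [_BETA_BOUNDS] * (n_par - n_free_b)
    res = minimize(
        negloglik_and_grad if use_score else negloglik,
        theta0,
        jac=True if use_score else None,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-10},
    )
    model = unpack(res.x)

    se_lb = np.full((E, K), np.nan)
    se_beta = np.full((K, C), np.nan)
    cov = None
    if compute_se and n_par:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if use_score:
                    H = _hessian_from_score(neg_score, res.x)
                else:
                    H = approx_hess(res.x, negloglik)
            cov = np.linalg.pinv(H)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
            se_lb[free_b] = se[:n_free_b]
            if C:
                sb = se[n_free_b:].reshape(K, C)
                sb[~est_mask] = np.nan
                se_beta = sb
        except Exception as exc:  # pragma: no cover - numerical edge
            warnings.warn(f"standard-error computation failed: {exc}")
    return FitResult(
        model=model,
        se_log_baseline=se_lb,
        se_beta=se_beta,
        cov_params=cov,
        loglik=-res.fun,
        converged=bool(res.success),
        n_intervals=len(pa.i0),
        n_sequences=pa.n_sequences,
        not_estimable=not_estimable,
        message=str(res.message),
        free_mask_baseline=free_b,
    )


# ---------------------------------------------------------------------------
# prediction


@dataclass
class PredictionSurface:
    """Occupation probabilities over the 5 states from an origin."""

    origin_state: DiseaseState
    origin_day: float
    days: np.ndarray
    probs: np.ndarray  # (n_days, 5)

    def at(self, day: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.days - day)))
        return self.probs[idx]

    def prob(self, day: float, state: DiseaseState) -> float:
        return float(self.at(day)[int(state) - 1])


def occupation_probs(
    model_or_fit,
    s0: DiseaseState,
    t0: float,
    covariates: dict | np.ndarray | None = None,
    horizon: float = HORIZON_DAY,
    scenario: Optional[dict[float, dict]] = None,
) -> PredictionSurface:
    """Predicted state-occupation probabilities for days t0+1 ... horizon.

    Covariates are carried forward from ``covariates`` unless
    ``scenario`` supplies replacements from given future days (e.g. an
    "improvement" path where vasopressors stop at day 3).  An absorbing
    origin returns the degenerate surface with probability one forever.
    """
    model: IntensityModel = getattr(model_or_fit, "model", model_or_fit)
    s0 = DiseaseState(s0)
    n = model.structure.n_states
    days = np.arange(np.floor(t0) + 1, horizon + 1)
    if s0.is_absorbing:
        probs = np.zeros((len(days), n))
        probs[:, int(s0) - 1] = 1.0
        return PredictionSurface(s0, t0, days, probs)
    if not (1 <= t0 < horizon):
        raise ValueError(f"origin day {t0} outside [1, {horizon})")

    base_cov = dict(covariates) if isinstance(covariates, dict) else None
    if base_cov is None and covariates is not None:
        x_fixed = np.asarray(covariates, float)
    else:
        x_fixed = model.x_vector(base_cov or {})
    scenario = {float(k): v for k, v in (scenario or {}).items()}

    probs = np.empty((len(days), n))
    P = np.eye(n)
    t_prev = float(t0)
    x = x_fixed
    cov_now = dict(base_cov or {})
    for w, d in enumerate(days):
        changes = [sd for sd in scenario if t_prev <= sd < d]
        for sd in sorted(changes):
            if sd > t_prev:
                P = P @ transition_matrix(model, x, t_prev, sd)
                t_prev = sd
            cov_now.update(scenario[sd])
            x = model.x_vector(cov_now)
        P = P @ transition_matrix(model, x, t_prev, float(d))
        t_prev = float(d)
        probs[w] = P[int(s0) - 1]
    return PredictionSurface(s0, t0, days, probs)


def update_prediction(
    model_or_fit,
    observation_days: Sequence[float],
    states: Sequence[DiseaseState],
    covariates: dict | None = None,
    horizon: float = HORIZON_DAY,
    scenario: Optional[dict[float, dict]] = None,
) -> PredictionSurface:
    """Re-predict from the latest observation.

    By the Markov assumption only the current state, day and covariate
    values matter; earlier history is discarded by design.
    """
    last_state = DiseaseState(states[-1])
    if last_state.is_absorbing:
        raise ValueError("cannot update prediction from an absorbing state")
    return occupation_probs(
        model_or_fit, last_state, float(observation_days[-1]), covariates,
        horizon=horizon, scenario=scenario,
    )
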