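"""Univariable predictor screening.

Each candidate PIRO predictor is fitted alone, acting log-linearly on
all allowed transition intensities, yielding crude per-transition
hazard ratios with Wald confidence intervals.  A predictor enters the
final model when it is associated with *any* transition at P < 0.10
(strict); no forward or backward selection follows.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .multistate import FitResult, _BETA_BOUNDS, fit
from .records import PanelSequence
from .states import TransitionStructure


class DegenerateInputError(ValueError):
    """The predictor carries no information (constant in the data)."""


def crude_hr(
    panels: Sequence[PanelSequence],
    predictor: str,
    structure: Optional[TransitionStructure] = None,
    epochs: Sequence[float] = (1.0, 3.0, 7.0),
    **fit_kwargs,
) -> pd.DataFrame:
    """Crude hazard ratios of one predictor for every transition.

    Fits the panel multi-state likelihood with ``predictor`` as the
    single covariate and returns one row per allowed transition with
    ``hr``, Wald 95% CI, ``p`` and a ``converged`` flag.  Separated or
    non-converged fits are flagged, never silently reported.  Raises
    :class:`DegenerateInputError` when the predictor is constant.
    """
    values = [
        cov.get(predictor, 0.0)
        for seq in panels
        for cov in (seq.covariates or [])
    ]
    if len(set(np.round(values, 12))) < 2:
        raise DegenerateInputError(f"predictor {predictor!r} is constant")
    res: FitResult = fit(
        panels, structure=structure, covariate_names=(predictor,),
        epochs=epochs, **fit_kwargs,
    )
    lo_b, hi_b = _BETA_BOUNDS
    rows = []
    hrs = res.hazard_ratios()
    for k, lab in enumerate(res.model.structure.labels()):
        info = hrs[f"{predictor}:{lab}"]
        b = res.model.beta[k, 0]
        at_bound = b <= lo_b + 1e-3 or b >= hi_b - 1e-3
        pair = res.model.structure.allowed[k]
        rows.append(
            {
                "predictor": predictor,
                "transition": lab,
                "hr": info["hr"],
                "ci_lower": info["lo"],
                "ci_upper": info["hi"],
                "p": info["p"],
                "converged": bool(res.converged and not at_bound
                                  and np.isfinite(info["p"])),
                "estimable": pair not in res.not_estimable,
            }
        )
    return pd.DataFrame(rows)


def screen_predictors(
    panels: Sequence[PanelSequence],
    predictors: Sequence[str],
    **kwargs,
) -> pd.DataFrame:
    """Crude hazard-ratio table for a list of predictors."""
    tables = []
    for name in predictors:
        try:
            tables.append(crude_hr(panels, name, **kwargs))
        except DegenerateInputError:
            warnings.warn(f"skipping constant predictor {name!r}")
    return pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()


def select_predictors(
    table: pd.DataFrame,
    alpha: float = 0.10,
    per_transition: bool = False,
) -> list[str] | dict[str, list[str]]:
    """Apply the P < alpha (strict) univariable inclusion rule.

    Default: a predictor is included when its smallest per-transition
    p-value is below ``alpha``.  With ``per_transition`` a separate
    covariate set per transition is returned instead (non-default; the
    published model uses one shared covariate set).
    """
    usable = table[table["estimable"] & np.isfinite(table["p"])]
    if per_transition:
        out: dict[str, list[str]] = {}
        for lab, grp in usable.groupby("transition"):
            out[lab] = sorted(grp.loc[grp["p"] < alpha, "predictor"].unique())
        return out
    keep = usable.groupby("predictor")["p"].min()
    return sorted(keep.index[keep < alpha])
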