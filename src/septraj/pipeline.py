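"""End-to-end orchestration: simulate -> impute -> stage -> panel ->
screen -> fit -> predict -> evaluate, with a derivation/validation split.

The validation set is an independently simulated cohort from the same
truth (the original study used a later real cohort from one centre).
Every run writes a self-describing directory: config copy, intermediate
CSV/JSON artifacts, a log, and a metrics JSON that is byte-identical
across reruns with the same seed.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import __version__
from .cohort import (
    Admission,
    apply_palliative_censoring,
    build_panel,
    merge_readmissions,
    write_cohort,
)
from .evaluation import (
    DEFAULT_EVAL_TIMES,
    compare_models,
    multistate_cstat,
    observed_state_matrix,
    per_transition_cstat,
    predict_matrix,
)
from .impute import impute_cohort, pool_estimates
from .multistate import FitResult, IntensityModel, fit
from .records import PanelSequence
from .simulate import SimulationConfig, simulate_cohort
from .staging import StagingConfig, stage_series


class PipelineError(RuntimeError):
    """A pipeline stage failed; message names the stage and artifact."""


DEFAULT_BASELINE_COVARIATES = (
    "age_std", "immunodeficiency", "renal_insufficiency",
    "respiratory_insufficiency", "site_abdominal",
)
DEFAULT_DYNAMIC_COVARIATES = (
    "log_crp_std", "new_onset_af", "icu_acquired_infection", "bacteremia",
)


@dataclass
class PipelineConfig:
    """Configuration of one full run; all randomness flows from ``seed``."""

    out_dir: str = "runs/latest"
    seed: int = 0
    n_admissions: int = 500
    validation_fraction: float = 0.3
    simulation: Optional[SimulationConfig] = None
    m_imputations: int = 5
    epochs: tuple[float, ...] = (1.0, 3.0, 7.0)
    baseline_covariates: tuple[str, ...] = DEFAULT_BASELINE_COVARIATES
    dynamic_covariates: tuple[str, ...] = DEFAULT_DYNAMIC_COVARIATES
    screen_alpha: float = 0.10
    eval_times: tuple[float, ...] = DEFAULT_EVAL_TIMES
    n_bootstrap: int = 100
    staging: StagingConfig = field(default_factory=StagingConfig)

    def __post_init__(self) -> None:
        if not (0 < self.validation_fraction < 1):
            raise ValueError("validation_fraction must be in (0, 1)")


def _stage_to_panels(
    admissions: Sequence[Admission],
    daily_covariates: dict[str, list[dict]],
    staging_cfg: StagingConfig,
) -> list[PanelSequence]:
    panels = []
    for adm in admissions:
        states = stage_series(adm.records, staging_cfg)
        covs = daily_covariates[adm.admission_id][: len(states)]
        seq = build_panel(adm.admission_id, states, covs, adm.outcome)
        panels.append(apply_palliative_censoring(seq, adm.outcome))
    return panels


def _pooled_model(fits: Sequence[FitResult]) -> IntensityModel:
    """Rubin-pool parameters across multiply-imputed fits."""
    if len(fits) == 1:
        return fits[0].model
    est = np.stack(
        [np.concatenate([f.model.log_baseline.ravel(), f.model.beta.ravel()])
         for f in fits]
    )
    var = np.stack(
        [np.concatenate([
            np.nan_to_num(f.se_log_baseline.ravel(), nan=0.0) ** 2,
            np.nan_to_num(f.se_beta.ravel(), nan=0.0) ** 2,
        ]) for f in fits]
    )
    pooled = pool_estimates(est, var)["estimate"]
    ref = fits[0].model
    nlb = ref.log_baseline.size
    return IntensityModel(
        structure=ref.structure,
        epochs=ref.epochs,
        log_baseline=pooled[:nlb].reshape(ref.log_baseline.shape),
        beta=pooled[nlb:].reshape(ref.beta.shape),
        covariate_names=ref.covariate_names,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the metrics dict it also writes."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    def fail(stage: str, exc: Exception) -> PipelineError:
        (out / "log.txt").write_text("\n".join(log_lines) + f"\nFAILED: {stage}: {exc}\n")
        return PipelineError(f"stage {stage!r} failed ({out}): {exc}")

    log(f"septraj {__version__} seed={config.seed}")
    sim_cfg = config.simulation or SimulationConfig(
        n_admissions=config.n_admissions, seed=config.seed
    )
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "seed": config.seed,
                "n_admissions": sim_cfg.n_admissions,
                "validation_fraction": config.validation_fraction,
                "m_imputations": config.m_imputations,
                "epochs": list(config.epochs),
                "baseline_covariates": list(config.baseline_covariates),
                "dynamic_covariates": list(config.dynamic_covariates),
                "version": __version__,
            },
            fh,
        )

    try:  # ------------------------------------------------ simulate
        sims, admissions = simulate_cohort(sim_cfg)
        write_cohort(
            admissions,
            out / "patient_days.csv",
            out / "baseline.csv",
            out / "outcomes.csv",
        )
        daily_covs = {s.admission_id: s.daily_covariates for s in sims}
        log(f"simulated {len(admissions)} admissions")
    except Exception as exc:
        raise fail("simulate", exc) from exc

    try:  # ------------------------------------------------ preprocess + impute
        admissions = merge_readmissions(admissions)
        completed, report = impute_cohort(
            admissions, m=config.m_imputations, seed=config.seed
        )
        (out / "imputation.json").write_text(
            json.dumps(dataclasses.asdict(report), indent=2, sort_keys=True)
        )
        log(
            f"missing {report.fraction_missing_before:.3f} -> "
            f"{report.fraction_missing_after_trend:.3f} after trend; m={report.m}"
        )
    except Exception as exc:
        raise fail("impute", exc) from exc

    try:  # ------------------------------------------------ stage + panel
        panel_sets = [
            _stage_to_panels(cohort, daily_covs, config.staging)
            for cohort in completed
        ]
        n_val = int(round(config.validation_fraction * len(admissions)))
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
        order = rng.permutation(len(admissions))
        val_idx = set(order[:n_val].tolist())
        log(f"derivation {len(admissions) - n_val}, validation {n_val}")
    except Exception as exc:
        raise fail("stage", exc) from exc

    covariates = tuple(config.baseline_covariates) + tuple(config.dynamic_covariates)
    try:  # ------------------------------------------------ fit (per imputation, pooled)
        fits_dyn, fits_base = [], []
        for panels in panel_sets:
            deriv = [p for k, p in enumerate(panels) if k not in val_idx]
            fits_dyn.append(
                fit(deriv, covariate_names=covariates, epochs=config.epochs)
            )
            fits_base.append(
                fit(deriv, covariate_names=tuple(config.baseline_covariates),
                    epochs=config.epochs)
            )
        model_dyn = _pooled_model(fits_dyn)
        model_base = _pooled_model(fits_base)
        fit_json = {
            "epochs": list(config.epochs),
            "loglik_per_imputation": [f.loglik for f in fits_dyn],
            "converged": [f.converged for f in fits_dyn],
            "covariates": list(covariates),
            "log_baseline": model_dyn.log_baseline.tolist(),
            "beta": model_dyn.beta.tolist(),
            "not_estimable": [list(p) for p in fits_dyn[0].not_estimable],
        }
        (out / "fit.json").write_text(json.dumps(fit_json, indent=2, sort_keys=True))
        log(f"fitted dynamic model, loglik={fits_dyn[0].loglik:.1f}")
    except Exception as exc:
        raise fail("fit", exc) from exc

    try:  # ------------------------------------------------ evaluate
        metrics: dict = {"seed": config.seed, "version": __version__}
        panels0 = panel_sets[0]
        for name, keep in (
            ("derivation", lambda k: k not in val_idx),
            ("validation", lambda k: k in val_idx),
        ):
            subset = [p for k, p in enumerate(panels0) if keep(k)]
            observed = observed_state_matrix(subset, config.eval_times)
            preds = predict_matrix(model_dyn, subset, config.eval_times, dynamic=True)
            rep = multistate_cstat(
                preds, observed, config.eval_times,
                n_bootstrap=config.n_bootstrap, seed=config.seed,
            )
            brier = compare_models(model_base, model_dyn, subset, config.eval_times)
            metrics[name] = {
                "overall_cstat": rep.overall,
                "cstat_ci": [rep.ci_lower, rep.ci_upper],
                "per_transition_cstat": per_transition_cstat(model_dyn, subset),
                "brier_baseline": brier.brier_baseline,
                "brier_dynamic": brier.brier_dynamic,
                "brier_relative_reduction": brier.relative_reduction,
                "n": len(subset),
            }
        (out / "metrics.json").write_text(
            json.dumps(metrics, indent=2, sort_keys=True, allow_nan=True)
        )
        log("evaluation complete")
    except Exception as exc:
        raise fail("evaluate", exc) from exc

    (out / "log.txt").write_text("\n".join(log_lines) + "\n")
    return metrics
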