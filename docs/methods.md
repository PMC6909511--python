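# Methods

`septraj` models the day-by-day evolution of organ failure in ICU
patients with sepsis.  This note records the model, the staging rules,
the synthetic cohort the package is tested against, and the numerical
choices a maintainer would want to know about.

## Disease states and staging

Each ICU day, seven organ systems (CNS, cardiovascular, respiratory,
renal, coagulation, liver, gastro-intestinal) are classified as
*no / moderate / severe* dysfunction from raw physiology and organ
support, using SOFA-like thresholds extended with symptom-duration
criteria (e.g. hypotension must last > 2 h; refractory shock requires
high-dose vasopressors for > 12 h together with fluid overload and
lactataemia).  Where criteria overlap, the worst satisfied level is
assigned.  Criteria demanding persistence beyond 24 h (prolonged coma,
prolonged oliguria, prolonged food intolerance) are evaluated across
consecutive days — today's duration hours plus yesterday's must exceed
24 — and therefore cannot fire on day 1: a patient cannot be *admitted*
with these failures.

The patient-level stage follows from the organ counts:

| stage | rule |
|---|---|
| at risk | no severe dysfunction and moderate dysfunction in ≤ 2 systems |
| limited organ failure | anything between the other two rows |
| multiple-organ failure (MOF) | severe dysfunction in ≥ 3 systems |

Two boundary readings deserve note.  A profile with ≤ 2 moderate
dysfunctions satisfies the wording of both "at risk" and "limited"; we
resolve to the least severe stage.  A profile with ≥ 4 moderate but
< 3 severe dysfunctions is assigned *limited* organ failure, because
MOF is defined exclusively by the severe count.  The cardiovascular
"lactate > 2 mmol/L" clause is grammatically ambiguous (attached to the
vasopressor list versus standalone); the default requires a concurrent
vasopressor/inotrope infusion, and `StagingConfig(lactate_standalone=True)`
selects the other reading.  All seven organ systems, including the gut,
count equally toward the stage.

## The multi-state model

Patients move among three transient states — at risk (1), limited organ
failure (2), MOF (3) — and two absorbing states, discharge alive (4) and
death in ICU (5).  Direct jumps that skip a severity level (1↔3, 1→5,
3→4) are structural zeros: their rates are fixed at zero and never
estimated.  The remaining eight intensities are piecewise constant over
ICU-day epochs and log-linear in covariates:

    q_ij(t, x) = q0_ij(epoch(t)) · exp(β_ij · x)

The default epochs are [1,3), [3,7) and [7,15] ICU days — an early,
middle and late phase chosen to leave enough events per piece; they are
fully configurable.  The Markov assumption means predictions depend only
on the current state, day and covariate values.

States are observed on a 2-day grid (days 1, 3, …, 15): this *panel*
observation scheme deliberately skips alternate days so that measurements
already contaminated by an incubating transition are not used as
predictors of it.  The transition probability over an interval is the
product of matrix exponentials `exp(Q·dt)` across the epoch segments it
crosses, with covariates held at their interval-start value.  Follow-up
ends at day 15; patients still in ICU then are right-censored.

### Absorbing events

Discharge and death days are completely recorded, but at whole-day
resolution: "death on day d" means death during the 24-hour block
(d−1, d].  The default likelihood term for an absorbing observation is
therefore the probability of absorption *during* that day,

    P_abs(t_k, t_d) − P_abs(t_k, t_d − 1),

not the exact-time transition density Σ_r P_{s_k,r}(t_k, t_d)·q_{r,abs}.
The density form assumes the event time is known to the instant; with
day-level recording it places early deaths at the upper end of their
day, and in recovery experiments (20 replicates of 2000 admissions) it
biased the first-epoch absorbing intensities downward by about 30% with
confidence-interval coverage collapsing below 55%.  The day-censored
form shows |relative bias| ≤ 3% and ~97% coverage under the same
conditions.  `absorbing_exact="density"` retains the exact-time form
for sensitivity analyses, and `absorbing_exact=False` falls back to
plain panel terms.

### Estimation

The panel likelihood is maximised over (log q0, β) by L-BFGS-B with an
analytic score: the derivative of each `exp(Q·dt)` is evaluated with the
eigendecomposition form of the Fréchet derivative and chain-ruled
through the log-linear intensities; tasks whose eigenbasis is
ill-conditioned (reconstruction error > 1e-8) fall back to
`scipy.linalg.expm_frechet`.  Intervals are grouped by unique
(covariate vector, epoch segmentation), so covariate-free fits need only
a handful of matrix exponentials per evaluation.  Standard errors come
from the inverse observed information, computed by central differences
of the analytic score.  Log-parameterisation keeps intensities positive;
box bounds of [−12, 2.5] on log-intensities and ±6 on β stabilise the
search, and a score-weight floor of 1e-10 keeps gradients finite at
extreme trial points so the line search can recover.  Convergence uses a
relative log-likelihood tolerance of 1e-10 and a projected-gradient
tolerance of 1e-6; non-convergence is flagged on the result, never
raised.

A transition with no directly observed panel pair is not estimable from
the data; its baseline log-intensity is pinned at a floor (rate
1e-8/day) with a warning and reported in `FitResult.not_estimable`.
Covariate effects for pinned transitions are fixed at zero.

### Prediction

`occupation_probs` returns the full 5-state occupation vector for every
day up to 15, from any transient state and day, with covariates carried
forward; a scenario map can replace covariate values from future days
(e.g. "vasopressors stop at day 3") to produce improvement/worsening
forecasts.  `update_prediction` re-predicts from the latest observation;
by the Markov property history beyond the current state is ignored.
Predictions from an absorbing state return the degenerate surface.

## Missing data

Daily labs are completed in two stages before staging:

1. **Trend imputation** fills gaps of ≤ 2 days per variable per patient
   by linear extrapolation of the last two observed values (clamped at
   physiologic floors; after a single observation the value is carried
   forward).  Longer runs and leading gaps remain missing.
2. **Chained-equations multiple imputation** (default m = 5) completes
   the rest: Bayesian-linear-regression posterior-predictive draws for
   continuous variables, logistic draws for binaries, five cycles, all
   daily variables plus the day index as predictors.  Column
   standardisation and ridge-stabilised normal equations make the draws
   robust to collinear or near-constant predictors.  Entirely-missing
   columns are excluded with a warning.

Imputation precedes staging because the staging rules need complete
per-day fields; anything still missing at staging time is treated as
"criterion not met".  Fits on the m completed datasets are combined by
Rubin's rules (pooled point = mean; total variance = mean within +
(1 + 1/m) × between, Barnard–Rubin degrees of freedom for intervals).

## Screening and evaluation

Univariable screening fits each candidate predictor alone on all eight
transitions and keeps predictors whose smallest Wald p-value is < 0.10
(strict); no stepwise selection follows.  Separated or non-converged
fits are flagged rather than silently reported.

Discrimination uses a multi-state concordance statistic computed from
predicted occupation probabilities: for each ordered state pair (i, j)
and evaluation time, the fraction of patients observed in i whose
predicted P(i) exceeds their P(j), ties counting one half; the two
directions of a pair are averaged, then pairs and times are averaged
uniformly (a `weight_by_at_risk`-style weighting was considered and
rejected as the less conventional reading; times enter unweighted).
Confidence intervals come from a patient-level bootstrap (default 200
resamples).  Accuracy uses the multi-category Brier score, the mean
squared distance between the 5-state forecast and the one-hot observed
state; a uniform forecast scores 0.8 on five states.

`compare_models` contrasts a baseline-information-only model (predicting
every horizon from day 1) against a dynamic model re-applied at each
grid day with the current state and time-varying covariates — the same
patient-time set for both, with absorbing states persisting as observed
outcomes.  The per-transition concordance evaluates predicted 2-day
transition probabilities on the regular grid only, because mixing
grid intervals with shorter exact-day absorbing intervals deflates the
statistic artifactually.

## The synthetic cohort

No public data accompany the study design this package implements, so a
generator produces cohorts with known ground truth.  Its defaults are
the study conditions: 1371 admissions mixing 4% / 84% / 12% across the
three severity states on day 1; continuous-time trajectories driven by
the same log-linear intensity family the estimator fits (making
parameter recovery well-posed); 17% overall missingness in daily labs
with a strongly skewed per-variable profile (a handful of
sparingly-ordered labs — APTT, albumin, transaminases, lactate — carry
most of it, while vital signs stay nearly complete); and rare
palliative-care censoring (~0.8% of
admissions are discharged alive after an end-of-life decision; their
observation time is censored from that day, while deaths are never
censored).

Baseline intensities were calibrated — by matrix-exponential occupancy
calculations, before any estimator code ran — so the marginal 14-day
flows match the published cohort: of limited-organ-failure admissions
~17% progress or die and ~70% improve or leave; of MOF admissions ~40%
die and ~54% improve; day-14 mortality ~18%.  The frozen values are
(per day) q12 = 0.10, q14 = 0.12, q21 = 0.04, q23 = 0.028, q24 = 0.088,
q25 = 0.017, q32 = 0.16, q35 = 0.080, with early-phase multipliers 1.3–1.4
on progression and death and late-phase multipliers 1.2 on recovery and
discharge (0.7–0.8 on progression/death).  Each transition's baseline is
compensated by its expected covariate multiplier so these marginals
survive the covariate effects.

Covariates: baseline predisposition and infection-site variables with
Table-3-like prevalences; CRP as a state-linked log-normal AR(1)
(state-wise medians 118/189/225 mg/L, ρ = 0.7); WBC log-normal; and five
binary clinical events (fever, new-onset AF, ICU-acquired infection,
bacteremia, corticosteroids) as two-state Markov processes with
state-linked onset and multi-day persistence — infections and treatment
courses last days, and a memoryless daily redraw would make them nearly
invisible to 2-day panel intervals.  Four covariates (sex,
cardiovascular disease, diabetes, hospital acquisition) carry zero true
effect so screening has genuine negatives to reject.

Raw patient-day records are emitted by inverting the staging rules: for
each day an organ-level profile compatible with the latent stage is
drawn, then values are written that fire exactly those criteria.
Severe levels are emitted only through single-day criteria
(cardiovascular, respiratory, renal, coagulation, liver), because CNS
and gut severe failure require cross-day persistence; staging the
emitted records reproduces the latent stage on 100% of patient-days,
which anchors the whole pipeline's correctness.

What the generator does *not* emulate: joint covariate correlations
beyond these marginals, measurement error in the staging inputs,
informative (non-MCAR) missingness, readmission dynamics, or
between-centre heterogeneity.  Green tests therefore demonstrate
internal consistency and estimator correctness under the stated
conditions, not clinical validity on real ICU data.

## Known limitations

* Time-varying covariate effects estimated from 2-day panels are
  attenuated relative to the daily-acting truth (the interval holds the
  left-endpoint value while the generator updates covariates daily);
  time-fixed effects recover essentially unbiased.  This is inherent to
  panel observation, not a defect of the optimiser.
* The covariate-marginal compensation is exact only under independent
  covariates; residual shifts of a point or two in the flow fractions
  remain.
* Epoch cut-points are assumed known; they are configurable but not
  selected from data.
* No frailty, semi-Markov, or state-misclassification extensions.

## Problem sizes used in the test suite

The default suite simulates cohorts of 150–3000 admissions and runs the
parameter-recovery check at 8 replicates of 1500 admissions; the
acceptance script uses 10 replicates of 2000 admissions and a 900-
admission end-to-end pipeline run.  These sizes give Monte-Carlo noise
comfortably inside the asserted tolerances while keeping a full run in
the minutes range on one CPU.
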