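"""Published derivation-cohort flow counts and the percentages they imply.

The original two-centre sepsis cohort is not publicly deposited, but
its study-flow counts are published and serve two purposes here: they
fix the synthetic generator's marginal targets, and the percentage
arithmetic can be recomputed as a self-check.
"""

from __future__ import annotations

#: Study-population flow counts of the derivation cohort.
DERIVATION_FLOW: dict[str, int] = {
    "admissions": 1371,
    "patients": 1251,
    "observation_days": 10891,
    "at_risk_at_admission": 53,
    "limited_of_at_admission": 1151,
    "mof_at_admission": 167,
    "limited_worse_by_day14": 197,      # progressed to MOF or died
    "limited_same_by_day14": 145,
    "limited_better_by_day14": 809,     # improved or discharged alive
    "mof_died_by_day14": 67,
    "mof_better_by_day14": 91,
    "at_risk_discharged_by_day14": 38,
    "at_risk_died": 5,
    "deaths_by_day14": 252,
    "deaths_total": 320,
    "palliative_discharged_alive": 11,
    "observation_days_excluded": 22,
}

#: Validation-cohort counts (admission mix and mortality).
VALIDATION_FLOW: dict[str, int] = {
    "patients": 553,
    "at_risk_at_admission": 14,
    "limited_of_at_admission": 484,
    "mof_at_admission": 55,
    "deaths_by_day14": 91,
    "deaths_total": 129,
}


def percentage(numerator: float, denominator: float, ndigits: int = 0) -> float:
    """Percent of ``numerator`` in ``denominator``, rounded as printed."""
    if denominator == 0:
        raise ZeroDivisionError("empty denominator")
    return round(100.0 * numerator / denominator, ndigits)


def flow_percentages(counts: dict[str, int] | None = None) -> dict[str, float]:
    """Recompute the cohort flow percentages from the raw counts."""
    c = counts or DERIVATION_FLOW
    n = c["admissions"]
    return {
        "admission_pct_at_risk": percentage(c["at_risk_at_admission"], n),
        "admission_pct_limited_of": percentage(c["limited_of_at_admission"], n),
        "admission_pct_mof": percentage(c["mof_at_admission"], n),
        "limited_pct_worse_by_day14": percentage(
            c["limited_worse_by_day14"], c["limited_of_at_admission"]
        ),
        "limited_pct_same_by_day14": percentage(
            c["limited_same_by_day14"], c["limited_of_at_admission"]
        ),
        "limited_pct_better_by_day14": percentage(
            c["limited_better_by_day14"], c["limited_of_at_admission"]
        ),
        "mof_pct_died_by_day14": percentage(
            c["mof_died_by_day14"], c["mof_at_admission"]
        ),
        "mof_pct_better_by_day14": percentage(
            c["mof_better_by_day14"], c["mof_at_admission"]
        ),
        "at_risk_pct_discharged_by_day14": percentage(
            c["at_risk_discharged_by_day14"], c["at_risk_at_admission"]
        ),
        "at_risk_pct_died": percentage(c["at_risk_died"], c["at_risk_at_admission"]),
        "pct_mortality_day14": percentage(c["deaths_by_day14"], n),
        "pct_mortality_total": percentage(c["deaths_total"], n),
        "pct_palliative_discharged": percentage(
            c["palliative_discharged_alive"], n, ndigits=2
        ),
    }
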