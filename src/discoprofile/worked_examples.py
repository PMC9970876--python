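"""Worked examples from reported profile-comparison estimates.

Reported per-profile estimates (point value and 95% CI per allele) for traits
where the concordant and discordant obesity/T2D profiles separate, taken from
the published phenome-wide comparison this package reimplements.  They serve
as fixed inputs for recomputing the between-profile δ-test: standard errors
are recovered as CI width / (2 × 1.96), on the log scale for odds ratios, and
δ = |β_C − β_D| is referred to a two-sided z-test.
"""

from __future__ import annotations

from dataclasses import dataclass

from .grs_individual import compare_estimates, estimate_from_ci


@dataclass(frozen=True)
class ReportedComparison:
    """One trait's published per-profile estimates with 95% CIs."""

    trait: str
    source: str
    ratio_scale: bool  # True when the report is an OR/HR
    c_point: float
    c_lo: float
    c_hi: float
    d_point: float
    d_lo: float
    d_hi: float
    reported_p_delta: float


#: per-allele effects; continuous traits in s.d. units, diseases as ORs
REPORTED = {
    "sbp": ReportedComparison(
        "systolic blood pressure", "summary phenome scan", False,
        0.002, -0.001, 0.004, -0.008, -0.012, -0.004, 1.39e-4,
    ),
    "chd": ReportedComparison(
        "coronary heart disease", "summary phenome scan", True,
        1.01, 1.01, 1.02, 0.98, 0.97, 0.99, 1.3e-6,
    ),
    "hypertension": ReportedComparison(
        "essential hypertension", "BioVU PheWAS", True,
        1.014, 1.009, 1.019, 0.99, 0.98, 0.99, 1.2e-6,
    ),
    "ckd": ReportedComparison(
        "chronic kidney disease", "BioVU PheWAS", True,
        1.02, 1.01, 1.02, 0.98, 0.97, 0.99, 2.9e-6,
    ),
}


def recompute_delta_p(key: str) -> float:
    """δ-test p-value recomputed from the reported estimates and CIs."""
    r = REPORTED[key]
    est_c = estimate_from_ci(r.trait, "C", r.c_point, r.c_lo, r.c_hi, r.ratio_scale)
    est_d = estimate_from_ci(r.trait, "D", r.d_point, r.d_lo, r.d_hi, r.ratio_scale)
    return compare_estimates(est_c, est_d).p
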