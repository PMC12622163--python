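"""Decomposition of the observed accuracy loss.

LoA(LD+MAF) = (1 - RA_expected) / (1 - RA_obs) x 100% is the share of the
observed loss of PGI accuracy explained by cross-population LD and MAF
differences; multiplying RA_expected by the target-to-reference
SNP-heritability ratio gives the LD+MAF+h² variant.  Standard errors are
propagated with the delta method treating RA_obs and RA_expected as
independent (they derive from disjoint data: target-cohort regressions vs
reference-panel LD with discovery betas); values above 100% are reported
as computed, never truncated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .accuracy import RAEstimate

__all__ = [
    "LoAEstimate",
    "gate_phenotypes",
    "compute_loa",
    "adjust_for_h2",
    "loa_se_delta",
    "cross_cohort_test",
]


@dataclass
class LoAEstimate:
    phenotype: str
    ancestry: str
    cohort: str
    variant: str  # "ld_maf" or "ld_maf_h2"
    ra_obs: float
    ra_expected: float
    loa_percent: float
    se: float
    ci_low: float
    ci_high: float


def gate_phenotypes(ra_estimates: list[RAEstimate]) -> list[RAEstimate]:
    """Retain pairs whose RA_obs is statistically smaller than one.

    Implemented as: upper bound of the 95% percentile bootstrap CI < 1.
    """
    return [ra for ra in ra_estimates if ra.ci_high < 1.0]


def compute_loa(ra_obs: float, ra_expected: float) -> float:
    """(1 - RA_expected) / (1 - RA_obs) x 100, defined only for RA_obs < 1."""
    if ra_obs >= 1.0:
        raise ValueError("LoA undefined for RA_obs >= 1 (gate violated)")
    return (1.0 - ra_expected) / (1.0 - ra_obs) * 100.0


def adjust_for_h2(ra_expected: float, h2_target: float, h2_ref: float,
                  se_expected: float = 0.0, se_h2_target: float = 0.0,
                  se_h2_ref: float = 0.0) -> tuple[float, float]:
    """Scale RA_expected by the target/reference SNP-heritability ratio.

    Returns ``(adjusted, se)`` with the SE propagated by the delta method
    treating the three inputs as independent.
    """
    if h2_ref <= 0:
        raise ValueError("reference heritability must be > 0")
    ratio = h2_target / h2_ref
    adjusted = ra_expected * ratio
    if adjusted == 0:
        return 0.0, abs(ratio) * se_expected
    rel = 0.0
    if ra_expected != 0:
        rel += (se_expected / ra_expected) ** 2
    if h2_target != 0:
        rel += (se_h2_target / h2_target) ** 2
    rel += (se_h2_ref / h2_ref) ** 2
    return float(adjusted), float(abs(adjusted) * np.sqrt(rel))


def loa_se_delta(ra_obs: float, se_obs: float, ra_expected: float,
                 se_expected: float) -> float:
    """Delta-method SE of LoA percent, RA_obs and RA_expected independent."""
    if ra_obs >= 1.0:
        raise ValueError("LoA undefined for RA_obs >= 1")
    if se_obs < 0 or se_expected < 0:
        raise ValueError("standard errors must be >= 0")
    d = 1.0 - ra_obs
    return 100.0 * float(np.sqrt(
        (se_expected / d) ** 2 + ((1.0 - ra_expected) * se_obs / d ** 2) ** 2))


def make_loa_estimate(phenotype: str, ancestry: str, cohort: str, variant: str,
                      ra_obs: float, se_obs: float,
                      ra_expected: float, se_expected: float) -> LoAEstimate:
    """Assemble a LoA estimate with delta-method SE and normal 95% CI."""
    loa = compute_loa(ra_obs, ra_expected)
    se = loa_se_delta(ra_obs, se_obs, ra_expected, se_expected)
    return LoAEstimate(phenotype=phenotype, ancestry=ancestry, cohort=cohort,
                       variant=variant, ra_obs=ra_obs, ra_expected=ra_expected,
                       loa_percent=loa, se=se,
                       ci_low=loa - 1.96 * se, ci_high=loa + 1.96 * se)


def cross_cohort_test(loa_a: LoAEstimate, loa_b: LoAEstimate) -> tuple[float, float]:
    """Log-scale Z test for a cohort difference in LoA.

    z = (ln LoA_a - ln LoA_b) / sqrt((se_a/LoA_a)² + (se_b/LoA_b)²);
    two-sided p.  Non-positive LoA values are rejected (excluded upstream).
    """
    for est in (loa_a, loa_b):
        if est.loa_percent <= 0:
            raise ValueError("log-scale comparison needs positive LoA")
    denom = np.sqrt((loa_a.se / loa_a.loa_percent) ** 2
                    + (loa_b.se / loa_b.loa_percent) ** 2)
    if denom == 0:
        z = 0.0 if loa_a.loa_percent == loa_b.loa_percent else np.inf
    else:
        z = (np.log(loa_a.loa_percent) - np.log(loa_b.loa_percent)) / denom
    p = float(2 * stats.norm.sf(abs(z)))
    return float(z), p
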