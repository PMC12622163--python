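"""Small genetic-statistics utilities shared across modules."""

from __future__ import annotations

import numpy as np

__all__ = ["hwe_exact_pvalue", "hwe_exact_pvalues"]


def _hwe_pvalue(n_het: int, n_hom_rare: int, n_hom_common: int,
                logfact: np.ndarray) -> float:
    n = n_het + n_hom_rare + n_hom_common
    if n == 0:
        return 1.0
    n_rare = 2 * n_hom_rare + n_het
    n_rare = min(n_rare, 2 * n - n_rare)
    if n_rare == 0:
        return 1.0
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_r = (n_rare - hets) // 2
    hom_c = n - hets - hom_r
    logp = (
        logfact[n] - logfact[hom_r] - logfact[hets] - logfact[hom_c]
        + hets * np.log(2.0)
        + logfact[n_rare] + logfact[2 * n - n_rare] - logfact[2 * n]
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = prob[hets == n_het]
    if obs.size == 0:  # inconsistent het count (should not happen with hard calls)
        return 1.0
    return float(prob[prob <= obs[0] * (1 + 1e-12)].sum())


def hwe_exact_pvalue(n_het: int, n_hom_rare: int, n_hom_common: int) -> float:
    """Exact Hardy-Weinberg test p-value for one biallelic variant.

    Sums the probabilities of all heterozygote counts (given the allele
    counts) no more likely than the observed one.
    """
    n = n_het + n_hom_rare + n_hom_common
    logfact = _log_factorials(2 * n)
    return _hwe_pvalue(n_het, n_hom_rare, n_hom_common, logfact)


def _log_factorials(n_max: int) -> np.ndarray:
    return np.concatenate([[0.0], np.cumsum(np.log(np.arange(1, n_max + 1)))])


def hwe_exact_pvalues(hard_dosages: np.ndarray) -> np.ndarray:
    """Exact HWE p-value per variant column; NaN entries are ignored."""
    x = np.asarray(hard_dosages, dtype=float)
    nan = np.isnan(x)
    n2 = ((x == 2) & ~nan).sum(axis=0)
    n1 = ((x == 1) & ~nan).sum(axis=0)
    n0 = ((x == 0) & ~nan).sum(axis=0)
    logfact = _log_factorials(2 * x.shape[0])
    out = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        hom_rare, hom_common = (n2[j], n0[j]) if n2[j] <= n0[j] else (n0[j], n2[j])
        out[j] = _hwe_pvalue(int(n1[j]), int(hom_rare), int(hom_common), logfact)
    return out
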