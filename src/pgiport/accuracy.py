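"""Observed relative accuracy and its resampling / inference machinery.

The portability of a PGI is measured by incremental R² — the gain in the
coefficient of determination when the PGI is added to a covariate-only
regression — and by the observed relative accuracy

    RA_obs = R²(target ancestry) / R²(reference ancestry),

with percentile-bootstrap confidence intervals (individuals resampled with
replacement within each ancestry group independently), a paired bootstrap
test for comparing two PGIs scored on the same samples, leave-one-phenotype-
out jackknife summaries, Welch's heteroscedastic ANOVA across groups, and
Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RAEstimate",
    "GroupSummary",
    "incremental_r2",
    "relative_accuracy",
    "bootstrap_ci",
    "ra_observed",
    "paired_bootstrap_ra_test",
    "jackknife_mean_se",
    "welch_anova",
    "bh_adjust",
]


@dataclass
class RAEstimate:
    phenotype: str
    ancestry: str
    r2_ref: float
    r2_target: float
    ra_obs: float
    ci_low: float
    ci_high: float
    n_target: int
    n_ref: int
    B: int
    se: float = float("nan")


@dataclass
class GroupSummary:
    group: str
    mean: float
    se_jackknife: float
    n_phenotypes: int


# ---------------------------------------------------------------------------
# Incremental R²
# ---------------------------------------------------------------------------

def _r2(y: np.ndarray, X: np.ndarray | None) -> float:
    """R² of an OLS fit of y on [1, X]."""
    y = np.asarray(y, dtype=float)
    yc = y - y.mean()
    tss = yc @ yc
    if tss == 0:
        return 0.0
    if X is None or X.size == 0:
        return 0.0
    Xc = X - X.mean(axis=0)
    coef, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    resid = yc - Xc @ coef
    return float(1.0 - (resid @ resid) / tss)


def incremental_r2(y: np.ndarray, pgi: np.ndarray, covars: np.ndarray | None = None) -> float:
    """R²(y ~ covars + PGI) - R²(y ~ covars); may be negative by noise."""
    y = np.asarray(y, dtype=float)
    pgi = np.asarray(pgi, dtype=float).reshape(-1, 1)
    if covars is not None:
        covars = np.asarray(covars, dtype=float)
        if covars.ndim == 1:
            covars = covars.reshape(-1, 1)
        if covars.shape[1]:
            rank = np.linalg.matrix_rank(covars - covars.mean(axis=0))
            if rank < covars.shape[1]:
                raise ValueError(
                    f"rank-deficient covariate matrix: rank {rank} < {covars.shape[1]} columns")
        full = np.hstack([covars, pgi])
        return _r2(y, full) - _r2(y, covars)
    return _r2(y, pgi)


def relative_accuracy(r2_target: float, r2_ref: float) -> float:
    """Ratio of target-ancestry to reference-ancestry incremental R²."""
    if r2_ref <= 0:
        raise ValueError("relative accuracy undefined: reference incremental R² <= 0")
    return r2_target / r2_ref


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ci(data, statistic, B: int = 1000, seed: int = 0):
    """Percentile bootstrap of ``statistic`` over per-sample records.

    ``data`` is either an array-like (single group) or a dict of group
    label -> array-like; groups are resampled independently.  The statistic
    receives the resampled data in the same shape it was given.  Returns
    ``(estimate, ci_low, ci_high)`` at the 2.5th / 97.5th percentiles.
    Replicates where the statistic is undefined (raises ``ValueError`` or
    returns NaN) are dropped; if more than 10% are undefined the CI is
    still reported over the defined ones.
    """
    rng = np.random.default_rng(seed)
    grouped = isinstance(data, dict)
    groups = {k: np.asarray(v) for k, v in data.items()} if grouped else {None: np.asarray(data)}
    estimate = statistic(data)
    reps = np.full(B, np.nan)
    for b in range(B):
        resampled = {}
        for k, v in groups.items():
            n = v.shape[0]
            resampled[k] = v[rng.integers(0, n, size=n)]
        try:
            reps[b] = statistic(resampled if grouped else resampled[None])
        except ValueError:
            continue
    ok = reps[~np.isnan(reps)]
    if ok.size == 0:
        raise ValueError("statistic undefined in every bootstrap replicate")
    lo, hi = np.percentile(ok, [2.5, 97.5])
    return float(estimate), float(lo), float(hi)


def _resampled_ra(y_ref, pgi_ref, y_tar, pgi_tar, covars_ref, covars_tar, i_ref, i_tar):
    r2r = incremental_r2(y_ref[i_ref], pgi_ref[i_ref],
                         None if covars_ref is None else covars_ref[i_ref])
    r2t = incremental_r2(y_tar[i_tar], pgi_tar[i_tar],
                         None if covars_tar is None else covars_tar[i_tar])
    if r2r <= 0:
        return np.nan
    return r2t / r2r


def ra_observed(
    y_ref, pgi_ref, y_target, pgi_target,
    covars_ref=None, covars_target=None,
    phenotype: str = "trait", ancestry: str = "target",
    B: int = 1000, seed: int = 0,
) -> RAEstimate:
    """RA_obs with a percentile bootstrap CI.

    Reference- and target-ancestry individuals are resampled independently
    (the two incremental R² come from disjoint samples).  Negative
    incremental R² in a replicate propagates into the RA replicate
    unmodified, so CIs can include negative values.
    """
    y_ref, pgi_ref = np.asarray(y_ref, float), np.asarray(pgi_ref, float)
    y_tar, pgi_tar = np.asarray(y_target, float), np.asarray(pgi_target, float)
    r2_ref = incremental_r2(y_ref, pgi_ref, covars_ref)
    r2_tar = incremental_r2(y_tar, pgi_tar, covars_target)
    ra = relative_accuracy(r2_tar, r2_ref)
    rng = np.random.default_rng(seed)
    nr, nt = len(y_ref), len(y_tar)
    reps = np.full(B, np.nan)
    for b in range(B):
        i_ref = rng.integers(0, nr, size=nr)
        i_tar = rng.integers(0, nt, size=nt)
        reps[b] = _resampled_ra(y_ref, pgi_ref, y_tar, pgi_tar,
                                covars_ref, covars_target, i_ref, i_tar)
    ok = reps[~np.isnan(reps)]
    lo, hi = np.percentile(ok, [2.5, 97.5])
    return RAEstimate(phenotype=phenotype, ancestry=ancestry,
                      r2_ref=r2_ref, r2_target=r2_tar, ra_obs=ra,
                      ci_low=float(lo), ci_high=float(hi),
                      n_target=nt, n_ref=nr, B=B, se=float(ok.std(ddof=1)))


def paired_bootstrap_ra_test(
    y_ref, pgi_ref_a, pgi_ref_b, y_target, pgi_target_a, pgi_target_b,
    covars_ref=None, covars_target=None, B: int = 1000, seed: int = 0,
):
    """Paired nonparametric bootstrap test for a difference in RA_obs.

    Both PGIs (a and b, e.g. standard vs family-based) are scored on the
    same individuals; each replicate resamples the *same* individuals for
    both and records the RA difference a - b.  Two-sided
    p = 2 min(frac <= 0, frac >= 0), clamped to [2/B, 1].
    """
    arrays = [np.asarray(v, float) for v in
              (y_ref, pgi_ref_a, pgi_ref_b, y_target, pgi_target_a, pgi_target_b)]
    y_ref, pa_ref, pb_ref, y_tar, pa_tar, pb_tar = arrays
    ra_a = relative_accuracy(incremental_r2(y_tar, pa_tar, covars_target),
                             incremental_r2(y_ref, pa_ref, covars_ref))
    ra_b = relative_accuracy(incremental_r2(y_tar, pb_tar, covars_target),
                             incremental_r2(y_ref, pb_ref, covars_ref))
    delta = ra_a - ra_b
    rng = np.random.default_rng(seed)
    nr, nt = len(y_ref), len(y_tar)
    deltas = np.full(B, np.nan)
    for b in range(B):
        i_ref = rng.integers(0, nr, size=nr)
        i_tar = rng.integers(0, nt, size=nt)
        rep_a = _resampled_ra(y_ref, pa_ref, y_tar, pa_tar, covars_ref, covars_target, i_ref, i_tar)
        rep_b = _resampled_ra(y_ref, pb_ref, y_tar, pb_tar, covars_ref, covars_target, i_ref, i_tar)
        deltas[b] = rep_a - rep_b
    ok = deltas[~np.isnan(deltas)]
    p = 2 * min((ok <= 0).mean(), (ok >= 0).mean())
    p = float(np.clip(p, 2.0 / B, 1.0))
    return float(delta), p


# ---------------------------------------------------------------------------
# Summaries and tests
# ---------------------------------------------------------------------------

def jackknife_mean_se(values, group: str = "all") -> GroupSummary:
    """Leave-one-out jackknife SE of the mean across phenotypes."""
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise ValueError("jackknife requires at least 2 values")
    total = v.sum()
    loo = (total - v) / (n - 1)
    se = np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2))
    return GroupSummary(group=group, mean=float(v.mean()), se_jackknife=float(se),
                        n_phenotypes=n)


def welch_anova(groups):
    """Welch's heteroscedastic F test with Satterthwaite denominator df.

    Returns ``(F, df1, df2, p)``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    n = np.array([g.size for g in groups])
    if (n < 2).any():
        raise ValueError("each group needs n >= 2")
    var = np.array([g.var(ddof=1) for g in groups])
    if (var == 0).any():
        raise ValueError("zero-variance group")
    mean = np.array([g.mean() for g in groups])
    w = n / var
    sw = w.sum()
    grand = (w * mean).sum() / sw
    num = ((w * (mean - grand) ** 2).sum()) / (k - 1)
    tmp = ((1 - w / sw) ** 2 / (n - 1)).sum() / (k ** 2 - 1)
    den = 1 + 2 * (k - 2) * tmp
    F = num / den
    df1 = k - 1
    df2 = 1.0 / (3 * tmp)
    p = float(stats.f.sf(F, df1, df2))
    return float(F), float(df1), float(df2), p


def bh_adjust(pvals, fdr: float = 0.05):
    """Benjamini-Hochberg step-up: adjusted p-values and rejection flags."""
    pvals = np.asarray(pvals, dtype=float)
    reject, p_adj, *_ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    return p_adj, reject
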