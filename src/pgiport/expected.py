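"""Expected relative accuracy from cross-population LD and MAF differences.

The model predicts the target-to-reference ratio of PGI predictive accuracy
as the product of three factors:

* an effects factor rho_b² h2²/h1² (cross-population causal-effect
  correlation and heritability ratio; defaults to 1),
* an LD/MAF transfer factor
  [ sum_k r̄(k,1)r(k,2) sqrt(p(k,2)q(k,2) / p(k,1)q(k,1)) ]² /
  [ sum_k r̄²(k,1) ]²,
* a variance-scale factor sum_k p(k,1)q(k,1) β̂k² / sum_k p(k,2)q(k,2) β̂k²,

where the sums run over the PGI-SNPs k with at least one candidate causal
SNP in-window, r̄²(k,1) is the mean squared allele-count correlation between
SNP k and its candidate causal SNPs in the reference population,
r̄(k,1)r(k,2) the mean product of those correlations across the two
populations, p(k,i) the minor allele frequency in population i, and β̂k the
discovery-GWAS marginal effect.  The outer squares on both LD sums are the
bracketing that reproduces the exact one-SNP-predictor R² ratio in a
single-tag/single-causal system (see docs/methods.md).

PGI-SNPs are the index SNPs of a greedy p-value-ordered LD clumping
(2,000 kb window, r² > 0.01, p < 0.5), taken at top-100 / 1,000 / 10,000
set sizes; candidate causal SNPs are QC-passing variants within 100 kb of
an index SNP with r² > 0.45 to it in the reference population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypePanel
from .gstats import hwe_exact_pvalues

__all__ = [
    "LDReference",
    "TopSnpSet",
    "CandidateCausalSet",
    "ExpectedRA",
    "clump",
    "qc_common_snps",
    "select_candidate_causal",
    "ld_summaries",
    "expected_ra",
    "stability_curve",
]

DEFAULT_SET_SIZES = (100, 1000, 10000)


@dataclass
class TopSnpSet:
    """Clump index variants ordered by ascending p, with clump membership."""

    index_ids: list[str]
    clumps: dict[str, list[str]]
    set_sizes: tuple[int, ...] = DEFAULT_SET_SIZES

    def top(self, k: int) -> list[str]:
        return self.index_ids[:k]


@dataclass
class CandidateCausalSet:
    """Per index variant: candidate causal SNP ids and their r² to it."""

    candidates: dict[str, list[str]]
    r2: dict[str, np.ndarray]

    def pooled_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for ids in self.candidates.values():
            for vid in ids:
                seen[vid] = None
        return list(seen)


@dataclass
class ExpectedRA:
    factor_effects: float
    factor_ld_maf: float
    factor_varscale: float
    ra_expected: float
    snp_set_size: int
    M_T: int


class LDReference:
    """Cached standardized dosages + positions for fast windowed correlations.

    Build once per reference panel and pass to :func:`clump`,
    :func:`select_candidate_causal` and :func:`ld_summaries` to avoid
    re-standardizing the dosage matrix.
    """

    def __init__(self, panel: GenotypePanel):
        self.panel = panel
        x = panel.imputed_dosages()
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        self.z = (x - mu) / sd
        self.n = x.shape[0]
        self.ids = panel.variants["id"].to_numpy()
        self.chrom = panel.variants["chrom"].to_numpy()
        self.pos = panel.variants["pos"].to_numpy()
        self.id_to_idx = {v: i for i, v in enumerate(self.ids)}

    def window(self, j: int, window_bp: int) -> np.ndarray:
        """Indices on the same chromosome within +/- window_bp (inclusive)."""
        same = self.chrom == self.chrom[j]
        near = np.abs(self.pos - self.pos[j]) <= window_bp
        return np.where(same & near)[0]

    def corr(self, j: int, cols: np.ndarray) -> np.ndarray:
        return (self.z[:, cols].T @ self.z[:, j]) / self.n


def _as_ref(reference) -> LDReference:
    return reference if isinstance(reference, LDReference) else LDReference(reference)


# ---------------------------------------------------------------------------
# Clumping
# ---------------------------------------------------------------------------

def clump(
    sumstats: pd.DataFrame,
    reference: GenotypePanel,
    window_kb: float = 2000,
    r2_min: float = 0.01,
    p_max: float = 0.5,
    set_sizes: tuple[int, ...] = DEFAULT_SET_SIZES,
    max_indices: int | None = None,
) -> TopSnpSet:
    """Greedy p-value-ordered LD clumping against a reference panel.

    The lowest-p unassigned variant becomes an index; every unassigned
    variant with p < ``p_max`` within ``window_kb`` and r² > ``r2_min`` to
    it joins its clump; repeat until no p < ``p_max`` variant remains.
    ``max_indices`` stops early once that many index SNPs are found (the
    top-K index set is unchanged by early stopping because indices emerge
    in ascending p order).  ``reference`` may be a panel or a prebuilt
    :class:`LDReference`.
    """
    ref = _as_ref(reference)
    m = len(ref.ids)
    pvals = np.full(m, np.inf)  # variants absent from sumstats never clump
    loc = pd.Index(ref.ids).get_indexer(pd.Index(sumstats["id"]))
    pvals[loc[loc >= 0]] = sumstats["pval"].to_numpy(dtype=float)[loc >= 0]
    order = np.argsort(pvals, kind="stable")
    assigned = np.zeros(m, dtype=bool)
    eligible = pvals < p_max
    window_bp = int(window_kb * 1000)
    index_ids: list[str] = []
    clumps: dict[str, list[str]] = {}
    limit = max_indices if max_indices is not None else (max(set_sizes) if set_sizes else m)
    for j in order:
        if assigned[j] or not eligible[j]:
            if not np.isfinite(pvals[j]):
                break  # sorted order: only absent-from-sumstats variants remain
            continue
        assigned[j] = True
        vid = ref.ids[j]
        near = ref.window(j, window_bp)
        near = near[~assigned[near] & eligible[near]]
        members = []
        if near.size:
            r2 = ref.corr(j, near) ** 2
            members = near[r2 > r2_min]
            assigned[members] = True
            members = list(ref.ids[members])
        index_ids.append(vid)
        clumps[vid] = members
        if len(index_ids) >= limit:
            break
    if set_sizes and len(index_ids) < min(set_sizes):
        import warnings

        warnings.warn(
            f"only {len(index_ids)} index variants; smaller top sets will be returned")
    return TopSnpSet(index_ids=index_ids, clumps=clumps, set_sizes=tuple(set_sizes))


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_common_snps(
    panels: dict[str, GenotypePanel],
    call_rate_min: float = 0.95,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-10,
    sample_missing_max: float = 0.01,
) -> list[str]:
    """Variants passing, in every population: call rate, MAF and HWE filters.

    Sample-level missingness >= ``sample_missing_max`` is applied per
    population first; the HWE exact test uses hard calls (rounded dosages).
    """
    if len(panels) < 2:
        raise ValueError("need at least 2 populations")
    keep: pd.Index | None = None
    for name, panel in panels.items():
        ok_samples = panel.sample_missingness() < sample_missing_max
        sub = panel.subset(sample_mask=ok_samples)
        passing = (
            (sub.call_rate() > call_rate_min)
            & (sub.maf() > maf_min)
            & (hwe_exact_pvalues(np.rint(sub.dosages)) > hwe_p_min)
        )
        ids = pd.Index(sub.variants["id"][passing])
        keep = ids if keep is None else keep.intersection(ids)
    if keep is None or keep.empty:
        raise ValueError("no variant passes QC in all populations")
    # preserve the order of the first panel
    first = next(iter(panels.values()))
    keep_set = set(keep)
    return [v for v in first.variants["id"] if v in keep_set]


# ---------------------------------------------------------------------------
# Candidate causal SNPs and LD summaries
# ---------------------------------------------------------------------------

def select_candidate_causal(
    top: TopSnpSet | list[str],
    reference_pop1: GenotypePanel,
    qc_ids: list[str] | None = None,
    window_kb: float = 100,
    r2_min: float = 0.45,
    set_size: int | None = None,
) -> CandidateCausalSet:
    """QC'd variants within ``window_kb`` of an index SNP with r² > ``r2_min``.

    r² is measured in the designated reference population (population 1).
    """
    index_ids = top.top(set_size) if isinstance(top, TopSnpSet) else list(top)
    if set_size is not None and not isinstance(top, TopSnpSet):
        index_ids = index_ids[:set_size]
    ref = _as_ref(reference_pop1)
    qc_mask = np.ones(len(ref.ids), dtype=bool)
    if qc_ids is not None:
        qc_set = set(qc_ids)
        qc_mask = np.array([v in qc_set for v in ref.ids])
    window_bp = int(window_kb * 1000)
    cands: dict[str, list[str]] = {}
    r2s: dict[str, np.ndarray] = {}
    for vid in index_ids:
        if vid not in ref.id_to_idx:
            cands[vid], r2s[vid] = [], np.empty(0)
            continue
        j = ref.id_to_idx[vid]
        near = ref.window(j, window_bp)
        near = near[qc_mask[near]]
        r2 = ref.corr(j, near) ** 2
        hit = r2 > r2_min
        cands[vid] = list(ref.ids[near[hit]])
        r2s[vid] = r2[hit]
    return CandidateCausalSet(candidates=cands, r2=r2s)


def ld_summaries(
    pgi_snps: pd.DataFrame,
    candidates: CandidateCausalSet,
    ref_pop1: GenotypePanel,
    ref_pop2: GenotypePanel,
    window_kb: float = 100,
) -> pd.DataFrame:
    """Per PGI-SNP cross-population LD statistics and allele frequencies.

    ``pgi_snps`` needs columns ``id`` and ``beta_hat``.  For each PGI-SNP k,
    over all pooled candidate causal SNPs within ``window_kb`` of it:
    ``mean_r2_pop1`` is the mean of r²(k, c) in population 1 and
    ``mean_r1r2`` the mean of r(k,c; pop1) x r(k,c; pop2), with r the
    Pearson correlation of allele counts under the shared allele coding.
    PGI-SNPs with no candidate in-window are excluded.  Both panels must
    carry identical variant coding (align with :mod:`pgiport.io` first).
    """
    ref1, ref2 = _as_ref(ref_pop1), _as_ref(ref_pop2)
    pool = [vid for vid in candidates.pooled_ids() if vid in ref1.id_to_idx]
    pool_idx1 = np.array([ref1.id_to_idx[v] for v in pool], dtype=int)
    maf1 = ref1.panel.maf()
    maf2 = ref2.panel.maf()
    window_bp = int(window_kb * 1000)
    rows = []
    for row in pgi_snps.itertuples(index=False):
        vid = row.id
        if vid not in ref1.id_to_idx:
            continue
        j1 = ref1.id_to_idx[vid]
        near_pool = pool_idx1[
            (ref1.chrom[pool_idx1] == ref1.chrom[j1])
            & (np.abs(ref1.pos[pool_idx1] - ref1.pos[j1]) <= window_bp)
        ]
        if near_pool.size == 0:
            continue
        r1 = ref1.corr(j1, near_pool)
        idx2 = np.array([ref2.id_to_idx[ref1.ids[c]] for c in near_pool], dtype=int)
        r2 = ref2.corr(ref2.id_to_idx[vid], idx2)
        rows.append({
            "id": vid,
            "mean_r2_pop1": float(np.mean(r1 ** 2)),
            "mean_r1r2": float(np.mean(r1 * r2)),
            "maf_pop1": float(maf1[j1]),
            "maf_pop2": float(maf2[ref2.id_to_idx[vid]]),
            "beta_hat": float(row.beta_hat),
            "n_candidates": int(near_pool.size),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Expected relative accuracy
# ---------------------------------------------------------------------------

def expected_ra(summary: pd.DataFrame, effects_factor: float = 1.0,
                snp_set_size: int | None = None) -> ExpectedRA:
    """Evaluate the expected-relative-accuracy model on LD/MAF summaries."""
    if summary.empty:
        raise ValueError("empty LD summary")
    p1 = summary["maf_pop1"].to_numpy(dtype=float)
    p2 = summary["maf_pop2"].to_numpy(dtype=float)
    if (p1 <= 0).any() or (p2 <= 0).any():
        raise ValueError("monomorphic PGI-SNP in a population; apply the "
                         "common-SNP QC before evaluating the model")
    h1 = p1 * (1 - p1)
    h2 = p2 * (1 - p2)
    beta2 = summary["beta_hat"].to_numpy(dtype=float) ** 2
    num = np.sum(summary["mean_r1r2"].to_numpy(dtype=float) * np.sqrt(h2 / h1))
    den = np.sum(summary["mean_r2_pop1"].to_numpy(dtype=float))
    if den <= 0:
        raise ValueError("zero LD denominator sum")
    factor_ld_maf = (num / den) ** 2
    var1 = np.sum(h1 * beta2)
    var2 = np.sum(h2 * beta2)
    if var1 <= 0 or var2 <= 0:
        raise ValueError("zero variance-scale sum")
    factor_varscale = var1 / var2
    ra = effects_factor * factor_ld_maf * factor_varscale
    return ExpectedRA(
        factor_effects=float(effects_factor),
        factor_ld_maf=float(factor_ld_maf),
        factor_varscale=float(factor_varscale),
        ra_expected=float(ra),
        snp_set_size=int(snp_set_size if snp_set_size is not None else len(summary)),
        M_T=int(len(summary)),
    )


def stability_curve(
    sumstats: pd.DataFrame,
    ref_pop1: GenotypePanel,
    ref_pop2: GenotypePanel,
    set_sizes: tuple[int, ...] = DEFAULT_SET_SIZES,
    qc_ids: list[str] | None = None,
    effects_factor: float = 1.0,
    clump_window_kb: float = 2000,
    clump_r2: float = 0.01,
    clump_p: float = 0.5,
    candidate_window_kb: float = 100,
    candidate_r2: float = 0.45,
) -> pd.DataFrame:
    """Expected RA recomputed per top-SNP set size, as a table."""
    ref_pop1, ref_pop2 = _as_ref(ref_pop1), _as_ref(ref_pop2)
    top = clump(sumstats, ref_pop1, window_kb=clump_window_kb, r2_min=clump_r2,
                p_max=clump_p, set_sizes=tuple(set_sizes))
    beta = sumstats.set_index("id")["beta"]
    rows = []
    for size in set_sizes:
        ids = top.top(size)
        cand = select_candidate_causal(ids, ref_pop1, qc_ids=qc_ids,
                                       window_kb=candidate_window_kb, r2_min=candidate_r2)
        pgi_snps = pd.DataFrame({"id": ids, "beta_hat": beta.reindex(ids).to_numpy()})
        summary = ld_summaries(pgi_snps, cand, ref_pop1, ref_pop2,
                               window_kb=candidate_window_kb)
        est = expected_ra(summary, effects_factor=effects_factor, snp_set_size=size)
        rows.append({
            "snp_set_size": size,
            "M_T": est.M_T,
            "factor_effects": est.factor_effects,
            "factor_ld_maf": est.factor_ld_maf,
            "factor_varscale": est.factor_varscale,
            "ra_expected": est.ra_expected,
        })
    return pd.DataFrame(rows)
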