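"""PCA-based genetic-ancestry assignment and ancestry-specific PC controls.

Ancestry assignment projects study samples onto principal components fitted
in a labelled reference panel and assigns a sample to an ancestry when each
of its first PCs lies within four reference standard deviations of that
ancestry's reference mean.  PC controls for the incremental-R² regressions
are built per ancestry from variants passing call-rate/MAF/HWE filters,
LD-pruned in a 1 Mb rolling window, on the unrelated subset of a VanRaden
genomic relatedness matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypePanel
from .gstats import hwe_exact_pvalues

__all__ = [
    "AncestryModel",
    "UNASSIGNED",
    "fit_ancestry_model",
    "assign_ancestry",
    "ld_prune",
    "genomic_relatedness",
    "relatedness_filter",
    "build_pc_controls",
]

UNASSIGNED = "UNASSIGNED"


@dataclass
class AncestryModel:
    variant_ids: list[str]
    mean: np.ndarray        # per-variant dosage mean in the reference
    scale: np.ndarray       # per-variant dosage SD in the reference
    loadings: np.ndarray    # (n_variants, n_pcs)
    ancestries: list[str]
    pc_mean: np.ndarray     # (n_ancestries, n_pcs)
    pc_sd: np.ndarray       # (n_ancestries, n_pcs)
    n_pcs: int


def _standardized(panel: GenotypePanel, mean=None, scale=None):
    x = panel.imputed_dosages()
    if mean is None:
        mean = x.mean(axis=0)
        scale = x.std(axis=0)
        scale = np.where(scale == 0, 1.0, scale)
    return (x - mean) / scale, mean, scale


def fit_ancestry_model(reference: GenotypePanel, n_pcs: int = 10) -> AncestryModel:
    """Fit PCA on a labelled reference and record per-ancestry PC means/SDs."""
    if reference.ancestry is None:
        raise ValueError("reference panel must carry ancestry labels")
    labels = pd.Series(reference.ancestry)
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 labelled ancestries")
    small = counts[counts < 3]
    if len(small):
        raise ValueError(f"ancestries with < 3 reference samples: {list(small.index)}")
    z, mean, scale = _standardized(reference)
    n_pcs = min(n_pcs, min(z.shape) - 1)
    # PCA via SVD of the centered/scaled matrix
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    loadings = vt[:n_pcs].T
    scores = z @ loadings
    ancestries = sorted(counts.index)
    pc_mean = np.vstack([scores[labels.to_numpy() == a].mean(axis=0) for a in ancestries])
    pc_sd = np.vstack([scores[labels.to_numpy() == a].std(axis=0, ddof=1) for a in ancestries])
    if (pc_sd <= 0).any():
        raise ValueError("zero PC standard deviation within an ancestry")
    return AncestryModel(
        variant_ids=list(reference.variants["id"]), mean=mean, scale=scale,
        loadings=loadings, ancestries=ancestries, pc_mean=pc_mean, pc_sd=pc_sd,
        n_pcs=n_pcs,
    )


def project(model: AncestryModel, panel: GenotypePanel) -> np.ndarray:
    """Project panel samples onto the model's PC space (missing variants -> mean)."""
    shared = [v for v in model.variant_ids if v in set(panel.variants["id"])]
    frac_missing = 1 - len(shared) / len(model.variant_ids)
    if frac_missing > 0:
        warnings.warn(f"{frac_missing:.1%} of model variants missing from panel; "
                      "treated as reference-mean dosage")
    z = np.zeros((panel.n_samples, len(model.variant_ids)))
    pos = {v: i for i, v in enumerate(model.variant_ids)}
    idx_model = np.array([pos[v] for v in shared], dtype=int)
    x = panel.subset(variant_ids=shared).imputed_dosages()
    z[:, idx_model] = (x - model.mean[idx_model]) / model.scale[idx_model]
    return z @ model.loadings


def assign_ancestry(model: AncestryModel, panel: GenotypePanel):
    """Per-sample ancestry label or UNASSIGNED, plus an ambiguity report.

    A sample matches ancestry A when each of its first n_pcs projected PCs
    lies within 4 reference SDs of A's reference mean; multiple matches are
    resolved to the smallest standardized Euclidean distance.
    """
    scores = project(model, panel)
    dev = np.abs(scores[:, None, :] - model.pc_mean[None, :, :]) / model.pc_sd[None, :, :]
    within = (dev <= 4.0).all(axis=2)          # (n_samples, n_ancestries)
    dist = np.sqrt((dev ** 2).sum(axis=2))
    labels = np.full(panel.n_samples, UNASSIGNED, dtype=object)
    n_ambiguous = 0
    for i in range(panel.n_samples):
        hits = np.where(within[i])[0]
        if hits.size == 1:
            labels[i] = model.ancestries[hits[0]]
        elif hits.size > 1:
            n_ambiguous += 1
            labels[i] = model.ancestries[hits[np.argmin(dist[i, hits])]]
    report = {"n_ambiguous": n_ambiguous,
              "n_unassigned": int((labels == UNASSIGNED).sum())}
    return labels, report


# ---------------------------------------------------------------------------
# LD pruning, GRM, relatedness
# ---------------------------------------------------------------------------

def ld_prune(panel: GenotypePanel, window_bp: int = 1_000_000,
             step_variants: int = 5, r2_max: float = 0.1) -> list[str]:
    """Greedy windowed LD pruning; returns retained variant ids.

    Variants must be position-sorted.  Within each rolling window (spanning
    ``window_bp`` from its leftmost variant) any variant with r² > ``r2_max``
    against an earlier retained variant is removed; the window start then
    advances by ``step_variants``.
    """
    pos = panel.variants["pos"].to_numpy()
    chrom = panel.variants["chrom"].to_numpy()
    for c in np.unique(chrom):
        p = pos[chrom == c]
        if np.any(np.diff(p) < 0):
            raise ValueError("variants must be position-sorted within chromosome")
    x = panel.imputed_dosages()
    z = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z /= sd
    n, m = z.shape
    keep = np.ones(m, dtype=bool)
    start = 0
    while start < m:
        end = start
        while end < m and chrom[end] == chrom[start] and pos[end] - pos[start] <= window_bp:
            end += 1
        idx = np.arange(start, end)
        idx = idx[keep[idx]]
        for a_i, a in enumerate(idx):
            if not keep[a]:
                continue
            later = idx[a_i + 1:]
            later = later[keep[later]]
            if later.size:
                r2 = ((z[:, later].T @ z[:, a]) / n) ** 2
                keep[later[r2 > r2_max]] = False
        start += step_variants
    return list(panel.variants["id"][keep])


def genomic_relatedness(panel: GenotypePanel) -> np.ndarray:
    """VanRaden GRM: dosages centered at 2p and scaled by sqrt(2p(1-p))."""
    x = panel.imputed_dosages()
    p = x.mean(axis=0) / 2.0
    denom = np.sqrt(2 * p * (1 - p))
    denom[denom == 0] = 1.0
    w = (x - 2 * p) / denom
    return (w @ w.T) / panel.n_variants


def relatedness_filter(panel: GenotypePanel, grm: np.ndarray,
                       threshold: float = 0.05) -> np.ndarray:
    """Boolean mask of samples kept after removing one of each related pair.

    From each pair with relatedness above the threshold, the member with the
    higher missingness is removed; ties break on the lexicographically later
    sample id.
    """
    n = panel.n_samples
    miss = panel.sample_missingness()
    ids = np.asarray(panel.samples, dtype=object)
    keep = np.ones(n, dtype=bool)
    iu, ju = np.triu_indices(n, k=1)
    related = grm[iu, ju] > threshold
    pairs = sorted(zip(iu[related], ju[related]),
                   key=lambda ij: -grm[ij[0], ij[1]])
    for i, j in pairs:
        if not (keep[i] and keep[j]):
            continue
        if miss[i] > miss[j]:
            keep[i] = False
        elif miss[j] > miss[i]:
            keep[j] = False
        else:
            keep[i if str(ids[i]) > str(ids[j]) else j] = False
    return keep


def build_pc_controls(
    panel: GenotypePanel,
    long_range_ld_regions: list[tuple[str, int, int]] | None = None,
    n_pcs: int = 20,
    call_rate_min: float = 0.99,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-5,
    prune_window_bp: int = 1_000_000,
    prune_step: int = 5,
    prune_r2: float = 0.1,
    relatedness_max: float = 0.05,
) -> pd.DataFrame:
    """20 PCs for the incremental-R² regressions, for a single-ancestry panel.

    Excludes variants failing call-rate/MAF/HWE filters and configured
    long-range-LD regions (1-based inclusive intervals), LD-prunes the rest,
    removes one member of each GRM pair above the relatedness threshold,
    fits the PCs on the unrelated set and projects relatives back.
    """
    v = panel.variants
    mask = (
        (panel.call_rate() >= call_rate_min)
        & (panel.maf() >= maf_min)
        & (hwe_exact_pvalues(np.rint(panel.dosages)) >= hwe_p_min)
    )
    for chrom, start, stop in (long_range_ld_regions or []):
        inside = (v["chrom"].to_numpy() == str(chrom)) & \
                 (v["pos"].to_numpy() >= start) & (v["pos"].to_numpy() <= stop)
        mask &= ~inside
    filtered = panel.subset(variant_ids=list(v["id"][mask]))
    kept_ids = ld_prune(filtered, window_bp=prune_window_bp,
                        step_variants=prune_step, r2_max=prune_r2)
    pruned = filtered.subset(variant_ids=kept_ids)
    grm = genomic_relatedness(pruned)
    unrelated = relatedness_filter(pruned, grm, threshold=relatedness_max)
    if unrelated.sum() < n_pcs + 1:
        raise ValueError(f"only {int(unrelated.sum())} unrelated samples; "
                         f"need > {n_pcs} for {n_pcs} PCs")
    base = pruned.subset(sample_mask=unrelated)
    z, mean, scale = _standardized(base)
    n_pcs = min(n_pcs, min(z.shape) - 1)
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    loadings = vt[:n_pcs].T
    z_all = (pruned.imputed_dosages() - mean) / scale
    scores = z_all @ loadings
    return pd.DataFrame(scores, index=pd.Index(panel.samples, name="sample_id"),
                        columns=[f"PC{i + 1}" for i in range(n_pcs)])
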