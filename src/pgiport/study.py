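"""End-to-end synthetic portability study.

Runs the whole pipeline on one generated two-population dataset: simulate
genotypes / causal architecture / phenotypes / discovery summary statistics,
clump the discovery GWAS against the population-1 reference, build the PGI
from the top index SNPs, measure incremental R² in each population, and
evaluate the expected relative accuracy from the cross-population LD/MAF
summaries over candidate causal SNPs.  This is the harness on which the
theory-recovery, heritability-adjustment and confounding-contrast
experiments run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import expected as exp
from .accuracy import incremental_r2, paired_bootstrap_ra_test, relative_accuracy
from .io import GenotypePanel
from .score import compute_pgi
from .simulate import (
    POP1,
    POP2,
    CausalModel,
    SimulationConfig,
    derive_weight_table,
    simulate_causal_architecture,
    simulate_discovery_sumstats,
    simulate_phenotypes,
    simulate_reference_panel,
)

__all__ = ["StudyResult", "run_portability_study", "study_inputs",
           "confounding_contrast"]


@dataclass
class StudyResult:
    r2_ref: float
    r2_target: float
    ra_obs: float
    ra_expected: float
    factor_ld_maf: float
    factor_varscale: float
    m_t: int
    n_index: int


def study_inputs(config: SimulationConfig, mode: str = "standard"):
    """Generate one dataset: panel, causal model, phenotype vector, sumstats."""
    panel = simulate_reference_panel(config)
    causal = simulate_causal_architecture(panel, config)
    pheno = simulate_phenotypes(panel, causal, config)
    y = pheno.set_index("sample_id")["value"].reindex(panel.samples).to_numpy()
    sumstats = simulate_discovery_sumstats(panel, causal, config, mode=mode)
    return panel, causal, y, sumstats


def analyze(
    panel: GenotypePanel,
    y: np.ndarray,
    sumstats: pd.DataFrame,
    top_k: int = 100,
    effects_factor: float = 1.0,
    qc: bool = True,
    hide_ids: list[str] | None = None,
) -> StudyResult:
    """Clump -> PGI -> incremental R² per population -> expected RA.

    ``hide_ids`` removes variants (typically the true causal SNPs) from the
    discovery summary statistics so the PGI is built from LD tags, the way
    real arrays rarely type the causal variant; the hidden variants remain
    in the reference panel and can re-enter as candidate causal SNPs.
    """
    ref1 = panel.by_ancestry(POP1)
    ref2 = panel.by_ancestry(POP2)
    qc_ids = exp.qc_common_snps({POP1: ref1, POP2: ref2}) if qc else list(panel.variants["id"])
    ss = sumstats[sumstats["id"].isin(qc_ids)]
    if hide_ids:
        ss = ss[~ss["id"].isin(hide_ids)]
    ld1, ld2 = exp.LDReference(ref1), exp.LDReference(ref2)
    top = exp.clump(ss, ld1, set_sizes=(top_k,), max_indices=top_k)
    index_ids = top.top(top_k)
    weights = derive_weight_table(ss[ss["id"].isin(index_ids)])
    mask1 = panel.ancestry == POP1
    pgi1 = compute_pgi(ref1, weights).standardized
    pgi2 = compute_pgi(ref2, weights).standardized
    r2_ref = incremental_r2(y[mask1], pgi1)
    r2_tar = incremental_r2(y[~mask1], pgi2)
    cand = exp.select_candidate_causal(index_ids, ld1, qc_ids=qc_ids)
    beta = ss.set_index("id")["beta"]
    pgi_snps = pd.DataFrame({"id": index_ids,
                             "beta_hat": beta.reindex(index_ids).to_numpy()})
    summary = exp.ld_summaries(pgi_snps, cand, ld1, ld2)
    est = exp.expected_ra(summary, effects_factor=effects_factor, snp_set_size=top_k)
    return StudyResult(
        r2_ref=r2_ref, r2_target=r2_tar,
        ra_obs=relative_accuracy(r2_tar, r2_ref),
        ra_expected=est.ra_expected,
        factor_ld_maf=est.factor_ld_maf,
        factor_varscale=est.factor_varscale,
        m_t=est.M_T, n_index=len(index_ids),
    )


def run_portability_study(
    config: SimulationConfig,
    top_k: int = 100,
    mode: str = "standard",
    effects_factor: float = 1.0,
) -> StudyResult:
    """One full synthetic run; seeded by ``config.seed``.

    The discovery GWAS covers only ``config.typed_fraction`` of the panel's
    variants, so most causal variants act through LD tags and
    cross-population LD / MAF differences produce a genuine portability
    loss; the full panel remains available for candidate causal SNPs.
    """
    panel, causal, y, sumstats = study_inputs(config, mode=mode)
    return analyze(panel, y, sumstats, top_k=top_k, effects_factor=effects_factor)


def _mode_pgi(panel, sumstats, qc_ids, top_k, index_ids=None):
    ss = sumstats[sumstats["id"].isin(qc_ids)]
    ref1 = panel.by_ancestry(POP1)
    if index_ids is None:
        top = exp.clump(ss, ref1, set_sizes=(top_k,), max_indices=top_k)
        index_ids = top.top(top_k)
    weights = derive_weight_table(ss[ss["id"].isin(index_ids)])
    return (compute_pgi(ref1, weights).standardized,
            compute_pgi(panel.by_ancestry(POP2), weights).standardized,
            index_ids)


def confounding_contrast(config: SimulationConfig, top_k: int = 100,
                         B: int = 1000, seed: int = 0,
                         shared_clump: bool = False) -> dict:
    """Standard-vs-family PGI contrast on one synthetic dataset.

    Builds both PGIs on the same individuals (standard-mode discovery betas
    carry the stratification bias when ``config.confound_strength`` > 0;
    family-mode betas are unbiased) and runs the paired bootstrap test for
    the RA_obs difference (family minus standard).  ``shared_clump`` scores
    both weightings on the standard-mode index SNP set, so the contrast
    isolates the weights themselves — the construction used for null
    calibration, where two independent noisy weightings of the same SNP set
    should show no systematic RA difference.
    """
    panel = simulate_reference_panel(config)
    causal = simulate_causal_architecture(panel, config)
    pheno = simulate_phenotypes(panel, causal, config)
    y = pheno.set_index("sample_id")["value"].reindex(panel.samples).to_numpy()
    ss_std = simulate_discovery_sumstats(panel, causal, config, mode="standard")
    ss_fam = simulate_discovery_sumstats(panel, causal, config, mode="family")
    ref1 = panel.by_ancestry(POP1)
    ref2 = panel.by_ancestry(POP2)
    qc_ids = exp.qc_common_snps({POP1: ref1, POP2: ref2})
    pgi1_std, pgi2_std, index_ids = _mode_pgi(panel, ss_std, qc_ids, top_k)
    pgi1_fam, pgi2_fam, _ = _mode_pgi(panel, ss_fam, qc_ids, top_k,
                                      index_ids=index_ids if shared_clump else None)
    mask1 = panel.ancestry == POP1
    y1, y2 = y[mask1], y[~mask1]
    out = {
        "r2_ref_standard": incremental_r2(y1, pgi1_std),
        "r2_target_standard": incremental_r2(y2, pgi2_std),
        "r2_ref_family": incremental_r2(y1, pgi1_fam),
        "r2_target_family": incremental_r2(y2, pgi2_fam),
    }
    out["ra_standard"] = relative_accuracy(out["r2_target_standard"], out["r2_ref_standard"])
    out["ra_family"] = relative_accuracy(out["r2_target_family"], out["r2_ref_family"])
    delta, p = paired_bootstrap_ra_test(
        y1, pgi1_fam, pgi1_std, y2, pgi2_fam, pgi2_std, B=B, seed=seed)
    out["delta_ra_family_minus_standard"] = delta
    out["p_value"] = p
    return out
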