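"""Two-population synthetic data with controllable divergence, LD and confounding.

The generator emulates the statistical structure the portability analysis
assumes: two populations whose allele frequencies diverge under the
Balding-Nichols model with parameter ``fst``; local LD produced by a
first-order Markov haplotype-copying process within blocks; a polygenic
causal architecture whose per-population standardized effects have
cross-population correlation ``rho_b``; phenotypes with ancestry-specific
heritabilities; and discovery GWAS summary statistics whose marginal
effects are computed analytically from the reference-panel LD and then
perturbed with sampling noise.  ``standard`` mode adds a stratification
bias aligned with the cross-population allele-frequency gradient;
``family`` mode is unbiased but noisier, emulating the smaller effective
sample size of within-family GWAS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypePanel

__all__ = [
    "SimulationConfig",
    "CausalModel",
    "simulate_reference_panel",
    "simulate_causal_architecture",
    "simulate_phenotypes",
    "simulate_discovery_sumstats",
    "derive_weight_table",
    "true_genetic_values",
    "stratification_scores",
    "POP1",
    "POP2",
]

POP1 = "pop1"  # discovery / reference ancestry
POP2 = "pop2"  # target ancestry

#: share of per-SNP drift variance carried by the block-shared component;
#: 1.0 makes the LD block the unit of drift (frequencies of linked SNPs
#: move together between populations, as tight LD implies)
DRIFT_BLOCK_SHARE = 1.0

#: sd of within-block ancestral-frequency jitter; 0 treats the block as a
#: single ancestral haplotype unit (uniform frequency, geometric LD decay)
FREQ_JITTER = 0.0


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic two-population experiment.

    Defaults are the conditions under which the pipeline's observed and
    expected relative accuracy are compared: 5,000 SNPs in 100 LD blocks,
    Balding-Nichols divergence fst = 0.1 (African-vs-European-like), 2,000
    samples per population, 200 causal SNPs, perfectly correlated causal
    effects, equal heritabilities of 0.5, and an analytic discovery GWAS
    of 100,000 individuals.
    """

    n_variants: int = 5000
    n_blocks: int = 100
    block_ld_rho: float = 0.85    # adjacent-SNP haplotype copying probability (pop 1)
    block_ld_rho_pop2: float | None = 0.6  # pop-2 copying parameter; None = same as pop 1
    fst: float = 0.1
    n_samples_per_pop: int = 2000
    n_causal: int = 200
    rho_b: float = 1.0            # cross-population causal-effect correlation
    h2_pop1: float = 0.5
    h2_pop2: float = 0.5
    n_discovery: int = 100_000
    typed_fraction: float = 0.25  # share of panel SNPs on the discovery array / in the PGI
    confound_strength: float = 0.0
    maf_floor: float = 0.05       # ancestral frequency bound
    seed: int = 0
    spacing_bp: int = 5000        # physical spacing between adjacent SNPs
    family_se_inflation: float = 1.6

    def __post_init__(self) -> None:
        if not (0 <= self.block_ld_rho < 1):
            raise ValueError("block_ld_rho must be in [0, 1)")
        if self.block_ld_rho_pop2 is not None and not (0 <= self.block_ld_rho_pop2 < 1):
            raise ValueError("block_ld_rho_pop2 must be in [0, 1)")
        if not (0 <= self.fst <= 0.5):
            raise ValueError("fst must be in [0, 0.5]")
        if not (-1 <= self.rho_b <= 1):
            raise ValueError("rho_b must be in [-1, 1]")
        for name in ("h2_pop1", "h2_pop2"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_causal > self.n_variants:
            raise ValueError("n_causal exceeds n_variants")
        if not (0 < self.maf_floor < 0.5):
            raise ValueError("maf_floor must be in (0, 0.5)")
        if self.confound_strength < 0:
            raise ValueError("confound_strength must be >= 0")
        if not (0 < self.typed_fraction <= 1):
            raise ValueError("typed_fraction must be in (0, 1]")


@dataclass
class CausalModel:
    """Causal SNP ids with per-population standardized-genotype effects."""

    causal_ids: list[str]
    beta_pop1: np.ndarray
    beta_pop2: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.causal_ids) == len(self.beta_pop1) == len(self.beta_pop2)):
            raise ValueError("causal ids and effect vectors must have equal length")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def block_bounds(n_variants: int, n_blocks: int) -> list[tuple[int, int]]:
    """Contiguous (start, stop) index ranges of the LD blocks."""
    edges = np.linspace(0, n_variants, n_blocks + 1).astype(int)
    return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:]) if b > a]


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _copying_haplotypes(
    freqs: np.ndarray, n_hap: int, lam: float,
    bounds: list[tuple[int, int]], rng: np.random.Generator,
) -> np.ndarray:
    """First-order Markov copying process, independent across blocks.

    Within a block each haplotype copies its previous allele with
    probability ``lam`` and otherwise draws a fresh allele whose frequency
    is chosen so the per-SNP marginal frequency is exactly ``freqs[j]``
    (the copying probability is clamped per pair where needed, since a
    copy chain cannot hold correlation ``lam`` between SNPs of very
    different frequencies).  Adjacent-SNP allele correlation is
    lam_j * sqrt(p_{j-1} q_{j-1} / (p_j q_j)), i.e. ``lam`` when
    neighbouring frequencies are equal.
    """
    m = freqs.size
    # clamp so the innovation frequency stays in [0, 1]
    prev = np.roll(freqs, 1)
    lam_j = np.minimum(lam, np.minimum(freqs / prev, (1 - freqs) / (1 - prev)))
    innov = (freqs - lam_j * prev) / (1 - lam_j)
    innov = np.clip(innov, 0.0, 1.0)
    # variant-major layout keeps the per-SNP rows contiguous in the loop
    hap = np.empty((m, n_hap), dtype=np.int8)
    fresh_u = rng.random((m, n_hap))
    copy = rng.random((m, n_hap)) < lam_j[:, None]
    for a, b in bounds:
        hap[a] = fresh_u[a] < freqs[a]
        for j in range(a + 1, b):
            hap[j] = np.where(copy[j], hap[j - 1], fresh_u[j] < innov[j])
    return hap.T


def simulate_reference_panel(config: SimulationConfig) -> GenotypePanel:
    """Two labelled populations under Balding-Nichols divergence with block LD."""
    rng = _rng(config.seed, 0)
    m = config.n_variants
    bounds = block_bounds(m, config.n_blocks)
    # SNPs in strong LD share ancestry, hence similar allele frequencies:
    # each block gets an anchor frequency (plus optional per-SNP jitter)
    p0 = np.empty(m)
    for a, b in bounds:
        anchor = rng.uniform(config.maf_floor, 1 - config.maf_floor)
        p0[a:b] = np.clip(anchor + rng.normal(0.0, FREQ_JITTER, size=b - a),
                          config.maf_floor, 1 - config.maf_floor)
    if config.fst > 0:
        # drift acts on haplotypes, so frequency deviations of linked SNPs are
        # correlated: per population, a block-shared drift component plus a
        # smaller per-SNP component, with total variance fst * p0(1-p0)
        shared = DRIFT_BLOCK_SHARE
        sd = np.sqrt(config.fst * p0 * (1 - p0))
        pop_freqs = []
        for _ in range(2):
            z = np.sqrt(1 - shared) * rng.standard_normal(m)
            for a, b in bounds:
                z[a:b] += np.sqrt(shared) * rng.standard_normal()
            pop_freqs.append(np.clip(p0 + sd * z, 1e-3, 1 - 1e-3))
    else:
        pop_freqs = [p0, p0]
    n = config.n_samples_per_pop
    lam2 = config.block_ld_rho if config.block_ld_rho_pop2 is None else config.block_ld_rho_pop2
    dosage_blocks, labels = [], []
    for pf, lam in zip(pop_freqs, (config.block_ld_rho, lam2)):
        hap = _copying_haplotypes(pf, 2 * n, lam, bounds, rng)
        dosage_blocks.append((hap[:n] + hap[n:]).astype(np.float64))
    dosages = np.vstack(dosage_blocks)
    labels = np.array([POP1] * n + [POP2] * n)
    variants = pd.DataFrame({
        "id": [f"snp{j}" for j in range(m)],
        "chrom": "1",
        "pos": 1 + np.arange(m) * config.spacing_bp,
        "a1": "A",
        "a2": "G",
    })
    samples = [f"{lab}_{i}" for lab, nn in ((POP1, n), (POP2, n)) for i in range(nn)]
    if config.fst == 0 and n < 50:
        warnings.warn("fst=0 with few samples: populations will not separate in PCA")
    return GenotypePanel(samples=samples, variants=variants, dosages=dosages, ancestry=labels)


def _standardize(dosages: np.ndarray) -> np.ndarray:
    x = dosages - dosages.mean(axis=0)
    sd = dosages.std(axis=0)
    sd[sd == 0] = 1.0
    return x / sd


# ---------------------------------------------------------------------------
# Causal architecture and phenotypes
# ---------------------------------------------------------------------------

def simulate_causal_architecture(panel: GenotypePanel, config: SimulationConfig) -> CausalModel:
    """Sample causal SNPs and correlated per-population standardized effects.

    Effects are drawn bivariate normal with correlation ``rho_b`` and then
    rescaled by a per-population scalar so the genetic variance realized in
    that population's panel equals the target heritability.
    """
    rng = _rng(config.seed, 1)
    if panel.n_variants < config.n_causal:
        raise ValueError("panel has fewer variants than n_causal")
    idx = np.sort(rng.choice(panel.n_variants, size=config.n_causal, replace=False))
    rho = config.rho_b
    z1 = rng.standard_normal(config.n_causal)
    z2 = rho * z1 + np.sqrt(max(1 - rho ** 2, 0.0)) * rng.standard_normal(config.n_causal)
    raw = np.column_stack([z1, z2])
    betas = {}
    for col, (pop, h2) in enumerate([(POP1, config.h2_pop1), (POP2, config.h2_pop2)]):
        sub = panel.by_ancestry(pop)
        z = _standardize(sub.imputed_dosages()[:, idx])
        b = raw[:, col]
        g = z @ b
        sd = g.std()
        betas[pop] = b * (np.sqrt(h2) / sd if sd > 0 else 0.0)
    ids = list(panel.variants["id"].iloc[idx])
    return CausalModel(causal_ids=ids, beta_pop1=betas[POP1], beta_pop2=betas[POP2])


def true_genetic_values(panel: GenotypePanel, causal: CausalModel) -> np.ndarray:
    """Per-sample genetic score, standardizing genotypes within each population."""
    idx = panel.variant_index(causal.causal_ids)
    x = panel.dosages[:, idx]
    if np.isnan(x).any():
        x = panel.subset(variant_ids=causal.causal_ids).imputed_dosages()
    g = np.empty(panel.n_samples)
    for pop, beta in ((POP1, causal.beta_pop1), (POP2, causal.beta_pop2)):
        mask = panel.ancestry == pop
        g[mask] = _standardize(x[mask]) @ beta
    return g


def stratification_scores(panel: GenotypePanel) -> np.ndarray:
    """Per-sample score on the cross-population allele-frequency gradient.

    The gradient direction weights each SNP by its population frequency
    difference; genotypes are standardized with population-1 constants and
    the score is scaled to unit variance within population 1.  This is the
    environmental axis along which the stratification confound acts.
    """
    mask1 = panel.ancestry == POP1
    x = panel.imputed_dosages()
    mu1 = x[mask1].mean(axis=0)
    sd1 = x[mask1].std(axis=0)
    sd1[sd1 == 0] = 1.0
    p1 = mu1 / 2.0
    p2 = x[~mask1].mean(axis=0) / 2.0
    a = p1 - p2
    s = ((x - mu1) / sd1) @ a
    scale = s[mask1].std()
    return s / (scale if scale > 0 else 1.0)


def simulate_phenotypes(
    panel: GenotypePanel,
    causal: CausalModel,
    config: SimulationConfig,
    phenotype: str = "trait",
    n_waves: int = 1,
    sex_effect: float = 0.0,
    age_effect: float = 0.0,
    birth_year_effect: float = 0.0,
) -> pd.DataFrame:
    """Phenotype table: genetic score + Gaussian noise scaled to the target h².

    The stratification confounder (``config.confound_strength`` x the
    frequency-gradient score) is added to population-1 phenotypes only,
    emulating gene-environment correlation specific to the discovery
    ancestry.  Optional sex / age / birth-year effects and extra waves
    support the residualization stage.
    """
    rng = _rng(config.seed, 2)
    g = true_genetic_values(panel, causal)
    noise_sd = np.where(panel.ancestry == POP1,
                        np.sqrt(max(1 - config.h2_pop1, 0.0)),
                        np.sqrt(max(1 - config.h2_pop2, 0.0)))
    confound = np.zeros(panel.n_samples)
    if config.confound_strength > 0:
        s = stratification_scores(panel)
        confound = np.where(panel.ancestry == POP1, config.confound_strength * s, 0.0)
    n = panel.n_samples
    sex = rng.integers(0, 2, size=n)
    birth_year = rng.integers(1940, 1971, size=n)
    rows = []
    for wave in range(1, n_waves + 1):
        age = (2008 + 2 * wave) - birth_year
        y = (g + confound + noise_sd * rng.standard_normal(n)
             + sex_effect * sex + age_effect * (age - age.mean()) / 10.0
             + birth_year_effect * (birth_year - birth_year.mean()) / 10.0)
        for i, sid in enumerate(panel.samples):
            rows.append((sid, phenotype, y[i], wave, int(sex[i]), int(birth_year[i]), float(age[i])))
    return pd.DataFrame(rows, columns=[
        "sample_id", "phenotype", "value", "wave", "sex", "birth_year", "age"])


# ---------------------------------------------------------------------------
# Discovery GWAS summary statistics
# ---------------------------------------------------------------------------

def _block_ld_products(z: np.ndarray, vec: np.ndarray, bounds) -> np.ndarray:
    """R @ vec computed block-by-block, with R the within-block correlation."""
    n = z.shape[0]
    out = np.zeros(z.shape[1])
    for a, b in bounds:
        sub = vec[a:b]
        if np.any(sub != 0):
            r = (z[:, a:b].T @ z[:, a:b]) / n
            out[a:b] = r @ sub
    return out


def simulate_discovery_sumstats(
    panel: GenotypePanel,
    causal: CausalModel,
    config: SimulationConfig,
    mode: str = "standard",
) -> pd.DataFrame:
    """Discovery GWAS summary statistics emulated analytically from pop-1 LD.

    Marginal standardized effects are the within-block LD products of the
    causal effects; sampling noise is N(0, se²) with the per-allele
    se = sd(y)/sqrt(2 p (1-p) n_discovery).  ``standard`` mode biases every
    effect by ``confound_strength`` times its correlation with the
    frequency-gradient score; ``family`` mode is unbiased but inflates the
    se by ``family_se_inflation``.

    Only a seeded random ``typed_fraction`` of panel variants is reported
    (the discovery array / PGI SNP set; identical across modes), emulating
    PGI weight sets that cover a minority of the common variants present in
    the reference panel.  Causal variants are therefore typed at the
    coverage rate and otherwise act through LD tags only.
    """
    if mode not in ("standard", "family"):
        raise ValueError(f"mode must be 'standard' or 'family', got {mode!r}")
    if config.n_discovery < 100:
        warnings.warn("n_discovery < 100: sampling-noise asymptotics unreliable")
    rng = _rng(config.seed, 3 if mode == "standard" else 4)
    sub = panel.by_ancestry(POP1)
    z = _standardize(sub.imputed_dosages())
    bounds = block_bounds(panel.n_variants, config.n_blocks)
    beta_full = np.zeros(panel.n_variants)
    beta_full[panel.variant_index(causal.causal_ids)] = causal.beta_pop1
    alpha = _block_ld_products(z, beta_full, bounds)

    var_y = 1.0
    if mode == "standard" and config.confound_strength > 0:
        s = stratification_scores(panel)
        s1 = s[panel.ancestry == POP1]
        lam = (z.T @ (s1 - s1.mean())) / (len(s1) * max(s1.std(), 1e-12))
        alpha = alpha + config.confound_strength * lam
        var_y += config.confound_strength ** 2

    p1 = sub.allele_freq()
    het = np.clip(2 * p1 * (1 - p1), 1e-6, None)
    beta_allele = alpha / np.sqrt(het)
    se = np.sqrt(var_y) / np.sqrt(het * config.n_discovery)
    n_eff = config.n_discovery
    if mode == "family":
        se = se * config.family_se_inflation
        n_eff = int(config.n_discovery / config.family_se_inflation ** 2)
    obs = beta_allele + rng.standard_normal(panel.n_variants) * se
    from scipy import stats

    zscore = obs / se
    pval = np.clip(2 * stats.norm.sf(np.abs(zscore)), np.finfo(float).tiny, 1.0)
    out = pd.DataFrame({
        "id": panel.variants["id"],
        "effect_allele": panel.variants["a1"],
        "other_allele": panel.variants["a2"],
        "eaf": p1,
        "beta": obs,
        "se": se,
        "pval": pval,
        "n": n_eff,
    })
    if config.typed_fraction < 1:
        typed_rng = _rng(config.seed, 5)  # same typed set for both modes
        n_typed = int(round(config.typed_fraction * panel.n_variants))
        typed = np.sort(typed_rng.choice(panel.n_variants, size=n_typed, replace=False))
        out = out.iloc[typed].reset_index(drop=True)
    return out


def derive_weight_table(sumstats: pd.DataFrame, rule: str = "identity",
                        p_threshold: float = 5e-8) -> pd.DataFrame:
    """PGI weights from summary statistics.

    ``identity`` copies betas as weights; ``pvalue_threshold`` zeroes the
    weights of variants with p above ``p_threshold``.
    """
    if sumstats.empty:
        raise ValueError("empty summary statistics")
    w = sumstats[["id", "effect_allele", "other_allele"]].copy()
    if rule == "identity":
        w["weight"] = sumstats["beta"].to_numpy()
    elif rule == "pvalue_threshold":
        w["weight"] = np.where(sumstats["pval"].to_numpy() <= p_threshold,
                               sumstats["beta"].to_numpy(), 0.0)
    else:
        raise ValueError(f"unknown weight rule {rule!r}")
    return w
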