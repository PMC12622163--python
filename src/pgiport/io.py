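"""Domain data model and readers/writers.

The in-memory substrate for the whole pipeline is :class:`GenotypePanel`,
a sample-by-variant dosage matrix (values in [0, 2], ``NaN`` = missing) with
variant metadata, plus plain :class:`pandas.DataFrame` tables for PGI
weights, GWAS summary statistics, phenotypes and heritability estimates.

Supported external formats: PLINK 1.9 bed/bim/fam (hard calls), VCF 4.x
(GT field, biallelic records only) and tab-delimited tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypePanel",
    "read_genotypes",
    "read_plink",
    "write_plink",
    "read_vcf",
    "read_weight_table",
    "read_sumstats",
    "read_phenotypes",
    "read_heritability",
    "write_table",
    "read_table",
    "align_alleles",
    "AMBIGUOUS_PAIRS",
]

VARIANT_COLUMNS = ["id", "chrom", "pos", "a1", "a2"]

#: strand-ambiguous allele pairs (complementary on the opposite strand)
AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class GenotypePanel:
    """Dosage matrix with variant metadata and optional ancestry labels.

    Attributes
    ----------
    samples : list of str
        Sample identifiers, one per dosage row.
    variants : pandas.DataFrame
        Columns ``id, chrom, pos, a1, a2``. ``a1`` is the counted (effect)
        allele; ``pos`` is 1-based.
    dosages : numpy.ndarray
        Shape ``(n_samples, n_variants)``, float64, values in [0, 2],
        ``NaN`` marks a missing genotype.
    ancestry : numpy.ndarray or None
        Optional per-sample ancestry label.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray
    ancestry: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            raise ValueError("dosages outside [0, 2]")
        ids = self.variants["id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate variant id {dup!r}")
        if self.ancestry is not None:
            self.ancestry = np.asarray(self.ancestry)
            if self.ancestry.shape[0] != len(self.samples):
                raise ValueError("ancestry labels do not match sample count")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, ids) -> np.ndarray:
        """Positional indices of the given variant ids (order preserved)."""
        lookup = pd.Index(self.variants["id"])
        idx = lookup.get_indexer(pd.Index(ids))
        if (idx < 0).any():
            missing = np.asarray(ids)[idx < 0][:3]
            raise KeyError(f"variants not in panel: {list(missing)} ...")
        return idx

    def subset(self, variant_ids=None, sample_mask=None) -> "GenotypePanel":
        """Return a new panel restricted to the given variants and/or samples."""
        cols = slice(None) if variant_ids is None else self.variant_index(variant_ids)
        rows = slice(None) if sample_mask is None else np.asarray(sample_mask)
        samples = list(np.asarray(self.samples, dtype=object)[rows]) if sample_mask is not None else list(self.samples)
        anc = None
        if self.ancestry is not None:
            anc = self.ancestry[rows]
        return GenotypePanel(
            samples=samples,
            variants=self.variants.iloc[cols] if variant_ids is not None else self.variants,
            dosages=self.dosages[rows][:, cols] if variant_ids is not None else self.dosages[rows],
            ancestry=anc,
        )

    def by_ancestry(self, label: str) -> "GenotypePanel":
        if self.ancestry is None:
            raise ValueError("panel has no ancestry labels")
        return self.subset(sample_mask=self.ancestry == label)

    # -- per-variant statistics --------------------------------------------
    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted allele (a1), missing dosages ignored."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def sample_missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=1)

    def imputed_dosages(self) -> np.ndarray:
        """Dosages with missing entries replaced by the per-variant mean."""
        x = self.dosages.copy()
        if np.isnan(x).any():
            col_mean = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            idx = np.where(np.isnan(x))
            x[idx] = col_mean[idx[1]]
        return x


# ---------------------------------------------------------------------------
# PLINK 1.9 bed/bim/fam
# ---------------------------------------------------------------------------

_BED_MAGIC = b"\x6c\x1b\x01"  # SNP-major variant-major mode
# 2-bit code -> dosage of A1 (PLINK: 00 hom A1, 01 missing, 10 het, 11 hom A2)
_BED_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def read_plink(prefix: str | Path) -> GenotypePanel:
    """Read a PLINK 1.9 fileset ``prefix.{bed,bim,fam}``.

    A1 (the first allele column of the .bim) is the counted allele.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"iid": str},
    )
    n, m = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: not a SNP-major PLINK bed file")
    bytes_per_variant = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_variant * m:
        raise ValueError(
            f"{prefix}.bed: expected {bytes_per_variant * m} data bytes, found {body.size}"
        )
    blocks = body.reshape(m, bytes_per_variant)
    # unpack 2-bit codes, little-endian within each byte
    codes = np.empty((m, bytes_per_variant * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (blocks >> (2 * k)) & 0b11
    dosages = _BED_CODE_TO_DOSAGE[codes[:, :n]].T
    variants = bim[["id", "chrom", "pos", "a1", "a2"]].copy()
    return GenotypePanel(samples=list(fam["iid"]), variants=variants, dosages=dosages)


def write_plink(panel: GenotypePanel, prefix: str | Path) -> None:
    """Write hard-call dosages as a PLINK 1.9 fileset (dosages are rounded)."""
    prefix = Path(prefix)
    v = panel.variants
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for row in v.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.id}\t0\t{row.pos}\t{row.a1}\t{row.a2}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for s in panel.samples:
            fh.write(f"{s}\t{s}\t0\t0\t0\t-9\n")
    n = panel.n_samples
    hard = np.rint(panel.dosages)
    code = np.full(hard.shape, 1, dtype=np.uint8)  # missing
    code[hard == 2] = 0b00
    code[hard == 1] = 0b10
    code[hard == 0] = 0b11
    bytes_per_variant = (n + 3) // 4
    padded = np.ones((panel.n_variants, bytes_per_variant * 4), dtype=np.uint8) * 0b11
    padded[:, :n] = code.T
    packed = np.zeros((panel.n_variants, bytes_per_variant), dtype=np.uint8)
    for k in range(4):
        packed |= padded[:, k::4] << (2 * k)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypePanel:
    """Read a VCF into a panel; dosage = count of the first ALT allele.

    Multi-allelic records are rejected with an explicit error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, a1s, a2s, rows = [], [], [], [], [], []
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            raise ValueError(
                f"{path}: record {i + 1} ({rec.CHROM}:{rec.POS}) is not biallelic "
                f"(ALT={rec.ALT}); split or drop multi-allelic sites first"
            )
        ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
        chroms.append(str(rec.CHROM))
        poss.append(int(rec.POS))
        a1s.append(rec.ALT[0])  # counted allele = first ALT
        a2s.append(rec.REF)
        gt = np.asarray(rec.genotype.array())[:, :2].astype(float)
        gt[gt < 0] = np.nan
        rows.append(gt.sum(axis=1))
    if not ids:
        raise ValueError(f"{path}: no variant records")
    variants = pd.DataFrame(
        {"id": ids, "chrom": chroms, "pos": poss, "a1": a1s, "a2": a2s}
    )
    return GenotypePanel(samples=samples, variants=variants,
                         dosages=np.column_stack(rows) if rows else np.empty((len(samples), 0)))


def read_genotypes(path: str | Path, format: str = "plink-bed") -> GenotypePanel:
    """Dispatch to :func:`read_plink` or :func:`read_vcf`."""
    if format == "plink-bed":
        return read_plink(path)
    if format == "vcf":
        return read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# Tab-delimited tables
# ---------------------------------------------------------------------------

def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as tab-delimited UTF-8 with >= 6 significant digits."""
    records.to_csv(path, sep="\t", index=False, float_format="%.8g", encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    dtypes = {c: str for c in ("id", "sample_id")}
    return pd.read_csv(path, sep="\t", dtype=dtypes)


def read_weight_table(path: str | Path) -> pd.DataFrame:
    """Columns: id, effect_allele, other_allele, weight."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    _require(df, ["id", "effect_allele", "other_allele", "weight"], path)
    if not np.isfinite(df["weight"]).all():
        raise ValueError(f"{path}: non-finite weights")
    if df["id"].duplicated().any():
        raise ValueError(f"{path}: duplicate variant ids")
    return df


def read_sumstats(path: str | Path) -> pd.DataFrame:
    """Columns: id, effect_allele, other_allele, eaf, beta, se, pval, n."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    _require(df, ["id", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n"], path)
    if (df["se"] <= 0).any():
        raise ValueError(f"{path}: non-positive SE")
    return df


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    _require(df, ["sample_id", "phenotype", "value"], path)
    return df


def read_heritability(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, ["phenotype", "ancestry", "h2", "se"], path)
    return df


def _require(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


# ---------------------------------------------------------------------------
# Allele alignment
# ---------------------------------------------------------------------------

def align_alleles(
    table: pd.DataFrame,
    panel: GenotypePanel,
    drop_ambiguous: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Align a weight/sumstats table to the panel's counted allele.

    Where the table's effect allele equals the panel's *other* allele the
    sign of ``beta``/``weight`` is flipped and ``eaf`` replaced by 1 - eaf.
    Variants whose alleles cannot be reconciled with the panel are dropped.
    Strand-ambiguous (A/T, C/G) variants are dropped by default since their
    orientation cannot be established.

    Returns the aligned table (panel allele coding) and a report dict with
    counts: ``matched, flipped, dropped_ambiguous, dropped_mismatch,
    dropped_absent``.
    """
    pv = panel.variants.set_index("id")
    report = dict(matched=0, flipped=0, dropped_ambiguous=0,
                  dropped_mismatch=0, dropped_absent=0)
    out_rows = []
    for row in table.itertuples(index=False):
        rec = row._asdict()
        vid = rec["id"]
        if vid not in pv.index:
            report["dropped_absent"] += 1
            continue
        ea, oa = str(rec["effect_allele"]), str(rec["other_allele"])
        if drop_ambiguous and (ea, oa) in AMBIGUOUS_PAIRS:
            report["dropped_ambiguous"] += 1
            continue
        a1, a2 = pv.at[vid, "a1"], pv.at[vid, "a2"]
        if ea == a1 and oa == a2:
            report["matched"] += 1
        elif ea == a2 and oa == a1:
            for col in ("beta", "weight"):
                if col in rec:
                    rec[col] = -rec[col]
            if "eaf" in rec:
                rec["eaf"] = 1.0 - rec["eaf"]
            rec["effect_allele"], rec["other_allele"] = a1, a2
            report["flipped"] += 1
        else:
            report["dropped_mismatch"] += 1
            continue
        out_rows.append(rec)
    if not out_rows:
        raise ValueError("no variants in the table could be aligned to the panel")
    return pd.DataFrame(out_rows), report
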