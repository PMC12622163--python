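"""Polygenic-index computation: weighted allele-count sums over dosages."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypePanel

__all__ = ["PGIVector", "compute_pgi"]


@dataclass
class PGIVector:
    """Raw and within-sample standardized polygenic index values."""

    samples: list[str]
    raw: np.ndarray
    standardized: np.ndarray
    n_variants_used: int
    coverage: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": self.samples,
            "raw": self.raw,
            "standardized": self.standardized,
            "n_variants_used": self.n_variants_used,
            "coverage": self.coverage,
        })


def compute_pgi(panel: GenotypePanel, weights: pd.DataFrame) -> PGIVector:
    """Raw score = sum_k weight_k x dosage_k; missing dosages mean-imputed.

    ``weights`` must already be aligned to the panel's counted allele
    (:func:`pgiport.io.align_alleles`).  The standardized score is a
    z-score within the scoring sample; a zero-variance score standardizes
    to zeros.
    """
    present = weights["id"].isin(panel.variants["id"])
    coverage = float(present.mean()) if len(weights) else 0.0
    if coverage == 0.0:
        raise ValueError("no weight-table variants found in the panel")
    if coverage < 0.5:
        warnings.warn(f"PGI coverage {coverage:.2f} < 0.5")
    used = weights.loc[present]
    idx = panel.variant_index(used["id"])
    x = panel.imputed_dosages()[:, idx]
    raw = x @ used["weight"].to_numpy(dtype=float)
    sd = raw.std()
    standardized = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)
    return PGIVector(samples=list(panel.samples), raw=raw,
                     standardized=standardized,
                     n_variants_used=int(present.sum()), coverage=coverage)
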