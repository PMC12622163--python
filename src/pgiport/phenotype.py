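"""Two-stage phenotype residualization on demographic covariates.

Multi-wave phenotypes: within each wave, OLS of the value on sex, a
second-degree polynomial in age at measurement, and sex-by-age interactions;
residuals standardized within wave; standardized residuals averaged across
a sample's available waves; the average residualized again on a third-degree
birth-year polynomial, sex, and their interactions.  Single-wave phenotypes
are residualized once on sex, the third-degree birth-year polynomial and
interactions.  Binary phenotypes run through the same linear (OLS) scheme.
Final residuals are z-scored, so the output is invariant to affine
rescaling of the raw phenotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ResidualizedPhenotype", "residualize"]

MIN_RECORDS_PER_WAVE = 30


@dataclass
class ResidualizedPhenotype:
    phenotype: str
    values: pd.Series          # index: sample_id, residual-scale values
    n_waves_used: int


def _design(cols: dict[str, np.ndarray]) -> np.ndarray:
    X = np.column_stack([np.ones(len(next(iter(cols.values()))))] + list(cols.values()))
    return X


def _ols_residuals(y: np.ndarray, X: np.ndarray, context: str) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    Xc[:, 0] = 1.0
    rank = np.linalg.matrix_rank(Xc)
    if rank < X.shape[1]:
        raise ValueError(
            f"collinear design in {context} (rank {rank} < {X.shape[1]} columns); "
            "for a sex-specific phenotype pass sex_specific=True")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def _standardize_guarded(r: np.ndarray, context: str, ref_scale: float = 1.0) -> np.ndarray:
    sd = r.std()
    if sd <= 1e-10 * max(ref_scale, 1e-30):
        warnings.warn(f"zero-variance residuals in {context}; returning zeros")
        return np.zeros_like(r)
    return (r - r.mean()) / sd


def residualize(pheno: pd.DataFrame, sex_specific: bool = False) -> ResidualizedPhenotype:
    """Residualize one phenotype's records on demographic covariates.

    ``pheno`` is a long table with columns ``sample_id, phenotype, value,
    sex, birth_year`` plus ``wave`` and ``age`` for multi-wave phenotypes;
    it must contain a single phenotype.  Records with any missing required
    covariate are dropped (the regression-complete subsample).
    """
    names = pheno["phenotype"].unique()
    if len(names) != 1:
        raise ValueError(f"expected a single phenotype, got {list(names)}")
    name = names[0]
    df = pheno.copy()
    waves = sorted(df["wave"].dropna().unique()) if "wave" in df else [1]
    multiwave = len(waves) > 1

    if multiwave:
        per_wave = []
        for w in waves:
            sub = df[df["wave"] == w].dropna(subset=["value", "sex", "age"])
            if len(sub) < MIN_RECORDS_PER_WAVE:
                raise ValueError(f"wave {w}: fewer than {MIN_RECORDS_PER_WAVE} complete records")
            age = sub["age"].to_numpy(dtype=float)
            sex = sub["sex"].to_numpy(dtype=float)
            cols = {"age": age, "age2": age ** 2}
            if not sex_specific:
                cols.update({"sex": sex, "sex_age": sex * age, "sex_age2": sex * age ** 2})
            yv = sub["value"].to_numpy(dtype=float)
            r = _ols_residuals(yv, _design(cols), f"wave {w} of {name}")
            per_wave.append(pd.Series(
                _standardize_guarded(r, f"wave {w} of {name}", ref_scale=yv.std()),
                index=sub["sample_id"].to_numpy()))
        stacked = pd.concat(per_wave, axis=1)
        averaged = stacked.mean(axis=1, skipna=True)  # samples missing a wave use available waves
        meta = (df.dropna(subset=["sex", "birth_year"])
                  .drop_duplicates("sample_id").set_index("sample_id"))
        common = averaged.index.intersection(meta.index)
        y = averaged.loc[common].to_numpy(dtype=float)
        by = meta.loc[common, "birth_year"].to_numpy(dtype=float)
        by = by - by.mean()
        sex = meta.loc[common, "sex"].to_numpy(dtype=float)
        cols = {"by": by, "by2": by ** 2, "by3": by ** 3}
        if not sex_specific:
            cols.update({"sex": sex, "sex_by": sex * by, "sex_by2": sex * by ** 2,
                         "sex_by3": sex * by ** 3})
        resid = _ols_residuals(y, _design(cols), f"second stage of {name}")
        resid = _standardize_guarded(resid, f"second stage of {name}",
                                     ref_scale=float(np.std(y)))
        return ResidualizedPhenotype(phenotype=name,
                                     values=pd.Series(resid, index=common),
                                     n_waves_used=len(waves))

    sub = df.dropna(subset=["value", "sex", "birth_year"])
    if len(sub) < MIN_RECORDS_PER_WAVE:
        raise ValueError(f"fewer than {MIN_RECORDS_PER_WAVE} complete records")
    by = sub["birth_year"].to_numpy(dtype=float)
    by = by - by.mean()
    sex = sub["sex"].to_numpy(dtype=float)
    cols = {"by": by, "by2": by ** 2, "by3": by ** 3}
    if not sex_specific:
        cols.update({"sex": sex, "sex_by": sex * by, "sex_by2": sex * by ** 2,
                     "sex_by3": sex * by ** 3})
    yv = sub["value"].to_numpy(dtype=float)
    resid = _ols_residuals(yv, _design(cols), name)
    resid = _standardize_guarded(resid, name, ref_scale=yv.std())
    return ResidualizedPhenotype(phenotype=name,
                                 values=pd.Series(resid, index=sub["sample_id"].to_numpy()),
                                 n_waves_used=1)
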