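import numpy as np
import pandas as pd
import pytest

from pgiport.io import GenotypePanel


def make_panel(dosages, pos=None, chrom="1", ids=None, a1="A", a2="G",
               ancestry=None, samples=None):
    """Small helper to build a panel from a raw dosage matrix."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    ids = ids if ids is not None else [f"snp{j}" for j in range(m)]
    pos = pos if pos is not None else 1 + 1000 * np.arange(m)
    variants = pd.DataFrame({
        "id": ids, "chrom": chrom, "pos": pos,
        "a1": [a1] * m if isinstance(a1, str) else a1,
        "a2": [a2] * m if isinstance(a2, str) else a2,
    })
    samples = samples if samples is not None else [f"s{i}" for i in range(n)]
    return GenotypePanel(samples=samples, variants=variants, dosages=dosages,
                         ancestry=None if ancestry is None else np.asarray(ancestry))


@pytest.fixture
def rng():
    return np.random.default_rng(7)


def random_panel(rng, n=60, m=20, maf_low=0.1, maf_high=0.5, missing=0.0, **kw):
    freqs = rng.uniform(maf_low, maf_high, size=m)
    dosages = rng.binomial(2, freqs, size=(n, m)).astype(float)
    if missing > 0:
        mask = rng.random((n, m)) < missing
        dosages[mask] = np.nan
    return make_panel(dosages, **kw)
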