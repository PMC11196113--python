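import numpy as np
import pandas as pd
import pytest

from ildsc.genio import MISSING, GenotypePanel


def make_panel(rng, n=20, j=50, missing_rate=0.0, n_chrom=1):
    """Random valid genotype panel (evenly spaced bp, optional missing calls)."""
    geno = rng.integers(0, 3, size=(n, j)).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random((n, j)) < missing_rate
        geno[mask] = MISSING
    per_chrom = j // n_chrom
    chrom = np.repeat([str(c + 1) for c in range(n_chrom)], per_chrom)[:j]
    if len(chrom) < j:
        chrom = np.concatenate([chrom, [chrom[-1]] * (j - len(chrom))])
    bp = np.concatenate(
        [(np.arange((chrom == c).sum()) + 1) * 1000 for c in pd.unique(chrom)]
    )
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "id": [f"rs{i}" for i in range(j)],
            "cm": bp * 1e-6,
            "bp": bp,
            "a1": "A",
            "a2": "G",
        }
    )
    return GenotypePanel(genotypes=geno, variants=variants)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_panel(rng):
    return make_panel(rng, n=20, j=50)
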