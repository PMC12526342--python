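import numpy as np
import pandas as pd
import pytest

from aridpop.io_core import GenotypeMatrix


def make_sites(n, chrom="PC1", start=1, spacing=10, qual=100.0):
    """Plain biallelic SNP site frame for hand-built fixtures."""
    return pd.DataFrame({
        "chromosome": [chrom] * n,
        "position": [start + i * spacing for i in range(n)],
        "ref": ["A"] * n,
        "alt": ["T"] * n,
        "qual": [qual] * n,
        "biallelic": [True] * n,
        "is_snp": [True] * n,
    })


def make_gm(dosage, **kwargs):
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    ids = [f"s{i}" for i in range(n)]
    return GenotypeMatrix(ids, make_sites(m), dosage, sort=False, **kwargs)


@pytest.fixture
def two_deme_gm():
    """Two demes of 5 with fixed differences at every second site."""
    rng = np.random.default_rng(0)
    dosage = rng.integers(0, 3, size=(10, 40)).astype(np.int8)
    dosage[:5, ::2] = 0
    dosage[5:, ::2] = 2
    return make_gm(dosage)
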