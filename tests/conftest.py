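import numpy as np
import pandas as pd
import pytest

from penrisk.types import GenotypeMatrix


def make_genotypes(dosages, sample_ids=None, snp_ids=None) -> GenotypeMatrix:
    dosages = np.asarray(dosages, dtype=float)
    n, p = dosages.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    snp_ids = snp_ids or [f"snp{j}" for j in range(p)]
    meta = pd.DataFrame(
        {
            "id": snp_ids,
            "chrom": 1,
            "pos": np.arange(1, p + 1),
            "allele1": "A",
            "allele2": "G",
        }
    )
    return GenotypeMatrix(sample_ids, meta, dosages)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_logistic_data(rng):
    """A well-conditioned 40 x 4 binary-response instance."""
    n, p = 40, 4
    X = rng.standard_normal((n, p))
    beta = np.array([1.0, -0.6, 0.0, 0.4])
    prob = 1.0 / (1.0 + np.exp(-(X @ beta)))
    y = (rng.random(n) < prob).astype(int)
    return X, y
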