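import numpy as np
import pandas as pd
import pytest

from gsarch.genomatrix import GenotypeMatrix
from gsarch.simdata import SimConfig, simulate_dataset


def make_geno(dosages, pos=None, chrom=None, ids=None):
    """Build a GenotypeMatrix from a raw dosage array for small tests."""
    dosages = np.asarray(dosages, dtype=float)
    m = dosages.shape[1]
    meta = pd.DataFrame({
        "id": ids if ids is not None else [f"m{j}" for j in range(m)],
        "chrom": chrom if chrom is not None else ["1"] * m,
        "pos": pos if pos is not None else np.arange(1, m + 1) * 1000,
        "ref": ["A"] * m,
        "alt": ["B"] * m,
    })
    return GenotypeMatrix(dosages, meta)


@pytest.fixture(scope="session")
def sim_small():
    """Shared small synthetic study (300 cows x 600 markers)."""
    return simulate_dataset(SimConfig(n_individuals=300, n_markers=600,
                                      h2=(0.5, 0.5, 0.5, 0.5), seed=11))


@pytest.fixture(scope="session")
def geno_hwe():
    """500 x 60 genotypes drawn under Hardy-Weinberg equilibrium."""
    rng = np.random.default_rng(7)
    f = rng.uniform(0.1, 0.5, 60)
    dos = (rng.random((500, 60)) < f).astype(float) + \
          (rng.random((500, 60)) < f)
    return make_geno(dos)
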