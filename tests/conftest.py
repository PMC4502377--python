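import numpy as np
import pandas as pd
import pytest

from palmpop import GenotypeMatrix, SimConfig, simulate_dataset


def make_matrix(dosage, depth=None, pl=None, samples=None, loci=None):
    """Build a GenotypeMatrix from a plain dosage array (helper for tests)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    samples = samples or [f"s{i}" for i in range(n)]
    if loci is None:
        loci = pd.DataFrame(
            {
                "contig": [f"ctg{j % 3}" for j in range(m)],
                "pos": [100 + 10 * j for j in range(m)],
                "ref": ["A"] * m,
                "alt": ["G"] * m,
            }
        )
    return GenotypeMatrix(samples, loci, dosage, depth, pl)


@pytest.fixture(scope="session")
def two_pop_sim():
    """Small diverged two-population dataset with admixed samples and truth."""
    cfg = SimConfig(
        n_loci=400,
        n_per_pop=(20, 20),
        n_admixed=4,
        fst_true=0.3,
        n_outgroup=2,
        n_duplicates=2,
        missing_rate=0.03,
        seed=20240,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
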