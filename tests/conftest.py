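import numpy as np
import pytest

from agblup.genotype_io import GenotypeMatrix
from agblup.simulate import SimScenario, simulate_genotypes, simulate_phenotypes


@pytest.fixture(scope="session")
def small_panel():
    """50 individuals x 200 markers, complete, no LD."""
    return simulate_genotypes(50, 200, seed=11)


@pytest.fixture(scope="session")
def trait_panel():
    """A moderately sized panel with a major-gene trait and known truth."""
    g = simulate_genotypes(200, 400, seed=21)
    y, tbv, causal = simulate_phenotypes(g, SimScenario.major_genes(0.5, 8), seed=22)
    return g, y, tbv, causal


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def make_genotypes(values, ids=None):
    """Wrap a raw dosage array (NaN = missing) in a GenotypeMatrix."""
    import pandas as pd

    values = np.asarray(values, dtype=float)
    n, m = values.shape
    markers = pd.DataFrame(
        {
            "id": [f"M{k:04d}" for k in range(m)],
            "chrom": "1",
            "pos": np.arange(1, m + 1) * 100,
            "allele_coded": "A",
            "allele_other": "B",
        }
    )
    return GenotypeMatrix(values, ids or [f"I{i}" for i in range(n)], markers)
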