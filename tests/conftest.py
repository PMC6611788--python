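import numpy as np
import pytest

from popdecline.genotypes import GenotypeMatrix


def make_matrix(dosage, populations=None, loci=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a plain array with generated labels."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, L = dosage.shape
    samples = [f"s{i}" for i in range(n)]
    if populations is None:
        populations = ["pop1"] * n
    loci = loci or [f"l{j}" for j in range(L)]
    return GenotypeMatrix(
        samples=samples,
        population_of=dict(zip(samples, populations)),
        loci=list(loci),
        dosage=dosage,
    )


@pytest.fixture
def small_panel():
    """8 samples x 6 loci across two populations, with some missing calls."""
    rng = np.random.default_rng(42)
    dosage = rng.integers(0, 3, size=(8, 6)).astype(np.int8)
    dosage[0, 1] = -1
    dosage[3, 4] = -1
    return make_matrix(dosage, populations=["A"] * 4 + ["B"] * 4)
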