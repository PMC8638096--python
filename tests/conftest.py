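import numpy as np
import pytest

from msnstat import CountMatrix, MutationKey


@pytest.fixture
def biopsy_counts():
    """Two EGFR mutations in two serial biopsies (T790M 40/72 → 0/15,
    C797S 5/100 → 0/30)."""
    from msnstat.io import _biopsy_example

    return _biopsy_example()


@pytest.fixture
def five_sample_counts():
    """One mutation in five samples A–E: 10/20, 0/20, 4/9, 0/8, 0/5."""
    from msnstat.io import _five_sample_example

    return _five_sample_example()


def random_count_matrix(seed: int, n_mut: int = 10, n_samp: int = 5) -> CountMatrix:
    """Seeded random matrix with a mix of covered, shallow and missing cells."""
    rng = np.random.default_rng(seed)
    mutations = [MutationKey(f"chr{1 + i % 3}", 100 + i, "A", "C") for i in range(n_mut)]
    samples = [f"s{j}" for j in range(n_samp)]
    total = rng.integers(0, 250, size=(n_mut, n_samp))
    total[rng.random(total.shape) < 0.1] = 0  # missing measurements
    vaf = rng.choice([0.0, 0.02, 0.2, 0.5], size=(n_mut, n_samp))
    mutant = rng.binomial(total, vaf)
    return CountMatrix(mutations, samples, mutant, total)
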