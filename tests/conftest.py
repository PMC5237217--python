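import numpy as np
import pytest

from hybridpanel.genotypes import GenotypeMatrix, Locus
from hybridpanel.synthetic import (FrequencyScenario, make_frequency_profile,
                                   sample_population)


@pytest.fixture(scope="session")
def diagnostic_freqs():
    """Fully diagnostic 50-locus two-population frequency profile."""
    return make_frequency_profile(
        FrequencyScenario(n_loci=50, scenario="diagnostic"), seed=11)


@pytest.fixture(scope="session")
def diagnostic_pures(diagnostic_freqs):
    """95 + 95 pure individuals sampled from fixed frequencies."""
    pure_a = sample_population(diagnostic_freqs, "A", 95, seed=21)
    pure_b = sample_population(diagnostic_freqs, "B", 95, seed=22)
    return pure_a, pure_b


def tiny_matrix():
    """2 individuals x 2 loci with one missing call."""
    loci = [Locus("loc1", allele_a="A", allele_b="G"),
            Locus("loc2", allele_a="C", allele_b="T")]
    calls = np.array([[0, 1], [2, -1]], dtype=np.int8)
    return GenotypeMatrix(loci, ["ind1", "ind2"], ["popX", "popY"], calls)
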