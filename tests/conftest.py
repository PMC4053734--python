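import numpy as np
import pytest

from chance_qc.fixtures import EnrichmentSpec, _as_coverage, gen_binned_pair
from chance_qc.genome_io import GenomeTable


@pytest.fixture
def genome():
    return GenomeTable((("chr1", 5000), ("chr2", 2500)))


@pytest.fixture
def small_pair():
    """Planted 10%-enriched pair at 5k bins (fast, strong signal)."""
    return gen_binned_pair(EnrichmentSpec(n_bins=5000, seed=11))


@pytest.fixture
def null_pair():
    """Two technical replicates of one Poisson-Gamma background."""
    rng = np.random.default_rng(7)
    lam = rng.gamma(2.0, 3.0, 5000)
    return _as_coverage(rng.poisson(lam)), _as_coverage(rng.poisson(lam))
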