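import numpy as np
import pytest

from altiscan.core import HaplotypeMatrix


def random_hap_matrix(rng, n_hap=8, n_sites=12, span=10_000, pops=None):
    """Small random haplotype matrix; sites polymorphic, positions sorted."""
    positions = np.sort(rng.choice(span, size=n_sites, replace=False))
    alleles = rng.integers(0, 2, size=(n_hap, n_sites)).astype(np.uint8)
    for j in range(n_sites):              # keep every site polymorphic
        if alleles[:, j].all() or not alleles[:, j].any():
            alleles[rng.integers(0, n_hap), j] ^= 1
    if pops is None:
        pops = np.array(["all"] * n_hap)
    ids = [f"s{i}" for i in range(n_hap // 2)]
    return HaplotypeMatrix("chr1", positions, alleles, pops, ids)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def hap_factory():
    return random_hap_matrix
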