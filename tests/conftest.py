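import numpy as np
import pytest

from radpopgen.genotypes import GenotypeMatrix, LocusInfo, SampleInfo


def make_matrix(rows, sites, tags=None, quals=None, positions=None):
    """Small GenotypeMatrix from a list of per-individual dosage rows."""
    geno = np.asarray(rows, dtype=np.int8)
    n, L = geno.shape
    tags = tags or [f"tag{j}" for j in range(L)]
    quals = quals or [50.0] * L
    positions = positions or [1 + j for j in range(L)]
    loci = [
        LocusInfo(f"L{j}", tags[j], positions[j], "A", "C", quals[j])
        for j in range(L)
    ]
    samples = [SampleInfo(f"ind{i}", sites[i]) for i in range(n)]
    return GenotypeMatrix(geno, loci, samples)


@pytest.fixture
def two_pop_toy():
    """6 individuals, 2 sites, 3 loci with real differentiation."""
    rows = [
        [0, 1, 2],
        [0, 0, 1],
        [1, 1, 2],
        [2, 1, 0],
        [2, 2, 0],
        [1, 2, 1],
    ]
    return make_matrix(rows, ["P1"] * 3 + ["P2"] * 3)


@pytest.fixture
def bn_small():
    from radpopgen.synthetic import generate_balding_nichols

    G, manifest = generate_balding_nichols(
        K_sites=3, n_per_site=20, L=300, F_per_site=0.02, seed=11
    )
    return G, manifest
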