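import numpy as np
import pytest

from episubnet.diffnet import NORMAL, TUMOR, OmicsMatrix


def block_similarity(block_sizes, within=1.0, cross=0.0, rng=None, jitter=0.0):
    """Block-structured symmetric similarity matrix with zero diagonal."""
    n = sum(block_sizes)
    a = np.full((n, n), cross, dtype=float)
    start = 0
    for size in block_sizes:
        a[start:start + size, start:start + size] = within
        start += size
    if jitter and rng is not None:
        noise = rng.uniform(0, jitter, size=(n, n))
        a = a + (noise + noise.T) / 2
    np.fill_diagonal(a, 0.0)
    return a


def make_omics(values, n_tumor, n_normal, gene_prefix="g"):
    values = np.asarray(values, dtype=float)
    genes = [f"{gene_prefix}{i}" for i in range(values.shape[0])]
    samples = [f"s{i}" for i in range(values.shape[1])]
    condition = np.array([TUMOR] * n_tumor + [NORMAL] * n_normal, dtype=object)
    return OmicsMatrix(values, genes, samples, condition)


@pytest.fixture(scope="session")
def null_network():
    """10,000 independent null edges: iid genes, disjoint-pair PPI."""
    from episubnet.diffnet import InteractionNetwork, build_differential_network

    rng = np.random.default_rng(7)
    n_genes, n_t, n_n = 20_000, 103, 103
    omics = make_omics(rng.standard_normal((n_genes, n_t + n_n)), n_t, n_n)
    ppi = InteractionNetwork([(f"g{2 * i}", f"g{2 * i + 1}") for i in range(n_genes // 2)])
    return build_differential_network(omics, ppi)
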