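import numpy as np
import pytest

from mucloc.synthetic_data import ClusterSpec, build_cluster_genome


@pytest.fixture(scope="session")
def cluster():
    """A deterministic 3-gene synthetic cluster with ground truth."""
    spec = ClusterSpec(seed=7)
    contig, truth = build_cluster_genome(spec)
    return spec, contig, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def random_protein(rng, n, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), n)])
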