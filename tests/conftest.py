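import numpy as np
import pytest

from seqpower import CountMatrix, PilotSpec, StudyDesign, generate_pilot


@pytest.fixture(scope="session")
def small_pilot():
    """A small but realistic two-condition pilot shared across test modules."""
    spec = PilotSpec(
        n_genes=300,
        replicates_per_condition=8,
        target_library_size=50_000,
        pi_de=0.3,
        seed=42,
    )
    return generate_pilot(spec)


@pytest.fixture()
def two_group_design():
    def make(n_a, n_b, labels=("A", "B")):
        assignments = {}
        for i in range(n_a):
            assignments[f"{labels[0]}_{i + 1}"] = labels[0]
        for i in range(n_b):
            assignments[f"{labels[1]}_{i + 1}"] = labels[1]
        return StudyDesign(assignments)

    return make


@pytest.fixture()
def matrix_from_array():
    def make(counts, sample_ids=None, gene_ids=None):
        counts = np.asarray(counts)
        g, s = counts.shape
        return CountMatrix(
            tuple(gene_ids) if gene_ids else tuple(f"g{i + 1}" for i in range(g)),
            tuple(sample_ids) if sample_ids else tuple(f"s{j + 1}" for j in range(s)),
            counts,
        )

    return make
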