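import numpy as np
import pytest

from omicload import (
    GeneratorConfig,
    OmicsMatrix,
    PathwayAnnotation,
    SampleDescriptor,
    generate_dataset,
    standardize,
)


def make_samples(conditions, layers=("transcript", "protein")):
    suffix = {"transcript": "RNA", "protein": "PROT"}
    return [
        SampleDescriptor(f"{c}_{suffix[l]}", c, l)
        for c in conditions
        for l in layers
    ]


def random_omics_matrix(rng, n_genes=30, conditions=("LB20", "LB60")):
    """Random positive abundance matrix over condition x layer columns."""
    samples = make_samples(conditions)
    values = 2.0 ** rng.normal(8.0, 1.0, (n_genes, len(samples)))
    genes = [f"g{i:03d}" for i in range(n_genes)]
    return OmicsMatrix(gene_ids=genes, samples=samples, values=values)


def random_standardized(rng, n_genes=30, conditions=("LB20", "LB60")):
    return standardize(random_omics_matrix(rng, n_genes, conditions), "none")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_matrix(rng):
    return random_omics_matrix(rng)


@pytest.fixture
def std_matrix(rng):
    return random_standardized(rng)


@pytest.fixture
def annotation():
    return PathwayAnnotation.from_records(
        [
            ("g000", "pwA", "pathway A"),
            ("g001", "pwA", "pathway A"),
            ("g002", "pwA", "pathway A"),
            ("g003", "pwB", "pathway B"),
            ("g004", "pwB", "pathway B"),
            ("g005", "pwB", "pathway B"),
            ("g000", "pwB", "pathway B"),
        ]
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A desk-size synthetic dataset with one strongly planted pathway."""
    cfg = GeneratorConfig(
        n_genes=400, n_pathways=8, genes_per_pathway=20, seed=7
    )
    return generate_dataset(cfg)
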