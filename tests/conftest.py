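import numpy as np
import pytest

from xsmono.io_formats import ExpressionMatrix, GeneSetCollection, RankedList


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples, 2 control vs 2 treated, exact values."""
    return ExpressionMatrix(
        gene_ids=["gA", "gB", "gC"],
        sample_ids=["c1", "c2", "t1", "t2"],
        values=np.array(
            [
                [1.0, 2.0, 3.0, 4.0],  # up in treatment
                [5.0, 5.0, 5.0, 5.0],  # flat
                [4.0, 3.0, 2.0, 1.0],  # down in treatment
            ]
        ),
        groups={"c1": "control", "c2": "control", "t1": "ami", "t2": "ami"},
    )


@pytest.fixture
def three_gene_ranked() -> RankedList:
    return RankedList.from_scores(["g1", "g2", "g3"], [3.0, 2.0, 1.0])


@pytest.fixture
def random_matrix_factory():
    """Pure-noise two-group matrices of arbitrary size."""

    def make(n_genes=500, n_per_group=(4, 4), seed=0, labels=("control", "ami")):
        rng = np.random.default_rng(seed)
        n = sum(n_per_group)
        genes = [f"g{i:05d}" for i in range(n_genes)]
        samples = [f"s{i}" for i in range(n)]
        groups = {
            s: (labels[0] if i < n_per_group[0] else labels[1]) for i, s in enumerate(samples)
        }
        return ExpressionMatrix(
            genes, samples, rng.normal(8.0, 1.0, size=(n_genes, n)), groups, treatment=labels[1]
        )

    return make


@pytest.fixture
def small_collection() -> GeneSetCollection:
    return GeneSetCollection.from_dict(
        {"SETA": ["g1", "g2"], "SETB": ["g2", "g3"]}, description="toy"
    )
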