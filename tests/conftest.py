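import numpy as np
import pytest

from grnmotif import EdgeList, ExpressionMatrix


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(10)]
    return ExpressionMatrix(
        gene_ids=genes,
        cell_ids=[f"c{j}" for j in range(20)],
        values=rng.poisson(5.0, size=(10, 20)).astype(float),
    )


@pytest.fixture
def small_network() -> EdgeList:
    return EdgeList(edges={("g0", "g2"), ("g0", "g3"), ("g1", "g4")})
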