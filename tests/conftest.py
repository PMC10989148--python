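import numpy as np
import pandas as pd
import pytest

from coexpanel.annotations import align_annotations
from coexpanel.core_data import ExpressionMatrix, log_normalize
from coexpanel.dgi import GCNConfig, train_and_embed
from coexpanel.fixtures import FixtureSpec, generate_dataset
from coexpanel.graph_builder import graph_from_dataset


@pytest.fixture
def tiny_expr():
    data = pd.DataFrame(
        {
            "dark_1": [0.0, 10.0, 100.0],
            "dark_2": [0.5, 12.0, 110.0],
            "blue_1": [0.0, 95.0, 105.0],
            "blue_2": [0.4, 105.0, 95.0],
        },
        index=["g1", "g2", "g3"],
    )
    design = {"dark_1": "dark", "dark_2": "dark", "blue_1": "blue", "blue_2": "blue"}
    return ExpressionMatrix(data, design)


@pytest.fixture(scope="session")
def planted():
    """600-gene planted fixture shared across the slower tests."""
    spec = FixtureSpec(n_genes=600, seed=0)
    expr, annot, truth = generate_dataset(spec)
    return spec, expr, annot, truth


@pytest.fixture(scope="session")
def planted_graph(planted):
    _, expr, annot, _ = planted
    norm = log_normalize(expr.data)
    aligned = align_annotations(annot, norm.index)
    return graph_from_dataset(norm, aligned, seed=0)


@pytest.fixture(scope="session")
def planted_embeddings(planted_graph):
    emb, state = train_and_embed(planted_graph, GCNConfig(seed=1))
    return emb, state
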