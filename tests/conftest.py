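import networkx as nx
import numpy as np
import pandas as pd
import pytest

from activesem import ExpressionData, GroundTruthModel, PathwayGraph
from activesem.data_io import DIRECTED


@pytest.fixture
def small_expression() -> ExpressionData:
    values = pd.DataFrame(
        np.arange(12, dtype=float).reshape(3, 4),
        index=["gA", "gB", "gC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    group = pd.Series([1, 1, 0, 0], index=values.columns)
    return ExpressionData(values, group)


def pathway_from_edges(name: str, edges, nodes=()) -> PathwayGraph:
    pw = PathwayGraph(name=name)
    pw.graph.add_nodes_from(nodes)
    for e in edges:
        u, v = e[:2]
        orient = e[2] if len(e) > 2 else DIRECTED
        pw.add_edge(u, v, orient)
    return pw


@pytest.fixture
def chain_model() -> GroundTruthModel:
    """A -> B chain with beta 0.5 in both groups and no group effect."""
    dag = nx.DiGraph([("A", "B")])
    return GroundTruthModel(
        dag=dag,
        beta_case={("A", "B"): 0.5},
        beta_ctrl={("A", "B"): 0.5},
        seed=7,
    )
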