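"""Case-control expression simulator with known causal ground truth.

Data are drawn from a linear-Gaussian structural equation model over a known
DAG: each gene, in topological order, is a linear function of its parents
plus an additive case-status effect and Gaussian noise.  Edge coefficients
may differ between cases and controls (edge perturbation) and nodes may
carry a group effect (node perturbation), so every downstream stage —
gene-set analysis, differential-correlation weighting, Steiner-tree
extraction, SEM fitting — can be scored against a planted truth.

The default study shape mirrors a small colonic-biopsy RNA-seq cohort:
17 cases and 18 controls, pathway graphs of a few dozen genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .data_io import DIRECTED, ExpressionData, PathwayGraph

__all__ = [
    "GroundTruthModel",
    "generate_dag",
    "simulate_expression",
    "warp_marginals",
    "generate_pathway_suite",
    "simulate_study",
    "DEFAULT_N_CASE",
    "DEFAULT_N_CTRL",
]

#: Default cohort size, matching the analyzed IBS-D study shape.
DEFAULT_N_CASE = 17
DEFAULT_N_CTRL = 18


@dataclass
class GroundTruthModel:
    """A linear-Gaussian SEM over a DAG, with per-group edge coefficients.

    ``beta_case`` / ``beta_ctrl`` map each DAG edge (u, v) to the coefficient
    of u in v's structural equation for that group; ``group_effect`` is the
    additive effect of case status (group = 1) on each node; ``noise_sd`` is
    the residual standard deviation per node.
    """

    dag: nx.DiGraph
    beta_case: dict[tuple[str, str], float]
    beta_ctrl: dict[tuple[str, str], float]
    group_effect: dict[str, float] = field(default_factory=dict)
    noise_sd: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.dag):
            raise ValueError("ground-truth graph must be acyclic")
        edges = set(self.dag.edges())
        for name, bmap in (("beta_case", self.beta_case), ("beta_ctrl", self.beta_ctrl)):
            if set(bmap) != edges:
                raise ValueError(f"{name} must be defined exactly on the DAG edges")
        for node in self.dag.nodes:
            self.group_effect.setdefault(node, 0.0)
            self.noise_sd.setdefault(node, 1.0)
        if any(sd <= 0 for sd in self.noise_sd.values()):
            raise ValueError("noise_sd must be positive")

    @classmethod
    def random(
        cls,
        n_nodes: int = 10,
        edge_prob: float = 0.3,
        n_perturbed_nodes: int = 3,
        n_perturbed_edges: int = 2,
        effect_size: float = 1.0,
        beta_scale: float = 0.6,
        seed: int = 0,
        prefix: str = "g",
    ) -> "GroundTruthModel":
        """Draw a random model: random DAG, betas ~ U(±[0.3, beta_scale+0.3]),
        group effects of ±``effect_size`` on ``n_perturbed_nodes`` nodes and
        case-control coefficient differences on ``n_perturbed_edges`` edges."""
        rng = np.random.default_rng(seed)
        dag = generate_dag(n_nodes, edge_prob, seed=int(rng.integers(2**31)), prefix=prefix)
        edges = sorted(dag.edges())
        sign = lambda: rng.choice([-1.0, 1.0])
        beta_ctrl = {e: sign() * rng.uniform(0.3, 0.3 + beta_scale) for e in edges}
        beta_case = dict(beta_ctrl)
        if edges and n_perturbed_edges:
            idx = rng.choice(len(edges), size=min(n_perturbed_edges, len(edges)), replace=False)
            for i in idx:
                beta_case[edges[i]] = beta_ctrl[edges[i]] + sign() * effect_size
        nodes = sorted(dag.nodes)
        group_effect = {v: 0.0 for v in nodes}
        if n_perturbed_nodes:
            idx = rng.choice(len(nodes), size=min(n_perturbed_nodes, len(nodes)), replace=False)
            for i in idx:
                group_effect[nodes[i]] = sign() * effect_size
        return cls(
            dag=dag,
            beta_case=beta_case,
            beta_ctrl=beta_ctrl,
            group_effect=group_effect,
            noise_sd={v: 1.0 for v in nodes},
            seed=seed,
        )


def generate_dag(n_nodes: int, edge_prob: float, seed: int = 0, prefix: str = "g") -> nx.DiGraph:
    """Random DAG: draw a topological order uniformly, then include each
    forward edge independently with probability ``edge_prob``."""
    if not 0.0 <= edge_prob <= 1.0:
        raise ValueError("edge_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    names = [f"{prefix}{i + 1}" for i in range(n_nodes)]
    order = list(rng.permutation(names))
    dag = nx.DiGraph()
    dag.add_nodes_from(names)
    for i, u in enumerate(order):
        for v in order[i + 1 :]:
            if rng.random() < edge_prob:
                dag.add_edge(u, v)
    assert nx.is_directed_acyclic_graph(dag)
    return dag


def simulate_expression(
    model: GroundTruthModel,
    n_case: int = DEFAULT_N_CASE,
    n_ctrl: int = DEFAULT_N_CTRL,
    seed: int | None = None,
) -> ExpressionData:
    """Sample expression for ``n_case`` cases and ``n_ctrl`` controls.

    Nodes are sampled in topological order:
    ``x_j = group_effect_j * g + sum_i beta_group(i->j) x_i + eps_j`` with
    ``eps_j ~ N(0, noise_sd_j)``.  Group sizes below 4 are rejected because
    Fisher's r-to-z test downstream needs n - 3 > 0.
    """
    if n_case < 4 or n_ctrl < 4:
        raise ValueError("need at least 4 samples per group")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    order = list(nx.topological_sort(model.dag))
    samples = [f"case{i + 1}" for i in range(n_case)] + [f"ctrl{i + 1}" for i in range(n_ctrl)]
    g = np.concatenate([np.ones(n_case), np.zeros(n_ctrl)])
    n = n_case + n_ctrl
    x = {v: np.zeros(n) for v in order}
    for v in order:
        val = model.group_effect[v] * g + rng.normal(0.0, model.noise_sd[v], size=n)
        for u in model.dag.predecessors(v):
            beta = np.where(g == 1, model.beta_case[(u, v)], model.beta_ctrl[(u, v)])
            val = val + beta * x[u]
        x[v] = val
    values = pd.DataFrame({s: [x[v][j] for v in sorted(order)] for j, s in enumerate(samples)},
                          index=sorted(order))
    group = pd.Series(g.astype(int), index=samples)
    return ExpressionData(values, group)


_WARPS = {
    "identity": lambda x: x,
    "exp": np.exp,
    "cube": lambda x: x**3,
    "logistic": lambda x: 1.0 / (1.0 + np.exp(-x)),
}


def warp_marginals(data: ExpressionData, warp: str = "exp") -> ExpressionData:
    """Pass every gene through a strictly monotone map, destroying Gaussian
    marginals while preserving per-gene ranks (a Gaussian-copula dataset)."""
    if warp not in _WARPS:
        raise ValueError(f"unknown warp {warp!r}; choose from {sorted(_WARPS)}")
    f = _WARPS[warp]
    return ExpressionData(
        pd.DataFrame(f(data.values.to_numpy()), index=data.values.index, columns=data.values.columns),
        data.group.copy(),
    )


def _pathway_from_dag(name: str, dag: nx.DiGraph) -> PathwayGraph:
    pw = PathwayGraph(name=name)
    pw.graph.add_nodes_from(dag.nodes)
    for u, v in dag.edges():
        pw.graph.add_edge(u, v, orientation=DIRECTED)
    return pw


def generate_pathway_suite(
    model: GroundTruthModel,
    n_null_pathways: int = 5,
    seed: int = 0,
    null_size: int = 10,
    null_edge_prob: float = 0.3,
) -> list[PathwayGraph]:
    """One perturbed pathway (the ground-truth DAG) plus null pathways over
    fresh genes that carry no group effect.  The perturbed pathway comes
    first and is named ``"perturbed"``."""
    rng = np.random.default_rng(seed)
    suite = [_pathway_from_dag("perturbed", model.dag)]
    for k in range(n_null_pathways):
        dag = generate_dag(null_size, null_edge_prob, seed=int(rng.integers(2**31)),
                           prefix=f"null{k + 1}_")
        suite.append(_pathway_from_dag(f"null{k + 1}", dag))
    return suite


def simulate_study(
    model: GroundTruthModel,
    n_null_pathways: int = 5,
    n_case: int = DEFAULT_N_CASE,
    n_ctrl: int = DEFAULT_N_CTRL,
    seed: int = 0,
    null_size: int = 10,
    null_edge_prob: float = 0.3,
    null_beta: float = 0.5,
) -> tuple[ExpressionData, list[PathwayGraph], GroundTruthModel]:
    """Full synthetic study: the perturbed pathway plus nulls, with one
    expression matrix covering every pathway's genes.

    Null-pathway genes follow the same linear-Gaussian family with equal
    coefficients in both groups (``null_beta`` on each null edge) and zero
    group effects, so they satisfy the no-perturbation null exactly.
    Returns (expression, pathways, combined model).
    """
    rng = np.random.default_rng(seed)
    pathways = generate_pathway_suite(model, n_null_pathways, seed=int(rng.integers(2**31)),
                                      null_size=null_size, null_edge_prob=null_edge_prob)
    combined = nx.DiGraph(model.dag)
    beta_case = dict(model.beta_case)
    beta_ctrl = dict(model.beta_ctrl)
    group_effect = dict(model.group_effect)
    noise_sd = dict(model.noise_sd)
    for pw in pathways[1:]:
        combined.add_nodes_from(pw.graph.nodes)
        for u, v in pw.graph.edges():
            combined.add_edge(u, v)
            beta_case[(u, v)] = beta_ctrl[(u, v)] = null_beta
        for v in pw.graph.nodes:
            group_effect.setdefault(v, 0.0)
            noise_sd.setdefault(v, 1.0)
    combined_model = GroundTruthModel(
        dag=combined, beta_case=beta_case, beta_ctrl=beta_ctrl,
        group_effect=group_effect, noise_sd=noise_sd, seed=int(rng.integers(2**31)),
    )
    data = simulate_expression(combined_model, n_case=n_case, n_ctrl=n_ctrl)
    return data, pathways, combined_model
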