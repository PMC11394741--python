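"""SEM fitting of the active module: DAG search, group-wise effect
estimation, and node/edge perturbation testing.

The Steiner tree fixes an undirected skeleton; a causal order estimated by
greedy BIC orients it, and node-wise Lasso over order-compatible candidate
parents (tree parents unpenalized) may add a few non-tree edges where they
pay for themselves in BIC.  Three Gaussian SEMs are then fitted on
standardized data:

* Model A — cases only: per-edge standardized coefficients beta with
  de-biased (OLS-refit) z-tests;
* Model B — controls only, same DAG;
* Model C — node and edge perturbation: the group enters as an exogenous
  parent of every gene (node effects b), and edge perturbations are the
  coefficient differences ``db = beta_A - beta_B`` with standard errors
  pooled in quadrature.

Fit quality is summarized by the SRMR between observed and model-implied
correlation matrices; indirect effects are exact sums over directed paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso

from .active_module import SteinerTree
from .data_io import ExpressionData

__all__ = [
    "ActiveModuleDAG",
    "SemFit",
    "PerturbationFit",
    "search_optimal_dag",
    "fit_sem_group",
    "fit_perturbation_model",
    "srmr",
    "indirect_effects",
]


@dataclass
class ActiveModuleDAG:
    """Oriented active module: a DAG over the tree's genes.

    ``order`` is the estimated causal order; ``added_edges`` are edges the
    sparsity search introduced beyond the oriented tree skeleton.
    """

    graph: nx.DiGraph
    order: list[str]
    added_edges: list[tuple[str, str]] = field(default_factory=list)
    confounded_pairs: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert nx.is_directed_acyclic_graph(self.graph), "active module must be acyclic"

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(self.graph.edges)

    def parents(self, v: str) -> list[str]:
        return sorted(self.graph.predecessors(v))


@dataclass
class SemFit:
    """One group's SEM fit: per-edge beta/se/z/p/CI table plus SRMR."""

    edges: pd.DataFrame  # columns: source, target, beta, se, z, p, ci_low, ci_high
    srmr: float
    n: int

    def beta(self, source: str, target: str) -> float:
        row = self.edges[(self.edges.source == source) & (self.edges.target == target)]
        if row.empty:
            raise KeyError(f"no edge {source}->{target} in the fit")
        return float(row.beta.iloc[0])


@dataclass
class PerturbationFit:
    """Model C: node perturbations (group -> gene effects b) and edge
    perturbations (db = beta_case - beta_ctrl)."""

    nodes: pd.DataFrame  # gene, b, se, z, p, ci_low, ci_high, direction
    edges: pd.DataFrame  # source, target, db, se, z, p, ci_low, ci_high, direction
    srmr: float
    n: int


def _standardize(values: pd.DataFrame) -> pd.DataFrame:
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    if (sd == 0).any():
        raise ValueError(f"zero-variance genes: {list(sd.index[sd == 0])}")
    return values.sub(mu, axis=0).div(sd, axis=0)


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least squares with coefficient SEs; returns (beta, se, rss)."""
    n, k = X.shape
    if n < k + 2:
        raise ValueError(f"too few samples ({n}) for {k} regressors")
    gram = X.T @ X
    try:
        ginv = np.linalg.inv(gram)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular design matrix") from exc
    beta = ginv @ X.T @ y
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2 = rss / (n - k)
    se = np.sqrt(sigma2 * np.diag(ginv))
    return beta, se, rss


def _bic(n: int, rss: float, k: int) -> float:
    return n * np.log(max(rss, 1e-12) / n) + k * np.log(n)


def search_optimal_dag(
    tree: SteinerTree,
    data: ExpressionData,
    sparsity: list[float] | np.ndarray | None = None,
    residual_corr_threshold: float = 0.4,
) -> ActiveModuleDAG:
    """Orient the Steiner tree and search for an optimal sparse DAG.

    The causal order is estimated by the top-down conditional-variance
    greedy for equal-noise linear SEMs: at each step the remaining node
    with the smallest residual variance given the already-ordered nodes is
    appended (sources have the least unexplained variance under equal
    noise; lexicographic tie-break).  The order uses the data on their
    original scale — per-gene rescaling destroys the variance signal the
    greedy relies on, in which case the order degrades gracefully to an
    arbitrary Markov-equivalent orientation of the tree.  Given the order,
    each node keeps its (unpenalized) tree parents while a Lasso over the
    remaining earlier nodes, swept across the ``sparsity`` grid and scored
    by BIC after an OLS refit, may add further parents.  An infinite
    penalty therefore recovers exactly the oriented tree.

    Node pairs that remain strongly correlated after the fit (above
    ``residual_corr_threshold``) are reported in ``confounded_pairs`` as
    candidate latent-confounder signals; they are not removed.
    """
    nodes = sorted(tree.tree.nodes)
    missing = [v for v in nodes if v not in set(data.gene_ids)]
    if missing:
        raise ValueError(f"tree genes missing from data: {missing}")
    n = data.n_samples
    if n < len(nodes) + 2:
        raise ValueError(f"{n} samples cannot identify a {len(nodes)}-node module")
    if sparsity is None:
        sparsity = np.geomspace(0.01, 0.5, 8)
    Z = _standardize(data.values.loc[nodes])
    X = {v: Z.loc[v].to_numpy() for v in nodes}
    raw = data.values.loc[nodes]
    Xraw = {v: raw.loc[v].to_numpy() - raw.loc[v].mean() for v in nodes}

    # top-down conditional-variance greedy (equal-noise linear SEM order)
    order: list[str] = []
    remaining = list(nodes)
    while remaining:
        best = None
        for v in remaining:
            y = Xraw[v]
            if order:
                P = np.column_stack([Xraw[u] for u in order])
                coef = np.linalg.lstsq(P, y, rcond=None)[0]
                resid = y - P @ coef
            else:
                resid = y
            score = float(resid @ resid) / n
            if best is None or score < best[0] - 1e-12 or (abs(score - best[0]) <= 1e-12 and v < best[1]):
                best = (score, v)
        order.append(best[1])
        remaining.remove(best[1])

    pos = {v: i for i, v in enumerate(order)}
    dag = nx.DiGraph()
    dag.add_nodes_from(nodes)
    added: list[tuple[str, str]] = []
    for v in order:
        tree_pa = sorted(u for u in tree.tree.neighbors(v) if pos[u] < pos[v])
        others = sorted(u for u in order[: pos[v]] if u not in tree_pa)
        for u in tree_pa:
            dag.add_edge(u, v)
        if not others:
            continue
        y = X[v]
        O = np.column_stack([X[u] for u in others])
        if tree_pa:
            T = np.column_stack([X[u] for u in tree_pa])
            proj = T @ np.linalg.lstsq(T, np.column_stack([y] + [O[:, j] for j in range(O.shape[1])]), rcond=None)[0]
            y_r = y - proj[:, 0]
            O_r = O - proj[:, 1:]
        else:
            y_r, O_r = y, O
        best_support: tuple[float, tuple[str, ...]] = (
            _bic(n, _ols(np.column_stack([X[u] for u in tree_pa]), y)[2] if tree_pa else float(y @ y), len(tree_pa)),
            (),
        )
        for lam in sparsity:
            if not np.isfinite(lam):
                continue
            model = Lasso(alpha=float(lam), fit_intercept=False, max_iter=5000)
            model.fit(O_r / np.sqrt(n), y_r / np.sqrt(n))
            sel = tuple(others[j] for j in np.flatnonzero(np.abs(model.coef_) > 1e-8))
            if not sel:
                continue
            Xfull = np.column_stack([X[u] for u in tree_pa] + [X[u] for u in sel])
            if Xfull.shape[1] + 2 > n:
                continue
            _, _, rss = _ols(Xfull, y)
            score = _bic(n, rss, len(tree_pa) + len(sel))
            if score < best_support[0] - 1e-12:
                best_support = (score, sel)
        for u in best_support[1]:
            dag.add_edge(u, v)
            added.append((u, v))

    # residual-correlation diagnostic (candidate confounding, reported only)
    resid = {}
    for v in nodes:
        pa = sorted(dag.predecessors(v))
        if pa:
            P = np.column_stack([X[u] for u in pa])
            beta, _, _ = _ols(P, X[v])
            resid[v] = X[v] - P @ beta
        else:
            resid[v] = X[v]
    confounded = []
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            if dag.has_edge(u, v) or dag.has_edge(v, u):
                continue
            r = float(np.corrcoef(resid[u], resid[v])[0, 1])
            if abs(r) > residual_corr_threshold:
                confounded.append((u, v, r))
    return ActiveModuleDAG(graph=dag, order=order, added_edges=sorted(added),
                           confounded_pairs=confounded)


def _implied_correlation(nodes: list[str], B: np.ndarray, resid_var: np.ndarray) -> np.ndarray:
    p = len(nodes)
    inv = np.linalg.inv(np.eye(p) - B)
    sigma = inv @ np.diag(resid_var) @ inv.T
    d = np.sqrt(np.diag(sigma))
    return sigma / np.outer(d, d)


def srmr(S_obs: np.ndarray, S_imp: np.ndarray) -> float:
    """Standardized root mean-square residual over the lower triangle
    (diagonal included) of two correlation matrices."""
    S_obs = np.asarray(S_obs, dtype=float)
    S_imp = np.asarray(S_imp, dtype=float)
    if S_obs.shape != S_imp.shape or S_obs.shape[0] != S_obs.shape[1]:
        raise ValueError("matrices must be square and of equal dimension")
    tri = np.tril_indices(S_obs.shape[0])
    return float(np.sqrt(np.mean((S_obs[tri] - S_imp[tri]) ** 2)))


def fit_sem_group(
    dag: ActiveModuleDAG,
    data: ExpressionData,
    alpha: float | None = None,
) -> SemFit:
    """Fit one group's SEM on standardized data.

    Each node is regressed on its DAG parents.  With ``alpha`` set, a Lasso
    at that penalty selects the support first and the de-biased estimate is
    the OLS refit on the selected support (parents dropped by the penalty
    are reported with beta = 0); the default ``alpha=None`` keeps the full
    parent set, the de-biased limit appropriate when n exceeds the largest
    parent set by a wide margin.
    """
    nodes = sorted(dag.graph.nodes)
    Z = _standardize(data.values.loc[nodes])
    n = data.n_samples
    X = {v: Z.loc[v].to_numpy() for v in nodes}
    rows = []
    Bmat = np.zeros((len(nodes), len(nodes)))
    resid_var = np.ones(len(nodes))
    idx = {v: i for i, v in enumerate(nodes)}
    for v in nodes:
        pa = dag.parents(v)
        if not pa:
            resid_var[idx[v]] = float(np.var(X[v], ddof=0))
            continue
        support = pa
        if alpha is not None and alpha > 0:
            P = np.column_stack([X[u] for u in pa])
            model = Lasso(alpha=float(alpha), fit_intercept=False, max_iter=5000)
            model.fit(P / np.sqrt(n), X[v] / np.sqrt(n))
            support = [u for u, c in zip(pa, model.coef_) if abs(c) > 1e-8]
        beta_map = {u: 0.0 for u in pa}
        se_map = {u: np.nan for u in pa}
        if support:
            P = np.column_stack([X[u] for u in support])
            beta, se, rss = _ols(P, X[v])
            for u, b, s in zip(support, beta, se):
                beta_map[u], se_map[u] = float(b), float(s)
            resid_var[idx[v]] = rss / n
        else:
            resid_var[idx[v]] = float(np.var(X[v], ddof=0))
        for u in pa:
            b, s = beta_map[u], se_map[u]
            z = b / s if np.isfinite(s) and s > 0 else np.nan
            p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            rows.append(
                dict(source=u, target=v, beta=b, se=s, z=z, p=p,
                     ci_low=b - 1.96 * s if np.isfinite(s) else np.nan,
                     ci_high=b + 1.96 * s if np.isfinite(s) else np.nan)
            )
            Bmat[idx[v], idx[u]] = b
    edges = pd.DataFrame(rows, columns=["source", "target", "beta", "se", "z", "p", "ci_low", "ci_high"])
    S_obs = np.corrcoef(Z.to_numpy())
    S_imp = _implied_correlation(nodes, Bmat, resid_var)
    return SemFit(edges=edges, srmr=srmr(S_obs, S_imp), n=n)


GROUP = "group"


def fit_perturbation_model(dag: ActiveModuleDAG, data: ExpressionData) -> PerturbationFit:
    """Model C, in two steps.

    Step 1 (node perturbation): on pooled-standardized data, each gene is
    regressed on the group indicator plus its DAG parents; the group
    coefficient b is the node perturbation, labelled "upregulated" when
    positive and "down-expressed" when negative.

    Step 2 (edge perturbation): Models A (cases) and B (controls) are
    fitted on within-group standardized data and each edge's
    ``db = beta_A - beta_B`` is tested with
    ``se = sqrt(se_A^2 + se_B^2)`` (two-tailed z).
    """
    if len(set(data.group)) < 2:
        raise ValueError("both groups must be present")
    nodes = sorted(dag.graph.nodes)
    Z = _standardize(data.values.loc[nodes])
    g = data.group.to_numpy(dtype=float)
    n = data.n_samples
    node_rows = []
    Bmat = np.zeros((len(nodes) + 1, len(nodes) + 1))  # group is variable 0
    resid_var = np.ones(len(nodes) + 1)
    resid_var[0] = float(np.var(g, ddof=0))
    idx = {v: i + 1 for i, v in enumerate(nodes)}
    for v in nodes:
        pa = dag.parents(v)
        X = np.column_stack([g] + [Z.loc[u].to_numpy() for u in pa])
        beta, se, rss = _ols(X, Z.loc[v].to_numpy())
        b, s = float(beta[0]), float(se[0])
        z = b / s
        node_rows.append(
            dict(gene=v, b=b, se=s, z=z, p=2.0 * stats.norm.sf(abs(z)),
                 ci_low=b - 1.96 * s, ci_high=b + 1.96 * s,
                 direction="upregulated" if b > 0 else "down-expressed")
        )
        Bmat[idx[v], 0] = b
        for u, bu in zip(pa, beta[1:]):
            Bmat[idx[v], idx[u]] = float(bu)
        resid_var[idx[v]] = rss / n
    fit_a = fit_sem_group(dag, data.subset_group(1))
    fit_b = fit_sem_group(dag, data.subset_group(0))
    edge_rows = []
    for (_, row_a), (_, row_b) in zip(fit_a.edges.iterrows(), fit_b.edges.iterrows()):
        assert (row_a.source, row_a.target) == (row_b.source, row_b.target)
        db = row_a.beta - row_b.beta
        se = float(np.sqrt(row_a.se**2 + row_b.se**2))
        z = db / se
        edge_rows.append(
            dict(source=row_a.source, target=row_a.target, db=db, se=se, z=z,
                 p=2.0 * stats.norm.sf(abs(z)),
                 ci_low=db - 1.96 * se, ci_high=db + 1.96 * se,
                 direction="upregulated" if db > 0 else "downregulated")
        )
    S_obs = np.corrcoef(np.vstack([g, Z.to_numpy()]))
    S_imp = _implied_correlation([GROUP] + nodes, Bmat, resid_var)
    return PerturbationFit(
        nodes=pd.DataFrame(node_rows),
        edges=pd.DataFrame(edge_rows, columns=["source", "target", "db", "se", "z", "p", "ci_low", "ci_high", "direction"]),
        srmr=srmr(S_obs, S_imp),
        n=n,
    )


def indirect_effects(dag: ActiveModuleDAG, fit: SemFit) -> pd.DataFrame:
    """Total indirect effects: for every ordered gene pair, the sum over
    all directed paths of length >= 2 of the product of edge betas
    (exact enumeration; a DAG has finitely many simple paths)."""
    beta = {(r.source, r.target): r.beta for r in fit.edges.itertuples()}
    rows = []
    nodes = sorted(dag.graph.nodes)
    for src in nodes:
        for dst in nodes:
            if src == dst:
                continue
            total = 0.0
            found = False
            for path in nx.all_simple_paths(dag.graph, src, dst):
                if len(path) < 3:
                    continue
                found = True
                prod = 1.0
                for u, v in zip(path, path[1:]):
                    prod *= beta.get((u, v), 0.0)
                total += prod
            if found:
                rows.append(dict(source=src, target=dst, indirect=total))
    return pd.DataFrame(rows, columns=["source", "target", "indirect"])
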