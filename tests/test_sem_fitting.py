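import networkx as nx
import numpy as np
import pandas as pd
import pytest

from activesem import (
    ActiveModuleDAG,
    GroundTruthModel,
    fit_perturbation_model,
    fit_sem_group,
    indirect_effects,
    search_optimal_dag,
    simulate_expression,
    srmr,
)
from activesem.active_module import SteinerTree
from activesem.datasets import ibsd_sem_effects
from activesem.sem_fitting import SemFit


def dag_from_edges(edges, nodes=()):
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    order = list(nx.topological_sort(g))
    return ActiveModuleDAG(graph=g, order=order)


def tree_from_dag(dag: nx.DiGraph) -> SteinerTree:
    und = nx.Graph(dag.to_undirected())
    nx.set_edge_attributes(und, 1.0, "w")
    return SteinerTree(tree=und, seeds=sorted(dag.nodes), connectors=[], total_cost=0.0)


def random_tree_model(n_nodes, seed, beta_low=0.4, beta_high=0.8):
    rng = np.random.default_rng(seed)
    nodes = [f"g{i}" for i in range(1, n_nodes + 1)]
    dag = nx.DiGraph()
    dag.add_nodes_from(nodes)
    perm = list(rng.permutation(nodes))
    for i in range(1, n_nodes):
        dag.add_edge(perm[rng.integers(0, i)], perm[i])
    betas = {e: float(rng.choice([-1, 1]) * rng.uniform(beta_low, beta_high)) for e in dag.edges}
    return GroundTruthModel(dag=dag, beta_case=dict(betas), beta_ctrl=dict(betas), seed=seed)


class TestSearchOptimalDag:
    def test_recovers_tree_skeleton_truth(self):
        """Data simulated from a DAG whose skeleton equals the tree:
        structural Hamming distance <= 1 in >= 80% of replicates."""
        ok = 0
        reps = 25
        for rep in range(reps):
            model = random_tree_model(8, seed=rep)
            data = simulate_expression(model, 500, 500, seed=1000 + rep)
            rec = search_optimal_dag(tree_from_dag(model.dag), data)
            shd = len(set(model.dag.edges) ^ set(rec.graph.edges))
            ok += shd <= 1
        assert ok / reps >= 0.8

    def test_infinite_penalty_recovers_oriented_tree(self):
        model = random_tree_model(6, seed=1)
        data = simulate_expression(model, 200, 200, seed=5)
        rec = search_optimal_dag(tree_from_dag(model.dag), data, sparsity=[np.inf])
        assert rec.added_edges == []
        skeleton = {frozenset(e) for e in rec.graph.edges}
        assert skeleton == {frozenset(e) for e in model.dag.edges}

    def test_no_added_edges_under_pure_noise(self):
        """Independent-noise data: BIC should not buy extra edges."""
        clean = 0
        reps = 20
        nodes = [f"g{i}" for i in range(1, 7)]
        chain = nx.DiGraph([(nodes[i], nodes[i + 1]) for i in range(5)])
        for rep in range(reps):
            model = GroundTruthModel(
                dag=nx.create_empty_copy(chain), beta_case={}, beta_ctrl={}, seed=rep,
            )
            data = simulate_expression(model, 100, 100, seed=3000 + rep)
            rec = search_optimal_dag(tree_from_dag(chain), data)
            clean += len(rec.added_edges) == 0
        assert clean / reps >= 0.9

    def test_acyclic_always(self):
        for rep in range(5):
            model = random_tree_model(7, seed=rep + 50)
            data = simulate_expression(model, 60, 60, seed=rep)
            rec = search_optimal_dag(tree_from_dag(model.dag), data)
            assert nx.is_directed_acyclic_graph(rec.graph)

    def test_too_few_samples_error(self):
        model = random_tree_model(10, seed=2)
        data = simulate_expression(model, 5, 5, seed=2)
        with pytest.raises(ValueError, match="samples"):
            search_optimal_dag(tree_from_dag(model.dag), data)


class TestFitSemGroup:
    def test_single_edge_beta_recovery(self):
        """X -> Y with standardized beta 0.8: estimate within +-0.08 in
        >= 95% of replicates at n = 500."""
        dag = nx.DiGraph([("X", "Y")])
        hits = 0
        reps = 100
        for rep in range(reps):
            model = GroundTruthModel(
                dag=dag, beta_case={("X", "Y"): 4.0 / 3.0}, beta_ctrl={("X", "Y"): 4.0 / 3.0},
                noise_sd={"X": 1.0, "Y": 1.0}, seed=rep,
            )
            # standardized beta = (4/3) / sqrt((4/3)^2 + 1) = 0.8
            data = simulate_expression(model, 250, 250, seed=rep)
            fit = fit_sem_group(dag_from_edges(dag.edges), data)
            hits += abs(fit.beta("X", "Y") - 0.8) <= 0.08
        assert hits / reps >= 0.95

    def test_null_edge_z_test_calibrated(self):
        """Type-I error of the edge z-test within [0.03, 0.07] at nominal
        0.05 over 1000 null replicates."""
        dag = nx.DiGraph()
        dag.add_nodes_from(["X", "Y"])
        module = dag_from_edges([("X", "Y")])
        hits = 0
        reps = 1000
        for rep in range(reps):
            model = GroundTruthModel(dag=dag, beta_case={}, beta_ctrl={}, seed=rep)
            data = simulate_expression(model, 50, 50, seed=20000 + rep)
            fit = fit_sem_group(module, data)
            hits += fit.edges.p.iloc[0] < 0.05
        assert 0.03 <= hits / reps <= 0.07

    def test_saturated_three_node_model_has_zero_srmr(self):
        model = random_tree_model(3, seed=9)
        data = simulate_expression(model, 100, 100, seed=9)
        sat = dag_from_edges([("g1", "g2"), ("g1", "g3"), ("g2", "g3")])
        fit = fit_sem_group(sat, data)
        assert fit.srmr == pytest.approx(0.0, abs=1e-10)

    def test_consistency_as_n_grows(self):
        """Mean absolute coefficient error shrinks from n=100 to n=1000."""
        errs = {}
        for n in (100, 1000):
            tot = 0.0
            cnt = 0
            for rep in range(10):
                model = random_tree_model(5, seed=rep)
                data = simulate_expression(model, n // 2, n // 2, seed=rep + n)
                module = dag_from_edges(model.dag.edges)
                fit = fit_sem_group(module, data)
                sd = {v: data.values.loc[v].std(ddof=1) for v in model.dag.nodes}
                for (u, v), b in model.beta_case.items():
                    b_std = b * sd[u] / sd[v]
                    tot += abs(fit.beta(u, v) - b_std)
                    cnt += 1
            errs[n] = tot / cnt
        assert errs[1000] < errs[100]
        assert errs[1000] < 0.05


class TestPerturbationModel:
    def test_db_equals_model_a_minus_model_b(self):
        model = random_tree_model(6, seed=4)
        model.group_effect["g1"] = 1.0
        model.beta_case[list(model.dag.edges)[0]] += 0.8
        data = simulate_expression(model, 40, 40, seed=4)
        module = dag_from_edges(model.dag.edges)
        pert = fit_perturbation_model(module, data)
        fit_a = fit_sem_group(module, data.subset_group(1))
        fit_b = fit_sem_group(module, data.subset_group(0))
        for row in pert.edges.itertuples():
            expect = fit_a.beta(row.source, row.target) - fit_b.beta(row.source, row.target)
            assert row.db == pytest.approx(expect, abs=1e-12)

    def test_identical_groups_give_zero_db(self):
        model = random_tree_model(5, seed=6)
        data = simulate_expression(model, 20, 20, seed=6)
        # duplicate the case block into the control block
        values = data.values.copy()
        values[data.control_ids[:20]] = data.values[data.case_ids[:20]].to_numpy()
        data2 = type(data)(values, data.group.copy())
        pert = fit_perturbation_model(dag_from_edges(model.dag.edges), data2)
        np.testing.assert_allclose(pert.edges.db, 0.0, atol=1e-12)
        np.testing.assert_allclose(pert.nodes.b, 0.0, atol=1e-10)

    def test_direction_labels_follow_sign(self):
        model = random_tree_model(5, seed=7)
        model.group_effect["g2"] = 1.5
        data = simulate_expression(model, 40, 40, seed=7)
        pert = fit_perturbation_model(dag_from_edges(model.dag.edges), data)
        for row in pert.nodes.itertuples():
            assert row.direction == ("upregulated" if row.b > 0 else "down-expressed")
        for row in pert.edges.itertuples():
            assert row.direction == ("upregulated" if row.db > 0 else "downregulated")

    def test_planted_node_perturbation_detected(self):
        model = random_tree_model(5, seed=8)
        model.group_effect["g3"] = 2.0
        data = simulate_expression(model, 100, 100, seed=8)
        pert = fit_perturbation_model(dag_from_edges(model.dag.edges), data)
        row = pert.nodes[pert.nodes.gene == "g3"].iloc[0]
        assert row.p < 0.01 and row.direction == "upregulated"

    def test_published_edge_difference_identity(self):
        """The reported per-group betas reproduce the reported edge
        perturbations via db = beta_case - beta_ctrl (within rounding)."""
        table = ibsd_sem_effects()
        np.testing.assert_allclose(
            table.beta_case - table.beta_ctrl, table.db_reported, atol=2e-3
        )


class TestSrmr:
    def test_identical_matrices_zero(self):
        S = np.array([[1.0, 0.3], [0.3, 1.0]])
        assert srmr(S, S) == 0.0

    def test_hand_computed_value(self):
        S1 = np.array([[1.0, 0.5], [0.5, 1.0]])
        S2 = np.array([[1.0, 0.3], [0.3, 1.0]])
        # lower triangle incl diagonal: residuals (0, 0.2, 0) -> sqrt(0.04/3)
        assert srmr(S1, S2) == pytest.approx(np.sqrt(0.04 / 3), rel=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        A = rng.uniform(-1, 1, (4, 4))
        S1 = (A + A.T) / 2
        B = rng.uniform(-1, 1, (4, 4))
        S2 = (B + B.T) / 2
        perm = rng.permutation(4)
        assert srmr(S1, S2) == pytest.approx(
            srmr(S1[np.ix_(perm, perm)], S2[np.ix_(perm, perm)]), rel=1e-12
        )

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            srmr(np.eye(2), np.eye(3))


class TestIndirectEffects:
    def fit_with_betas(self, edges):
        rows = [dict(source=u, target=v, beta=b, se=0.1, z=1.0, p=0.5,
                     ci_low=0.0, ci_high=0.0) for u, v, b in edges]
        return SemFit(edges=pd.DataFrame(rows), srmr=0.0, n=10)

    def test_chain_product_rule(self):
        dag = dag_from_edges([("A", "B"), ("B", "C")])
        fit = self.fit_with_betas([("A", "B", 0.5), ("B", "C", 0.4)])
        table = indirect_effects(dag, fit)
        val = table[(table.source == "A") & (table.target == "C")].indirect.iloc[0]
        assert val == pytest.approx(0.2, rel=1e-12)

    def test_no_long_path_means_absent(self):
        dag = dag_from_edges([("A", "B")])
        fit = self.fit_with_betas([("A", "B", 0.5)])
        assert indirect_effects(dag, fit).empty

    def test_parallel_paths_sum(self):
        dag = dag_from_edges([("A", "B"), ("B", "D"), ("A", "C"), ("C", "D")])
        fit = self.fit_with_betas(
            [("A", "B", 0.5), ("B", "D", 0.4), ("A", "C", 0.3), ("C", "D", 0.2)]
        )
        table = indirect_effects(dag, fit)
        val = table[(table.source == "A") & (table.target == "D")].indirect.iloc[0]
        assert val == pytest.approx(0.26, rel=1e-12)
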