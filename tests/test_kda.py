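"""Causal DAG learning, effector sets, key-driver enrichment, ranking."""

from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cultureshock as cs
from cultureshock.data import DirectedNetwork, ValidationError

from conftest import make_matrix


class TestTopVarying:
    def test_variance_ranking(self):
        rng = np.random.default_rng(0)
        norm = np.vstack([
            2.0 * rng.normal(size=500),   # var 4
            1.0 * rng.normal(size=500),   # var 1
            3.0 * rng.normal(size=500),   # var 9
        ])
        m = make_matrix(np.ones((3, 500), dtype=int), gene_symbols=["a", "b", "c"])
        top = cs.top_varying_genes(m, n_top=2, norm=norm)
        assert top == ["c", "a"]

    def test_full_list_descending(self):
        rng = np.random.default_rng(1)
        norm = rng.normal(size=(5, 100)) * np.arange(1, 6)[:, None]
        m = make_matrix(np.ones((5, 100), dtype=int))
        top = cs.top_varying_genes(m, n_top=5, norm=norm)
        assert top == ["g4", "g3", "g2", "g1", "g0"]

    def test_covariate_absorbs_gene_variance(self):
        rng = np.random.default_rng(2)
        norm = rng.normal(size=(3, 200))
        m = make_matrix(np.ones((3, 200), dtype=int))
        m.cell_meta["cov"] = norm[0]
        top = cs.top_varying_genes(m, covariates=("cov",), n_top=3, norm=norm)
        assert top[-1] == "g0"

    def test_zero_variance_covariate_rejected(self):
        m = make_matrix(np.ones((2, 60), dtype=int))
        m.cell_meta["cov"] = 1.0
        with pytest.raises(ValidationError):
            cs.top_varying_genes(m, covariates=("cov",), n_top=2)


class TestLearnDag:
    def test_pairwise_dependence_recovered(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        y = x + 0.5 * rng.normal(size=500)
        norm = np.vstack([x, y])
        m = make_matrix(np.ones((2, 500), dtype=int), gene_symbols=["x", "y"])
        dag = cs.learn_dag(m, ["x", "y"], norm=norm)
        assert {frozenset(e) for e in dag.edges} == {frozenset(("x", "y"))}

    def test_independent_genes_mostly_empty(self):
        rng = np.random.default_rng(1)
        norm = rng.normal(size=(20, 500))
        m = make_matrix(np.ones((20, 500), dtype=int))
        dag = cs.learn_dag(m, list(m.gene_symbols), norm=norm)
        assert len(dag.edges) <= 0.05 * comb(20, 2)

    def test_planted_ten_node_dag_f1(self):
        """Adjacency F1 >= 0.7 against a planted 10-node regulatory DAG
        at n=2000 cells."""
        t = cs.generate_truth(n_genes=300, n_states=2, n_modules=0,
                              n_dag_nodes=10, n_drivers=2,
                              n_condition_genes=5, seed=10)
        m = cs.simulate_counts(t, cells_per_state=1000, conditions=("fresh",), seed=11)
        dag = cs.learn_dag(m, list(t.dag.nodes),
                           covariates=("state_true",), seed=0)
        true_adj = {frozenset(e) for e in t.dag.edges}
        learn_adj = {frozenset(e) for e in dag.edges}
        tp = len(true_adj & learn_adj)
        prec = tp / max(len(learn_adj), 1)
        rec = tp / max(len(true_adj), 1)
        f1 = 2 * prec * rec / max(prec + rec, 1e-12)
        assert f1 >= 0.7

    def test_constant_gene_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        norm = np.vstack([rng.normal(size=100), np.zeros(100)])
        m = make_matrix(np.ones((2, 100), dtype=int), gene_symbols=["a", "flat"])
        with pytest.warns(UserWarning):
            dag = cs.learn_dag(m, ["a", "flat"], norm=norm)
        assert dag.nodes == ["a"]

    def test_too_few_cells_rejected(self):
        m = make_matrix(np.ones((2, 20), dtype=int))
        with pytest.raises(ValidationError):
            cs.learn_dag(m, ["g0", "g1"])


class TestDownstream:
    def chain(self):
        nodes = list("ABCDE")
        return DirectedNetwork(nodes, [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")])

    def test_chain_depth_three(self):
        assert cs.downstream_set(self.chain(), "A", 3) == {"B", "C", "D"}

    def test_sink_is_empty(self):
        assert cs.downstream_set(self.chain(), "E", 3) == set()

    def test_unbounded_equals_transitive_closure(self):
        assert cs.downstream_set(self.chain(), "A", None) == {"B", "C", "D", "E"}

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 4))
    def test_matches_bfs_oracle(self, seed, depth):
        rng = np.random.default_rng(seed)
        n = 12
        nodes = [f"n{i}" for i in range(n)]
        edges = [
            (nodes[i], nodes[j])
            for i in range(n) for j in range(i + 1, n)
            if rng.random() < 0.2
        ]
        net = DirectedNetwork(nodes, edges)
        g = net.to_networkx()
        for node in nodes:
            oracle = {
                k for k, l in nx.single_source_shortest_path_length(
                    g, node, cutoff=depth
                ).items() if l > 0
            }
            assert cs.downstream_set(net, node, depth) == oracle


class TestEffectorSets:
    def make_inputs(self, M, genes_per_module=1):
        genes = [f"g{i}" for i in range(M * genes_per_module + 5)]
        modules = pd.Series(
            {genes[i]: i % M for i in range(M * genes_per_module)}
        )
        net = DirectedNetwork(genes, [(genes[0], genes[1])])
        de = set(genes)  # every module overlaps the DE set
        return de, modules, net

    @pytest.mark.parametrize("M,expected", [(145, 291), (84, 169)])
    def test_printed_set_counts(self, M, expected):
        de, modules, net = self.make_inputs(M)
        eff = cs.build_effector_sets(de, modules, net)
        assert eff.n_total == expected
        assert len(eff.sets) == expected  # nothing empty here

    def test_hand_example_with_empty_overlap(self):
        genes = ["a", "b", "c", "d"]
        net = DirectedNetwork(genes, [("a", "b")])
        modules = pd.Series({"a": 0, "c": 0, "d": 1})
        eff = cs.build_effector_sets({"a", "b"}, modules, net)
        assert eff.n_total == 5  # 2M+1 with M=2
        assert len(eff.sets) == 4  # empty DE-module overlap dropped
        assert eff.n_dropped == 1

    def test_empty_de_rejected(self):
        _, modules, net = self.make_inputs(2)
        with pytest.raises(ValidationError):
            cs.build_effector_sets(set(), modules, net)


def hypergeom_oracle(N, K, n, k):
    """Exact upper-tail hypergeometric probability via integer arithmetic."""
    total = Fraction(0)
    for kk in range(k, min(K, n) + 1):
        total += Fraction(comb(K, kk) * comb(N - K, n - kk), comb(N, n))
    return float(total)


class TestKdaEnrich:
    def test_hand_hypergeometric(self):
        # universe 10, downstream 4, set 5, overlap 4 -> 5/210
        nodes = [f"n{i}" for i in range(10)]
        edges = [("n0", f"n{i}") for i in range(1, 5)]
        net = DirectedNetwork(nodes, edges)
        modules = pd.Series({"n1": 0})
        eff = cs.build_effector_sets({"n1", "n2", "n3", "n4", "n9"}, modules, net)
        table = cs.kda_enrich(net, eff, depth=1)
        row = table[(table.node == "n0") & (table.effector_set == "DE")].iloc[0]
        assert row["p_raw"] == pytest.approx(5 / 210)

    def test_universe_set_gives_p_one(self):
        nodes = [f"n{i}" for i in range(6)]
        net = DirectedNetwork(nodes, [("n0", "n1"), ("n1", "n2")])
        modules = pd.Series({"n1": 0})
        eff = cs.build_effector_sets(set(nodes), modules, net)
        table = cs.kda_enrich(net, eff)
        de_rows = table[table.effector_set == "DE"]
        assert np.allclose(de_rows["p_raw"], 1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exact_enumeration(self, seed):
        """Hypergeometric tails agree with exact integer enumeration on
        universes of <= 15 nodes to 1e-12."""
        rng = np.random.default_rng(seed)
        N = int(rng.integers(5, 16))
        nodes = [f"n{i}" for i in range(N)]
        edges = [
            (nodes[i], nodes[j])
            for i in range(N) for j in range(i + 1, N)
            if rng.random() < 0.25
        ]
        net = DirectedNetwork(nodes, edges)
        K = int(rng.integers(1, N))
        de = set(rng.choice(nodes, K, replace=False))
        modules = pd.Series({nodes[0]: 0})
        eff = cs.build_effector_sets(de | {nodes[0]}, modules, net)
        table = cs.kda_enrich(net, eff, depth=3)
        for _, row in table.iterrows():
            S = eff.sets[row["effector_set"]]
            p = hypergeom_oracle(N, len(S), row["downstream_size"], row["overlap"])
            assert abs(row["p_raw"] - p) < 1e-12

    def test_planted_drivers_called_with_true_dag(self, truth, shock_de,
                                                  shock_network):
        de_set = set(shock_de.significant(0.05, 0.5).index)
        eff = cs.build_effector_sets(de_set, shock_network.modules, truth.dag)
        table = cs.kda_enrich(truth.dag, eff, depth=3)
        hits = set(table[table.is_key_driver &
                         (table.effector_set == "DE")]["node"])
        assert set(truth.drivers) <= hits


class TestPrioritize:
    def records(self, rows):
        return pd.DataFrame(
            rows, columns=["gene", "n_sets", "n_categories", "min_p_adj"]
        ).set_index("gene")

    def test_both_networks_beats_set_count(self):
        a = self.records([("X", 40, 3, 1e-5), ("Y", 80, 3, 1e-9)])
        b = self.records([("X", 40, 3, 1e-5)])
        ranked = cs.prioritize(a, b)
        assert ranked.index[0] == "X"

    def test_identical_records_tie_alphabetical(self):
        a = self.records([("B", 2, 1, 0.01), ("A", 2, 1, 0.01)])
        ranked = cs.prioritize(a, a)
        assert list(ranked.index[:2]) == ["A", "B"]

    def test_row_order_invariance(self):
        a = self.records([("X", 4, 2, 0.01), ("Y", 9, 3, 0.001), ("Z", 1, 1, 0.04)])
        b = self.records([("Y", 2, 2, 0.02), ("Z", 5, 3, 0.01)])
        r1 = cs.prioritize(a, b)
        r2 = cs.prioritize(a.iloc[::-1], b.iloc[::-1])
        assert list(r1.index) == list(r2.index)

    def test_rank_unique_and_complete(self):
        a = self.records([("X", 4, 2, 0.01), ("Y", 9, 3, 0.001)])
        ranked = cs.prioritize(a, a.iloc[0:0])
        assert sorted(ranked["rank"]) == [1, 2]
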