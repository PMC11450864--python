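"""Random-walk-with-restart propagation: oracles and invariants."""

import networkx as nx
import numpy as np
import pytest

from dgdrp.io_chem import PPINetwork, PathwayCollection
from dgdrp.propagation import (PropagationConfig, column_normalize,
                               propagate_from_targets, reinforce_with_pathways,
                               rwr_propagate, select_indirect_targets)


def net_from_edges(edges, nodes=None):
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    for u, v, *s in edges:
        g.add_edge(u, v, score=s[0] if s else 1)
    return PPINetwork(g)


def linear_solve_oracle(W, gene_ids, seeds, alpha):
    """Closed-form fixed point: (I - (1-alpha) W) p = alpha p0."""
    n = len(gene_ids)
    p0 = np.zeros(n)
    idx = [gene_ids.index(s) for s in seeds]
    p0[idx] = 1.0 / len(idx)
    A = np.eye(n) - (1 - alpha) * W.toarray()
    return np.linalg.solve(A, alpha * p0)


class TestColumnNormalize:
    def test_path_graph_splits_middle_column(self):
        W, ids = column_normalize(net_from_edges([("A", "B"), ("B", "C")]))
        col_b = W.toarray()[:, ids.index("B")]
        expected = np.zeros(3)
        expected[ids.index("A")] = 0.5
        expected[ids.index("C")] = 0.5
        assert np.allclose(col_b, expected)

    def test_isolated_node_keeps_zero_column(self):
        W, ids = column_normalize(net_from_edges([("A", "B")], nodes=["A", "B", "D"]))
        assert np.allclose(W.toarray()[:, ids.index("D")], 0)
        # the other columns still sum to 1
        assert np.allclose(W.toarray()[:, ids.index("A")].sum(), 1)

    def test_triangle_equal_weights(self):
        W, ids = column_normalize(
            net_from_edges([("A", "B"), ("B", "C"), ("A", "C")]))
        dense = W.toarray()
        assert np.allclose(dense[dense > 0], 0.5)
        assert np.allclose(dense.sum(axis=0), 1)

    def test_empty_network_is_an_error(self):
        with pytest.raises(ValueError):
            column_normalize(PPINetwork(nx.Graph()))


class TestRWR:
    def test_alpha_one_returns_restart_vector(self):
        net = net_from_edges([("A", "B"), ("B", "C")])
        W, ids = column_normalize(net)
        res = rwr_propagate(W, ids, {"A"}, PropagationConfig(alpha=1.0))
        expected = np.zeros(3)
        expected[ids.index("A")] = 1.0
        assert np.allclose(res.scores, expected)

    def test_two_node_closed_form(self):
        # A-B, seed A, alpha=0.5: p = [2/3, 1/3]
        W, ids = column_normalize(net_from_edges([("A", "B")]))
        res = rwr_propagate(W, ids, {"A"}, PropagationConfig(alpha=0.5))
        assert res.scores[ids.index("A")] == pytest.approx(2 / 3, abs=1e-7)
        assert res.scores[ids.index("B")] == pytest.approx(1 / 3, abs=1e-7)

    @pytest.mark.parametrize("seed", range(10))
    def test_iterative_matches_linear_solve_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        g = nx.gnp_random_graph(n, 0.3, seed=seed)
        g.add_edges_from((i, i + 1) for i in range(n - 1))  # ensure connected
        net = net_from_edges([(f"g{u}", f"g{v}") for u, v in g.edges()])
        W, ids = column_normalize(net)
        seeds = {ids[i] for i in rng.choice(len(ids), 2, replace=False)}
        alpha = float(rng.uniform(0.1, 0.9))
        res = rwr_propagate(W, ids, seeds, PropagationConfig(alpha=alpha))
        oracle = linear_solve_oracle(W, ids, seeds, alpha)
        assert np.abs(res.scores - oracle).sum() < 1e-8

    def test_conservation_on_connected_graph(self):
        net = net_from_edges([("A", "B"), ("B", "C"), ("C", "D"), ("A", "D")])
        W, ids = column_normalize(net)
        res = rwr_propagate(W, ids, {"A", "C"}, PropagationConfig(alpha=0.3))
        assert abs(res.scores.sum() - 1.0) < 1e-9
        assert np.all(res.scores >= 0)

    def test_locality_scores_decrease_with_hops_on_path(self):
        edges = [(f"n{i}", f"n{i+1}") for i in range(9)]
        W, ids = column_normalize(net_from_edges(edges))
        res = rwr_propagate(W, ids, {"n0"}, PropagationConfig(alpha=0.4))
        ordered = [res.scores[ids.index(f"n{i}")] for i in range(10)]
        assert all(a > b for a, b in zip(ordered, ordered[1:]))

    def test_adding_a_seed_does_not_decrease_its_score(self):
        net = net_from_edges([("A", "B"), ("B", "C"), ("C", "D")])
        W, ids = column_normalize(net)
        cfg = PropagationConfig(alpha=0.3)
        without = rwr_propagate(W, ids, {"A"}, cfg)
        with_c = rwr_propagate(W, ids, {"A", "C"}, cfg)
        i = ids.index("C")
        assert with_c.scores[i] >= without.scores[i]

    def test_offnetwork_seeds_are_an_error(self):
        W, ids = column_normalize(net_from_edges([("A", "B")]))
        with pytest.raises(ValueError, match="seed"):
            rwr_propagate(W, ids, {"ZZ"})

    def test_nonconvergence_flags_and_warns(self):
        W, ids = column_normalize(net_from_edges([("A", "B"), ("B", "C")]))
        with pytest.warns(RuntimeWarning, match="converge"):
            res = rwr_propagate(W, ids, {"A"},
                                PropagationConfig(alpha=0.01, tol=1e-14,
                                                  max_iter=3))
        assert not res.converged


class TestReinforcement:
    @staticmethod
    def planted_net(seed=0):
        """Hub-and-spokes graph where one pathway covers the seed's region."""
        rng = np.random.default_rng(seed)
        g = nx.barabasi_albert_graph(60, 2, seed=seed)
        net = net_from_edges([(f"g{u}", f"g{v}") for u, v in g.edges()])
        return net

    def test_boost_factor_one_is_identity(self):
        net = self.planted_net()
        cfg = PropagationConfig(reinforcement="one_round", boost_factor=1.0)
        W, ids = column_normalize(net)
        base = rwr_propagate(W, ids, {"g0"}, cfg)
        pw = PathwayCollection({"P": ("p", frozenset(ids[:10]))})
        out = reinforce_with_pathways(base, pw, cfg, W=W)
        assert np.allclose(out.scores, base.scores)

    def test_no_enriched_pathway_returns_input(self):
        net = self.planted_net()
        W, ids = column_normalize(net)
        cfg = PropagationConfig(reinforcement="one_round", boost_factor=3.0,
                                enrich_p_cutoff=1e-12)
        base = rwr_propagate(W, ids, {"g0"}, cfg)
        pw = PathwayCollection({"P": ("p", frozenset(ids[-5:]))})
        out = reinforce_with_pathways(base, pw, cfg, W=W)
        assert np.allclose(out.scores, base.scores)

    def test_empty_pathways_warns_and_passes_through(self):
        net = self.planted_net()
        W, ids = column_normalize(net)
        cfg = PropagationConfig(reinforcement="one_round")
        base = rwr_propagate(W, ids, {"g0"}, cfg)
        with pytest.warns(RuntimeWarning):
            out = reinforce_with_pathways(base, None, cfg, W=W)
        assert out is base

    def test_planted_pathway_mean_score_strictly_increases(self):
        net = self.planted_net(seed=3)
        W, ids = column_normalize(net)
        cfg = PropagationConfig(reinforcement="one_round", boost_factor=3.0,
                                enrich_top_q=10)
        base = rwr_propagate(W, ids, {"g0"}, cfg)
        # pathway built from 8 of the top-10 propagated non-seed genes plus
        # 2 others; boosting shifts restart mass onto the members
        top = [g for g in base.top_genes(11) if g != "g0"][:8]
        members = frozenset(top + [ids[-1], ids[-2]])
        pw = PathwayCollection({"P1": ("planted", members),
                                "P2": ("bg", frozenset(ids[-6:-2]))})
        out = reinforce_with_pathways(base, pw, cfg, W=W)
        idx = [ids.index(g) for g in members]
        assert out.scores[idx].mean() > base.scores[idx].mean()


class TestIndirectTargets:
    def test_seeds_excluded_and_top_ranked(self):
        net = net_from_edges([("A", "B"), ("A", "C"), ("C", "D")])
        res = propagate_from_targets(net, {"A"}, PropagationConfig(alpha=0.5))
        picked = select_indirect_targets(res, n=1)
        assert picked != ["A"]
        assert len(select_indirect_targets(res, n=10)) == 3  # all non-seeds

    def test_tie_breaks_to_lower_gene_index(self):
        # star: B and C symmetric around seed A -> tied scores
        net = net_from_edges([("A", "B"), ("A", "C")])
        res = propagate_from_targets(net, {"A"}, PropagationConfig(alpha=0.5))
        ids = res.gene_ids
        b, c = sorted(["B", "C"], key=ids.index)
        assert select_indirect_targets(res, n=1) == [b]

    def test_default_count_is_twenty(self):
        import inspect
        from dgdrp.propagation import select_indirect_targets as f
        assert inspect.signature(f).parameters["n"].default == 20
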