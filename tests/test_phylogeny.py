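"""Steiner-tree construction: MST, candidates, pruning, regrafting."""

import itertools
import random

import networkx as nx
import numpy as np
import pytest

from cnvphylo.core import Bounds, ChromosomeMap
from cnvphylo.distance import DistanceContext, Model
from cnvphylo.phylogeny import (
    CopyNumberPhylogeny,
    SteinerSearchParams,
    infer_tree,
    prim_mst,
    prune_steiner_nodes,
    regraft_gd_edges,
    symmetric_distance_matrix,
    tree_weight,
    triplet_steiner_candidates,
)

from conftest import random_config, random_layout


class TestPrimMst:
    def test_two_nodes(self):
        edges, total = prim_mst(np.array([[0, 3], [3, 0]]))
        assert edges == [(0, 1)] and total == 3

    def test_three_node_path(self):
        W = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]])
        edges, total = prim_mst(W)
        assert sorted(tuple(sorted(e)) for e in edges) == [(0, 1), (1, 2)]
        assert total == 2

    def test_matches_exhaustive_enumeration(self):
        rng = random.Random(31)
        for _ in range(15):
            n = rng.randint(2, 6)
            W = np.zeros((n, n), dtype=np.int64)
            for i in range(n):
                for j in range(i + 1, n):
                    W[i, j] = W[j, i] = rng.randint(1, 9)
            _, total = prim_mst(W)
            best = min(
                sum(W[u][v] for u, v in comb)
                for comb in itertools.combinations(itertools.combinations(range(n), 2), n - 1)
                if nx.is_connected(nx.Graph(list(comb)) if len(comb) else nx.empty_graph(n))
                and nx.Graph(list(comb)).number_of_nodes() == n
            ) if n > 1 else 0
            assert total == best

    def test_rejects_non_square(self):
        with pytest.raises(ValueError):
            prim_mst(np.zeros((2, 3)))


class TestTripletCandidates:
    def test_degenerate_triplet(self):
        assert triplet_steiner_candidates((1, 2), (1, 2), (1, 2)) == set()

    def test_small_grid(self):
        assert triplet_steiner_candidates((1, 2), (2, 1), (2, 2)) == {(1, 1)}

    def test_all_distinct_counts(self):
        u, v, w = (0, 0, 0), (1, 1, 1), (2, 2, 2)
        assert len(triplet_steiner_candidates(u, v, w)) == 27 - 3


class TestDistanceMatrix:
    def test_single_config(self):
        m = ChromosomeMap.singletons(2)
        M = symmetric_distance_matrix([(2, 2)], Model.SD_CD_GD, m)
        assert M.shape == (1, 1) and M[0, 0] == 0

    def test_gd_asymmetry_resolved_by_min(self):
        m = ChromosomeMap.singletons(2)
        M = symmetric_distance_matrix([(2, 2), (4, 4)], Model.SD_CD_GD, m)
        assert M[0, 1] == M[1, 0] == 1

    def test_sd_model_is_l1(self):
        rng = random.Random(37)
        m = ChromosomeMap.singletons(3)
        cfgs = list({random_config(rng, 3, 9) for _ in range(6)})
        M = symmetric_distance_matrix(cfgs, Model.SD, m)
        for i, a in enumerate(cfgs):
            for j, b in enumerate(cfgs):
                assert M[i, j] == sum(abs(x - y) for x, y in zip(a, b))

    def test_duplicates_rejected(self):
        m = ChromosomeMap.singletons(2)
        with pytest.raises(ValueError):
            symmetric_distance_matrix([(2, 2), (2, 2)], Model.SD, m)


class TestInferTree:
    def test_single_configuration(self):
        m = ChromosomeMap.singletons(2)
        t = infer_tree([(2, 2), (2, 2)], Model.SD_CD_GD, m)
        assert t.number_of_nodes() == 1 and tree_weight(t) == 0
        assert t.nodes[(2, 2)]["weight"] == 1.0

    def test_two_configurations(self):
        m = ChromosomeMap.singletons(2)
        t = infer_tree([(2, 2), (4, 4)], Model.SD_CD_GD, m)
        assert tree_weight(t) == 1
        assert t.has_edge((2, 2), (4, 4))

    def test_no_helpful_steiner_exists(self, pair_map):
        """Three near-diploid cells plus the root: weight 3 is already
        optimal, so the search must not add Steiner nodes."""
        cells = [(3, 2), (2, 3), (3, 3), (2, 2)]
        t = infer_tree(cells, Model.SD_CD_GD, pair_map)
        assert tree_weight(t) == 3
        assert t.number_of_nodes() == 4

    def test_spans_observed_and_deterministic(self):
        rng = random.Random(41)
        m = random_layout(rng, 4)
        cells = [random_config(rng, 4, 6) for _ in range(30)]
        p = SteinerSearchParams(rng_seed=9)
        t1 = infer_tree(cells, Model.SD_CD_GD, m, Bounds(), p)
        t2 = infer_tree(cells, Model.SD_CD_GD, m, Bounds(), p)
        assert nx.utils.graphs_equal(t1, t2)
        observed = {tuple(c) for c in cells}
        assert observed <= set(t1.nodes)
        # parsimony lower bound: every edge costs at least 1
        assert tree_weight(t1) >= len(observed | {t1.graph["root"]}) - 1

    def test_steiner_nodes_have_zero_weight(self):
        rng = random.Random(43)
        m = random_layout(rng, 4)
        cells = [random_config(rng, 4, 6) for _ in range(25)]
        t = infer_tree(cells, Model.SD_CD_GD, m)
        for nd, attrs in t.nodes(data=True):
            if not attrs["observed"]:
                assert attrs["weight"] == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            infer_tree([], Model.SD, ChromosomeMap.singletons(2))


class TestPruneSteiner:
    def _ctx(self):
        return DistanceContext(Model.SD, ChromosomeMap.singletons(2), Bounds())

    def test_steiner_leaf_removed_observed_kept(self):
        T = nx.Graph()
        T.add_node((2, 2), observed=True, weight=0.5)
        T.add_node((3, 2), observed=True, weight=0.5)
        T.add_node((4, 2), observed=False, weight=0.0)
        T.add_edge((2, 2), (3, 2), weight=1)
        T.add_edge((3, 2), (4, 2), weight=1)
        T.graph["root"] = (2, 2)
        out = prune_steiner_nodes(T, self._ctx())
        assert (4, 2) not in out and (3, 2) in out

    def test_collinear_steiner_removed(self):
        T = nx.Graph()
        T.add_node((2, 2), observed=True, weight=0.5)
        T.add_node((3, 2), observed=False, weight=0.0)
        T.add_node((4, 2), observed=True, weight=0.5)
        T.add_edge((2, 2), (3, 2), weight=1)
        T.add_edge((3, 2), (4, 2), weight=1)
        T.graph["root"] = (2, 2)
        out = prune_steiner_nodes(T, self._ctx())
        assert (3, 2) not in out
        assert out[(2, 2)][(4, 2)]["weight"] == 2


class TestRegraft:
    def test_doubling_edge_untouched(self, pair_map):
        ctx = DistanceContext(Model.SD_CD_GD, pair_map, Bounds())
        T = nx.DiGraph(root=(2, 2))
        T.add_node((2, 2), observed=True, weight=0.5)
        T.add_node((4, 4), observed=True, weight=0.5)
        T.add_edge((2, 2), (4, 4), weight=1)
        out = regraft_gd_edges(T, ctx)
        assert nx.utils.graphs_equal(out, T)

    def test_halving_direction_repaired(self):
        """A chain rooted so that one edge runs (4,4) -> (2,2) costs d=2;
        regrafting must not increase the total directed weight."""
        m = ChromosomeMap.singletons(2)
        ctx = DistanceContext(Model.SD_CD_GD, m, Bounds())
        T = nx.DiGraph(root=(4, 4))
        for nd in [(4, 4), (2, 2), (2, 3)]:
            T.add_node(nd, observed=True, weight=1 / 3)
        T.add_edge((4, 4), (2, 2), weight=ctx.distance((4, 4), (2, 2)))
        T.add_edge((2, 2), (2, 3), weight=1)
        before = tree_weight(T)
        out = regraft_gd_edges(T, ctx)
        assert tree_weight(out) <= before
        assert set(out.nodes) == set(T.nodes)
        assert nx.is_arborescence(out)


class TestEstimator:
    def test_fit_sets_attributes(self):
        X = np.array([[2, 2], [3, 2], [3, 3], [2, 2]])
        est = CopyNumberPhylogeny(model="sdcdgd", chromosomes=["chr1", "chr1"])
        est.fit(X)
        assert est.n_features_in_ == 2
        assert est.weight_ == tree_weight(est.tree_)
        assert est.root_ == (2, 2)

    def test_sklearn_clone_roundtrip(self):
        from sklearn.base import clone

        est = CopyNumberPhylogeny(model="sd", random_state=3)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_invalid_input(self):
        with pytest.raises(ValueError):
            CopyNumberPhylogeny().fit(np.array([[2.5, 2.2]]))
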