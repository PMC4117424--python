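"""Heuristic Steiner-tree phylogenies over single-cell copy-number profiles.

The inference pipeline, in the median-joining tradition:

1. deduplicate the sampled cells into weighted configurations and add the
   diploid founder (2, ..., 2) as the root (a Steiner node when unobserved);
2. build the pairwise distance matrix under the chosen event model,
   symmetrized as ``min(d(i->j), d(j->i))`` since doublings are directed;
3. compute a minimum spanning tree (Prim);
4. repeatedly sample node triplets and propose Steiner candidates that agree
   in every coordinate with at least one member of the triplet; candidates
   that strictly reduce the MST cost are added, until no candidate helps;
5. prune Steiner nodes that no longer pay for themselves, root the tree at
   the diploid configuration, and regraft subtrees hanging on edges whose
   cheap direction was the (impossible) halving direction.

The total directed edge weight of the final tree is a parsimony score: the
number of mutational events the tree requires.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator

from .core import Bounds, ChromosomeMap, Config, as_config, configs_to_array
from .distance import DistanceContext, LandingTable, Model


@dataclass
class SteinerSearchParams:
    """Search-effort knobs for the triplet-sampling Steiner phase.

    ``triplets_per_round=None`` uses one triplet per current node.
    ``max_exact_per_triplet`` caps how many screened grid candidates per
    triplet are scored by an exact MST re-computation.
    """

    triplets_per_round: int | None = None
    max_rounds: int = 50
    max_exact_per_triplet: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.max_rounds <= 0 or self.max_exact_per_triplet <= 0:
            raise ValueError("search parameters must be positive")
        if self.triplets_per_round is not None and self.triplets_per_round <= 0:
            raise ValueError("triplets_per_round must be positive")


def symmetric_distance_matrix(
    configs: Sequence[Config],
    model: Model,
    m: ChromosomeMap,
    bd: Bounds = Bounds(),
) -> np.ndarray:
    """``min(d(i->j), d(j->i))`` for each distinct pair; zero diagonal."""
    configs = [as_config(c) for c in configs]
    if len(set(configs)) != len(configs):
        raise ValueError("configurations must be distinct")
    D = DistanceContext(model, m, bd).distance_matrix(configs)
    return np.minimum(D, D.T)


def prim_mst(matrix: np.ndarray) -> tuple[list[tuple[int, int]], int]:
    """Minimum spanning tree by Prim's algorithm.

    Ties break to the smallest node index (``argmin`` returns the first
    minimum), which makes the tree deterministic.  Returns the edge list and
    the total weight.
    """
    W = np.asarray(matrix)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("distance matrix must be square")
    n = W.shape[0]
    if n == 1:
        return [], 0
    in_tree = np.zeros(n, dtype=bool)
    best = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    parent = np.full(n, -1, dtype=np.int64)
    in_tree[0] = True
    best[0] = 0
    np.minimum(best, W[0], out=best)
    parent[1:] = 0
    edges: list[tuple[int, int]] = []
    total = 0
    for _ in range(n - 1):
        masked = np.where(in_tree, np.iinfo(np.int64).max, best)
        j = int(np.argmin(masked))
        edges.append((int(parent[j]), j))
        total += int(best[j])
        in_tree[j] = True
        improve = W[j] < best
        improve &= ~in_tree
        parent[improve] = j
        best[improve] = W[j][improve]
    return edges, total


def triplet_steiner_candidates(
    u: Sequence[int], v: Sequence[int], w: Sequence[int]
) -> set[Config]:
    """All configurations agreeing with u, v or w in each coordinate, minus
    the triplet itself."""
    u, v, w = as_config(u), as_config(v), as_config(w)
    if not len(u) == len(v) == len(w):
        raise ValueError("triplet members must have equal length")
    grid = set(itertools.product(*({a, b, c} for a, b, c in zip(u, v, w))))
    return grid - {u, v, w}


def _mst_with_candidate(
    mst_edges: list[tuple[int, int]], S: np.ndarray, col: np.ndarray
) -> int:
    """Exact MST weight after adding one node with symmetric column ``col``.

    The MST of a graph plus one vertex uses only the old MST edges and the
    new vertex's edges, so Kruskal on those 2n-1 edges suffices.
    """
    n = S.shape[0]
    us = np.array([u for u, _ in mst_edges] + list(range(n)), dtype=np.int64)
    vs = np.array([v for _, v in mst_edges] + [n] * n, dtype=np.int64)
    ws = np.concatenate(
        [np.array([S[u, v] for u, v in mst_edges], dtype=np.int64), col]
    )
    order = np.argsort(ws, kind="stable")
    parent = list(range(n + 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    total = 0
    joined = 0
    for e in order:
        ru, rv = find(int(us[e])), find(int(vs[e]))
        if ru != rv:
            parent[ru] = rv
            total += int(ws[e])
            joined += 1
            if joined == n:
                break
    return total


class _NodeSet:
    """Growable node set with cached directed/symmetric distance matrices.

    The GD-recursion landing sets of every node are kept stacked in one
    matrix so that the directed distances from a single candidate to all
    nodes reduce to one vectorized pass plus a segment-wise minimum.
    """

    def __init__(self, configs: list[Config], ctx: DistanceContext):
        self.ctx = ctx
        self.configs = list(configs)
        self.index = {c: i for i, c in enumerate(self.configs)}
        self.X = configs_to_array(self.configs)
        self.table = LandingTable(ctx, self.configs)
        self.D = self.table.dist_from(self.X).T.copy()  # D[i, j] = d(i -> j)
        self.S = np.minimum(self.D, self.D.T)

    def sym_columns(self, cands: list[Config]) -> np.ndarray:
        """(n, m) symmetric distances between current nodes and candidates."""
        C = configs_to_array(cands)
        to_nodes = self.table.dist_from(C)  # (m, n): d(cand -> node)
        cand_table = LandingTable(self.ctx, cands)
        from_nodes = cand_table.dist_from(self.X)  # (n, m): d(node -> cand)
        return np.minimum(to_nodes.T, from_nodes)

    def add(self, c: Config, col: np.ndarray) -> None:
        n = len(self.configs)
        D = np.zeros((n + 1, n + 1), dtype=np.int64)
        D[:n, :n] = self.D
        # directed entries are refined lazily; the symmetric matrix drives
        # the MST phase, and final edge weights are recomputed when rooting
        D[:n, n] = col
        D[n, :n] = col
        self.D = D
        S = np.zeros((n + 1, n + 1), dtype=np.int64)
        S[:n, :n] = self.S
        S[:n, n] = col
        S[n, :n] = col
        self.S = S
        self.configs.append(c)
        self.index[c] = n
        self.X = np.vstack([self.X, np.asarray(c, dtype=np.int64)[None, :]])
        self.table.add_target(c)


def infer_tree(
    cells: Sequence[Sequence[int]],
    model: Model,
    m: ChromosomeMap,
    bd: Bounds = Bounds(),
    params: SteinerSearchParams | None = None,
) -> nx.DiGraph:
    """Infer a rooted copy-number phylogeny from sampled cell profiles."""
    if len(cells) == 0:
        raise ValueError("need at least one cell")
    params = params or SteinerSearchParams()
    cells = [as_config(c) for c in cells]
    for c in cells:
        if not bd.contains(c):
            raise ValueError(f"cell {c} outside bounds")
    counts: dict[Config, int] = {}
    for c in cells:
        counts[c] = counts.get(c, 0) + 1
    n_cells = len(cells)
    root = (2,) * m.n_probes
    observed = set(counts)
    configs = sorted(observed | {root})

    ctx = DistanceContext.shared(model, m, bd)
    nodes = _NodeSet(configs, ctx)
    mst_edges, mst_cost = prim_mst(nodes.S)

    rng = np.random.default_rng(params.rng_seed)
    rejected: set[Config] = set()
    for _ in range(params.max_rounds):
        n = len(nodes.configs)
        if n < 3:
            break
        n_triplets = params.triplets_per_round or n
        pool: dict[Config, int] = {}
        existing = set(nodes.configs)
        if model.allows_gd:
            # GD-aware candidates: the nearest-even halves (pre-doubling
            # states) of every current node are natural Steiner ancestors
            # that triplet grids cannot propose
            for v in nodes.configs:
                for r, _ in ctx.landings(v):
                    if r not in existing and r not in rejected and r != v:
                        pool[r] = 0
        for _ in range(n_triplets):
            i, j, k = rng.choice(n, size=3, replace=False)
            u, v, w = nodes.configs[i], nodes.configs[j], nodes.configs[k]
            cands = [
                c
                for c in triplet_steiner_candidates(u, v, w)
                if c not in existing and c not in rejected and c not in pool
            ]
            if not cands:
                continue
            # cheap L1 screen: rank by rectilinear connection cost to the
            # triplet (the coordinate-wise median always ranks first)
            C = configs_to_array(cands)
            score = (
                np.abs(C - np.asarray(u)).sum(1)
                + np.abs(C - np.asarray(v)).sum(1)
                + np.abs(C - np.asarray(w)).sum(1)
            )
            order = np.argsort(score, kind="stable")[: params.max_exact_per_triplet]
            for idx in order:
                pool[cands[int(idx)]] = int(score[int(idx)])
        if not pool:
            break
        # exact scoring against the round-start MST, greedy acceptance
        cands = sorted(pool)
        cols = nodes.sym_columns(cands)  # (n, m)
        scored: list[tuple[int, Config, np.ndarray]] = []
        for j, cand in enumerate(cands):
            saving = mst_cost - _mst_with_candidate(mst_edges, nodes.S, cols[:, j])
            if saving > 0:
                scored.append((saving, cand, cols[:, j]))
            else:
                rejected.add(cand)
        scored.sort(key=lambda t: (-t[0], t[1]))
        accepted_any = False
        for _, cand, col in scored:
            if len(col) < len(nodes.configs):
                # extend the column to nodes accepted earlier this round
                extra = [
                    min(ctx.distance(cand, nd), ctx.distance(nd, cand))
                    for nd in nodes.configs[len(col) :]
                ]
                col = np.concatenate([col, np.asarray(extra, dtype=np.int64)])
            new_cost = _mst_with_candidate(mst_edges, nodes.S, col)
            if new_cost < mst_cost:
                nodes.add(cand, col)
                mst_edges, mst_cost = prim_mst(nodes.S)
                accepted_any = True
            else:
                rejected.add(cand)
        if not accepted_any:
            break

    # undirected weighted tree over the final node set
    T = nx.Graph()
    for idx, cfg in enumerate(nodes.configs):
        T.add_node(
            cfg,
            observed=cfg in observed,
            weight=counts.get(cfg, 0) / n_cells,
        )
    for i, j in mst_edges:
        T.add_edge(nodes.configs[i], nodes.configs[j], weight=int(nodes.S[i, j]))
    T.graph["root"] = root

    T = prune_steiner_nodes(T, ctx)
    D = _root_and_direct(T, root, ctx)
    D = regraft_gd_edges(D, ctx)
    D.graph["model"] = model
    return D


def prune_steiner_nodes(tree: nx.Graph, ctx: DistanceContext) -> nx.Graph:
    """Drop Steiner nodes that do not reduce the tree weight.

    Degree-1 Steiner nodes are removed outright; a degree-2 Steiner node is
    removed when connecting its two neighbors directly costs no more than
    the path through it.  Iterates to a fixed point.  The root is kept.
    """
    T = tree.copy()
    root = T.graph.get("root")
    changed = True
    while changed:
        changed = False
        for nd in sorted(T.nodes):
            if nd == root or T.nodes[nd]["observed"]:
                continue
            deg = T.degree(nd)
            if deg == 1:
                T.remove_node(nd)
                changed = True
            elif deg == 2:
                a, b = sorted(T.neighbors(nd))
                direct = min(ctx.distance(a, b), ctx.distance(b, a))
                through = T[a][nd]["weight"] + T[nd][b]["weight"]
                if direct <= through:
                    T.remove_node(nd)
                    if not T.has_edge(a, b):
                        T.add_edge(a, b, weight=direct)
                    changed = True
    return T


def _root_and_direct(T: nx.Graph, root: Config, ctx: DistanceContext) -> nx.DiGraph:
    D = nx.DiGraph()
    D.graph.update(T.graph)
    for nd, attrs in T.nodes(data=True):
        D.add_node(nd, **attrs)
    for parent, child in nx.bfs_edges(T, root):
        D.add_edge(parent, child, weight=ctx.distance(parent, child))
    return D


def regraft_gd_edges(tree: nx.DiGraph, ctx: DistanceContext) -> nx.DiGraph:
    """Repair edges whose MST weight came from the halving direction.

    The MST phase uses symmetrized distances, but a GD edge is only cheap
    parent->child when the parent is the half.  Any edge whose directed
    weight exceeds its symmetric weight is a candidate: the child's subtree
    is detached and reattached below the node (outside the subtree) that
    reaches the child most cheaply, keeping the change only when the total
    directed weight does not increase.
    """
    T = tree.copy()
    root = T.graph["root"]
    total = tree_weight(T)
    for parent, child in list(nx.bfs_edges(tree, root)):
        if not T.has_edge(parent, child):
            continue  # structure changed by an earlier regraft
        w_dir = T[parent][child]["weight"]
        w_sym = min(w_dir, ctx.distance(child, parent))
        if w_dir <= w_sym:
            continue
        subtree = set(nx.descendants(T, child)) | {child}
        hosts = [nd for nd in sorted(T.nodes) if nd not in subtree]
        if not hosts:
            continue
        dists = ctx.evaluator(child).dist_from(configs_to_array(hosts))
        best = int(np.argmin(dists))
        host, w_new = hosts[best], int(dists[best])
        if host == parent:
            continue
        new_total = total - w_dir + w_new
        if new_total <= total:
            T.remove_edge(parent, child)
            T.add_edge(host, child, weight=w_new)
            total = new_total
    return T


def tree_weight(tree: nx.DiGraph) -> int:
    """Parsimony score: sum of directed edge weights."""
    return int(sum(w for _, _, w in tree.edges(data="weight")))


class CopyNumberPhylogeny(BaseEstimator):
    """Steiner-tree copy-number phylogeny estimator.

    Parameters
    ----------
    model : {"sd", "sdcd", "sdgd", "sdcdgd"} or Model
        Event model used for all distances.
    chromosomes : sequence of str or None
        Chromosome label per probe (same-chromosome probes contiguous);
        ``None`` places every probe on its own chromosome.
    bounds : tuple (lb, ub)
        Copy-number bounds; FISH counts saturate at ub.
    triplets_per_round, max_rounds, max_exact_per_triplet
        Steiner search effort (see :class:`SteinerSearchParams`).
    random_state : int
        Seed for the triplet sampler; fixed seed gives a bit-identical tree.

    Attributes
    ----------
    tree_ : networkx.DiGraph
        Rooted phylogeny; nodes are copy-number tuples with ``observed`` and
        ``weight`` (cell fraction) attributes, edges carry directed model
        distances.
    weight_ : int
        Parsimony score of the fitted tree.
    root_ : tuple of int
        The diploid root configuration.
    """

    def __init__(
        self,
        model: str | Model = "sdcdgd",
        chromosomes: Sequence[str] | None = None,
        bounds: tuple[int, int] = (0, 9),
        triplets_per_round: int | None = None,
        max_rounds: int = 50,
        max_exact_per_triplet: int = 5,
        random_state: int = 0,
    ):
        self.model = model
        self.chromosomes = chromosomes
        self.bounds = bounds
        self.triplets_per_round = triplets_per_round
        self.max_rounds = max_rounds
        self.max_exact_per_triplet = max_exact_per_triplet
        self.random_state = random_state

    def _resolve(self, n_probes: int) -> tuple[Model, ChromosomeMap, Bounds]:
        model = Model(self.model) if not isinstance(self.model, Model) else self.model
        if self.chromosomes is None:
            cmap = ChromosomeMap.singletons(n_probes)
        else:
            if len(self.chromosomes) != n_probes:
                raise ValueError("chromosomes length must equal the probe count")
            cmap = ChromosomeMap(
                [f"p{i + 1}" for i in range(n_probes)], list(self.chromosomes)
            )
        return model, cmap, Bounds(*self.bounds)

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("X must be a nonempty 2d array of copy numbers")
        if not np.issubdtype(X.dtype, np.integer):
            Xr = np.rint(X)
            if not np.allclose(X, Xr):
                raise ValueError("copy numbers must be integers")
            X = Xr.astype(np.int64)
        model, cmap, bd = self._resolve(X.shape[1])
        params = SteinerSearchParams(
            triplets_per_round=self.triplets_per_round,
            max_rounds=self.max_rounds,
            max_exact_per_triplet=self.max_exact_per_triplet,
            rng_seed=self.random_state,
        )
        self.n_features_in_ = X.shape[1]
        self.tree_ = infer_tree([tuple(row) for row in X], model, cmap, bd, params)
        self.weight_ = tree_weight(self.tree_)
        self.root_ = self.tree_.graph["root"]
        return self
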