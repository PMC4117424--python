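"""Comparing inferred phylogenies with simulated ground truth.

The tree-comparison metric works on *bipartitions*: deleting one tree edge
splits the taxa (unique copy-number configurations) into two sides.  The
true tree is first pruned of subtrees from which no cell was sampled, so an
inference is never penalized for clones it could not possibly see.  The
nontrivial bipartitions of the two trees (both sides holding at least two
common taxa) are then paired by a maximum-weight matching, scoring a pair
of bipartitions by the number of taxa they place in agreement.  The
reconstruction error

    E = 100 * (1 - 2 W / (|C| * (|B_R| + |B_I|)))

normalizes the matching weight ``W`` essentially by the total number of
edges of the two trees: it is 0 for isomorphic trees and approaches 100 in
the limit of complete disagreement.  Unlike Robinson-Foulds, the metric is
defined for trees over different node sets.

A generic neighbor-joining baseline (Euclidean distances between unique
profiles) is included for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj
from sklearn.base import BaseEstimator

from .core import Config, as_config

Split = tuple[frozenset, frozenset]


def prune_unsampled_subtrees(
    true_tree: nx.DiGraph, sampled: Sequence[int] | Sequence[Config]
) -> nx.DiGraph:
    """Remove every maximal subtree from which no cell was sampled.

    ``sampled`` is either the clone (node) ids the cells were drawn from, or
    cell configurations (a clone then counts as sampled when its profile was
    observed).  A clone with any sampled descendant survives.
    """
    sampled = list(sampled)
    if sampled and isinstance(sampled[0], (tuple, list)):
        cfgs = {as_config(c) for c in sampled}
        is_sampled = {n: true_tree.nodes[n]["config"] in cfgs for n in true_tree}
    else:
        ids = set(int(s) for s in sampled)
        is_sampled = {n: n in ids for n in true_tree}
    root = next(n for n in true_tree if true_tree.in_degree(n) == 0)
    keep: set = set()
    for n in reversed(list(nx.topological_sort(true_tree))):
        if is_sampled[n] or any(c in keep for c in true_tree.successors(n)):
            keep.add(n)
    keep.add(root)
    return true_tree.subgraph(keep).copy()


# ---------------------------------------------------------------------------
# bipartitions
# ---------------------------------------------------------------------------


def _as_taxon_tree(tree) -> tuple[nx.Graph, dict]:
    """Normalize the supported tree types to (undirected graph, node->taxon).

    Taxa are copy-number tuples.  Steiner nodes of inferred trees and
    internal NJ nodes carry no taxon (``None``).
    """
    if isinstance(tree, TreeNode):
        G = nx.Graph()
        taxon: dict = {}
        for i, node in enumerate(tree.traverse(include_self=True)):
            node._cnv_id = i
        for node in tree.traverse(include_self=True):
            taxon[node._cnv_id] = (
                as_config(node.name.split(",")) if node.is_tip() else None
            )
            if node.parent is not None:
                G.add_edge(node.parent._cnv_id, node._cnv_id)
            else:
                G.add_node(node._cnv_id)
        return G, taxon
    if isinstance(tree, (nx.DiGraph, nx.Graph)):
        G = tree.to_undirected(as_view=False) if tree.is_directed() else tree.copy()
        taxon = {}
        for n, attrs in tree.nodes(data=True):
            if "config" in attrs:  # ground-truth clone tree
                taxon[n] = attrs["config"]
            elif attrs.get("observed", True):
                taxon[n] = as_config(n)
            else:
                taxon[n] = None
        return G, taxon
    raise TypeError(f"unsupported tree type: {type(tree)!r}")


def tree_taxa(tree, unique_only: bool = False) -> set[Config]:
    """Taxa of a tree; with ``unique_only`` drop profiles occurring at more
    than one node, whose placement is ambiguous."""
    from collections import Counter

    _, taxon = _as_taxon_tree(tree)
    counts = Counter(t for t in taxon.values() if t is not None)
    if unique_only:
        return {t for t, k in counts.items() if k == 1}
    return set(counts)


def nontrivial_bipartitions(tree, C: set[Config]) -> list[Split]:
    """Distinct edge-induced splits restricted to the common taxa ``C``.

    A taxon occurring on both sides of a split (duplicate clones in the
    ground truth) supports neither side and is dropped from that split; a
    split is nontrivial when both sides retain at least two taxa.
    """
    from collections import Counter

    G, taxon = _as_taxon_tree(tree)
    if G.number_of_nodes() <= 1:
        return []
    total: Counter = Counter(
        taxon[n] for n in G if taxon[n] is not None and taxon[n] in C
    )
    root = min(G.nodes, key=lambda n: str(n))
    parent_of = dict(nx.bfs_predecessors(G, root))
    order = list(nx.bfs_tree(G, root))
    # per-edge taxon occurrence counts inside the child subtree
    inside: dict = {n: Counter() for n in G}
    for n in reversed(order):
        t = taxon[n]
        if t is not None and t in C:
            inside[n][t] += 1
        if n in parent_of:
            inside[parent_of[n]].update(inside[n])
    seen: set[frozenset] = set()
    splits: list[Split] = []
    for n in parent_of:  # one candidate split per edge (n, parent)
        cnt = inside[n]
        # a taxon supports a side only when all its occurrences are there
        a = frozenset(t for t, k in cnt.items() if k == total[t])
        b = frozenset(t for t in total if cnt[t] == 0)
        if len(a) >= 2 and len(b) >= 2:
            key = frozenset((a, b))
            if key not in seen:
                seen.add(key)
                splits.append((a, b))
    return splits


def matching_weight(B_R: Sequence[Split], B_I: Sequence[Split], C: set[Config]) -> int:
    """Maximum-weight bipartite matching of bipartitions (Hungarian).

    A pair of bipartitions scores the larger of its two orientation-wise
    taxon agreements ``|A1 n A2| + |B1 n B2|``.
    """
    if not B_R or not B_I:
        return 0
    S = np.zeros((len(B_R), len(B_I)), dtype=np.int64)
    for i, (a1, b1) in enumerate(B_R):
        for j, (a2, b2) in enumerate(B_I):
            S[i, j] = max(
                len(a1 & a2) + len(b1 & b2),
                len(a1 & b2) + len(b1 & a2),
            )
    rows, cols = linear_sum_assignment(S, maximize=True)
    return int(S[rows, cols].sum())


@dataclass
class ComparisonResult:
    """Full accounting of one tree comparison."""

    W: int
    C: set[Config]
    B_R: list[Split]
    B_I: list[Split]
    error: float


def compare_trees(true_tree, inferred_tree, sampled=None) -> ComparisonResult:
    """Prune, extract bipartitions, match, and compute the error in percent."""
    if sampled is not None:
        true_tree = prune_unsampled_subtrees(true_tree, sampled)
    # a profile carried by several clones has no unambiguous placement and
    # is not usable as a taxon; identical trees then compare to exactly 0
    taxa_r = tree_taxa(true_tree, unique_only=True)
    taxa_i = tree_taxa(inferred_tree, unique_only=True)
    C = taxa_r & taxa_i
    if not C:
        raise ValueError("trees share no taxa")
    B_R = nontrivial_bipartitions(true_tree, C)
    B_I = nontrivial_bipartitions(inferred_tree, C)
    if not B_R and not B_I:
        return ComparisonResult(0, C, B_R, B_I, 0.0)
    if not B_R or not B_I:
        return ComparisonResult(0, C, B_R, B_I, 100.0)
    W = matching_weight(B_R, B_I, C)
    err = 100.0 * (1.0 - 2.0 * W / (len(C) * (len(B_R) + len(B_I))))
    return ComparisonResult(W, C, B_R, B_I, err)


def reconstruction_error(true_tree, inferred_tree, sampled=None) -> float:
    """Percentage disagreement between true and inferred trees (0..100)."""
    return compare_trees(true_tree, inferred_tree, sampled).error


# ---------------------------------------------------------------------------
# neighbor-joining baseline
# ---------------------------------------------------------------------------


def nj_tree(cells: Sequence[Sequence[int]]) -> TreeNode:
    """Saitou-Nei neighbor joining on Euclidean distances of unique profiles."""
    unique = sorted({as_config(c) for c in cells})
    if len(unique) < 3:
        raise ValueError("neighbor joining needs at least 3 unique profiles")
    X = np.asarray(unique, dtype=float)
    D = squareform(pdist(X, metric="euclidean"))
    ids = [",".join(str(v) for v in cfg) for cfg in unique]
    return nj(DistanceMatrix(D, ids=ids))


class NeighborJoiningPhylogeny(BaseEstimator):
    """Generic NJ baseline as an estimator: ``fit(X)`` sets ``tree_``."""

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValueError("X must be 2d")
        self.n_features_in_ = X.shape[1]
        self.tree_ = nj_tree([tuple(int(v) for v in row) for row in X])
        return self
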