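"""Quantitative features from inferred trees and raw FISH counts.

Tree-derived features summarize how copy-number change is distributed over
the inferred phylogeny (per-gene gain/loss edge fractions, cell mass per
tree level); cell-derived features summarize the raw probe counts (mean
gain/loss relative to diploid, per-gene maxima, Shannon and Simpson
diversity of copy-number "species").  Downstream classification (e.g. an
SVM separating metastasizing from non-metastasizing tumors) composes these
with standard scikit-learn tooling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .core import as_config


@dataclass
class FeatureVector:
    """Named real-valued features with a provenance tag."""

    names: list[str]
    values: np.ndarray
    provenance: str = "tree-based"

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))


def _edges_with_depth(tree: nx.DiGraph):
    root = tree.graph["root"]
    depth = {root: 0}
    for p, c in nx.bfs_edges(tree, root):
        depth[c] = depth[p] + 1
    return depth


def tree_edge_features(tree: nx.DiGraph) -> FeatureVector:
    """Per-gene fractions of tree edges gaining and losing that gene.

    A GD edge raises every gene, so it counts as a gain for each.
    """
    root = tree.graph["root"]
    G = len(root)
    n_edges = tree.number_of_edges()
    gains = np.zeros(G)
    losses = np.zeros(G)
    for p, c in tree.edges():
        for g in range(G):
            if c[g] > p[g]:
                gains[g] += 1
            elif c[g] < p[g]:
                losses[g] += 1
    if n_edges:
        gains /= n_edges
        losses /= n_edges
    names = [f"gain_frac_g{g + 1}" for g in range(G)] + [
        f"loss_frac_g{g + 1}" for g in range(G)
    ]
    return FeatureVector(names, np.concatenate([gains, losses]))


def tree_level_features(tree: nx.DiGraph, levels: int = 4) -> FeatureVector:
    """Fraction of sampled cells at each of the first ``levels`` tree depths."""
    depth = _edges_with_depth(tree)
    vals = np.zeros(levels)
    for nd, d in depth.items():
        if d < levels:
            vals[d] += tree.nodes[nd].get("weight", 0.0)
    names = [f"level_frac_{i}" for i in range(levels)]
    return FeatureVector(names, vals)


def cell_summary_features(cells: Sequence[Sequence[int]]) -> FeatureVector:
    """Per-gene mean gain, mean loss (relative to diploid 2) and maximum."""
    X = np.asarray([as_config(c) for c in cells], dtype=float)
    if X.size == 0:
        raise ValueError("no cells")
    gains = np.clip(X - 2.0, 0.0, None).mean(axis=0)
    losses = np.clip(2.0 - X, 0.0, None).mean(axis=0)
    maxima = X.max(axis=0)
    G = X.shape[1]
    names = (
        [f"mean_gain_g{g + 1}" for g in range(G)]
        + [f"mean_loss_g{g + 1}" for g in range(G)]
        + [f"max_count_g{g + 1}" for g in range(G)]
    )
    return FeatureVector(
        names, np.concatenate([gains, losses, maxima]), provenance="cell-based"
    )


def diversity_indices(
    cells: Sequence[Sequence[int]],
    ploidy: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene Shannon and Simpson indices of copy-number species.

    A species is the pair (copy number, cellular ploidy) when ploidy
    annotations are given, else the copy number alone.  Shannon uses the
    natural log; Simpson is the collision probability ``sum p_i^2``.
    """
    X = np.asarray([as_config(c) for c in cells])
    n, G = X.shape
    if ploidy is not None and len(ploidy) != n:
        raise ValueError("ploidy annotations must match the cell count")
    shannon = np.zeros(G)
    simpson = np.zeros(G)
    for g in range(G):
        from collections import Counter

        if ploidy is None:
            keys = [int(v) for v in X[:, g]]
        else:
            keys = [(int(v), int(p)) for v, p in zip(X[:, g], ploidy)]
        counts = np.asarray(list(Counter(keys).values()), dtype=float)
        p = counts / counts.sum()
        shannon[g] = float(-(p * np.log(p)).sum())
        simpson[g] = float((p**2).sum())
    return shannon, simpson


def tree_statistics(tree: nx.DiGraph) -> tuple[float, float, float]:
    """Three scalar summaries of an inferred tree.

    * level Shannon index: entropy of the cell-mass-by-depth distribution;
    * weighted mean depth: expected depth of a sampled cell;
    * gain/loss balance: sum over genes of (gain fraction - loss fraction)
      of the tree edges.
    """
    depth = _edges_with_depth(tree)
    masses: dict[int, float] = {}
    for nd, d in depth.items():
        w = tree.nodes[nd].get("weight", 0.0)
        if w > 0:
            masses[d] = masses.get(d, 0.0) + w
    p = np.asarray(list(masses.values()))
    total = p.sum()
    if total <= 0:
        level_shannon, mean_depth = 0.0, 0.0
    else:
        p = p / total
        level_shannon = float(-(p * np.log(p)).sum())
        mean_depth = float(
            sum(d * w for d, w in masses.items()) / total
        )
    ef = tree_edge_features(tree)
    G = len(tree.graph["root"])
    balance = float(ef.values[:G].sum() - ef.values[G:].sum())
    return level_shannon, mean_depth, balance


class CellFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transformer mapping a cell-by-probe count matrix to summary features.

    Emits per-gene mean gain, mean loss, maximum copy number, and Shannon
    and Simpson diversity indices — the raw-count feature block used for
    sample classification.  Stateless; ``fit`` only records the feature
    names.
    """

    def __init__(self, include_diversity: bool = True):
        self.include_diversity = include_diversity

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("X must be a nonempty 2d count matrix")
        G = X.shape[1]
        names = cell_summary_features(X[:1]).names
        if self.include_diversity:
            names = names + [f"shannon_g{g + 1}" for g in range(G)] + [
                f"simpson_g{g + 1}" for g in range(G)
            ]
        self.feature_names_out_ = names
        self.n_features_in_ = G
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X)
        base = cell_summary_features(X).values
        if self.include_diversity:
            sh, si = diversity_indices(X)
            base = np.concatenate([base, sh, si])
        return base[None, :]

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_out_, dtype=object)
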