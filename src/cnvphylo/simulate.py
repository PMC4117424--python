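"""Ground-truth tumor simulation by a branching process.

Each simulated tumor starts from a diploid founder clone.  Every clone is
assigned a geometrically distributed number of children; each child differs
from its parent by exactly one event, drawn with probability ``p_sd`` for
each single-gene event, ``p_cd`` for a chromosome event and ``p_gd`` for a
whole-genome doubling (``G * p_sd + p_cd + p_gd = 1``).  SD and CD
directions are uniform; CD events are drawn only for chromosomes carrying at
least two probes (on a singleton chromosome a CD is indistinguishable from
an SD).  Events that would leave the copy-number bounds are redrawn.  Whole
trees outside a size window are discarded and regenerated, conditioning the
study on tumors of comparable complexity.

Sampled cells are drawn from clones either uniformly or with probability
proportional to ``beta ** depth`` (shallow clones are older and more
abundant, so small ``beta`` skews sampling toward the root).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import networkx as nx
import numpy as np

from .core import Bounds, ChromosomeMap, Config, Event, EventKind, apply_event


@dataclass
class SimulationParams:
    """Branching-process parameters.

    ``p_sd`` is the probability of each individual single-gene event, so the
    SD mass totals ``G * p_sd``; the three masses must sum to 1.
    """

    chrom_map: ChromosomeMap
    p_sd: float
    p_cd: float
    p_gd: float
    offspring_mean: float = 0.75
    bounds: Bounds = field(default_factory=Bounds)
    min_nodes: int = 25
    max_nodes: int = 400
    max_retries: int = 100_000

    def __post_init__(self) -> None:
        total = self.chrom_map.n_probes * self.p_sd + self.p_cd + self.p_gd
        # printed probability triples are rounded, so allow slack of 1e-3
        # and renormalize when drawing
        if not math.isclose(total, 1.0, abs_tol=1e-3):
            raise ValueError(f"G*p_sd + p_cd + p_gd must be 1, got {total:.6f}")
        if not 0 <= self.offspring_mean < 1:
            raise ValueError("offspring_mean must be in [0, 1) for a.s. termination")
        if self.p_cd > 0 and not self.chrom_map.multi_probe_chromosomes():
            raise ValueError("p_cd > 0 requires a chromosome with >= 2 probes")
        if self.min_nodes < 1 or self.max_nodes < self.min_nodes:
            raise ValueError("invalid tree-size window")


@dataclass
class SamplingScheme:
    """How observed cells are drawn from the clone tree."""

    kind: Literal["uniform", "depth_geometric"] = "uniform"
    n_cells: int = 250
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0 < self.beta <= 1:
            raise ValueError("beta must be in (0, 1]")


def _draw_event(
    rng: np.random.Generator, params: SimulationParams, parent: Config
) -> Event:
    """One event from the stated distribution, redrawn until valid."""
    m = params.chrom_map
    G = m.n_probes
    multi = params.chrom_map.multi_probe_chromosomes()
    total = G * params.p_sd + params.p_cd + params.p_gd
    for _ in range(10_000):
        u = rng.random() * total
        if u < G * params.p_sd:
            gene = int(rng.integers(G))
            kind = EventKind.SD_GAIN if rng.random() < 0.5 else EventKind.SD_LOSS
            ev = Event(kind, gene)
        elif u < G * params.p_sd + params.p_cd:
            ch = multi[int(rng.integers(len(multi)))]
            kind = EventKind.CD_GAIN if rng.random() < 0.5 else EventKind.CD_LOSS
            ev = Event(kind, ch)
        else:
            ev = Event(EventKind.GD)
        try:
            apply_event(parent, ev, m, params.bounds)
        except ValueError:
            continue
        return ev
    raise RuntimeError("no valid event found (degenerate bounds)")


def _grow_tree(rng: np.random.Generator, params: SimulationParams) -> nx.DiGraph:
    m = params.chrom_map
    root_cfg: Config = (2,) * m.n_probes
    T = nx.DiGraph()
    T.add_node(0, config=root_cfg, depth=0, event=None)
    # geometric on {0, 1, ...} with mean mu has success prob 1 / (1 + mu)
    p_child = 1.0 / (1.0 + params.offspring_mean)
    frontier = [0]
    next_id = 1
    while frontier:
        nd = frontier.pop()
        n_children = int(rng.geometric(p_child)) - 1
        for _ in range(n_children):
            if next_id > params.max_nodes:
                T.graph["oversize"] = True
                return T  # caller discards truncated trees
            ev = _draw_event(rng, params, T.nodes[nd]["config"])
            child_cfg = apply_event(T.nodes[nd]["config"], ev, m, params.bounds)
            T.add_node(
                next_id,
                config=child_cfg,
                depth=T.nodes[nd]["depth"] + 1,
                event=ev,
            )
            T.add_edge(nd, next_id)
            frontier.append(next_id)
            next_id += 1
    return T


def simulate_tree(params: SimulationParams, seed: int = 0) -> nx.DiGraph:
    """Simulate one ground-truth clone tree within the size window.

    Nodes carry ``config`` (copy-number tuple), ``depth`` and the generating
    ``event``; node 0 is the diploid root.  Trees outside
    ``[min_nodes, max_nodes]`` are discarded and regenerated; the number of
    discarded attempts is stored in ``T.graph["n_discarded"]``.
    """
    rng = np.random.default_rng(seed)
    for attempt in range(params.max_retries):
        T = _grow_tree(rng, params)
        if (
            not T.graph.get("oversize")
            and params.min_nodes <= T.number_of_nodes() <= params.max_nodes
        ):
            T.graph["n_discarded"] = attempt
            T.graph["params"] = params
            return T
    raise RuntimeError("tree-size window unsatisfiable within the retry cap")


def sample_cells(
    tree: nx.DiGraph, scheme: SamplingScheme, seed: int = 0
) -> tuple[list[Config], list[int]]:
    """Draw cell profiles from the clone tree (with replacement).

    Returns the drawn configurations and the clone (node) ids they came
    from; the node ids feed the pruning step of the tree-comparison metric.
    """
    rng = np.random.default_rng(seed)
    node_ids = sorted(tree.nodes)
    if scheme.kind == "uniform":
        probs = np.full(len(node_ids), 1.0 / len(node_ids))
    elif scheme.kind == "depth_geometric":
        depths = np.array([tree.nodes[n]["depth"] for n in node_ids], dtype=float)
        w = scheme.beta**depths
        probs = w / w.sum()
    else:
        raise ValueError(f"unknown sampling scheme: {scheme.kind!r}")
    draws = rng.choice(len(node_ids), size=scheme.n_cells, p=probs)
    chosen = [node_ids[int(i)] for i in draws]
    return [tree.nodes[n]["config"] for n in chosen], chosen


def table_layout(n_probes: int = 6, n_paired: int = 1) -> ChromosomeMap:
    """Probe map with ``n_paired`` two-probe chromosomes, rest singletons.

    ``n_probes=6, n_paired=1`` is the six-probe layout used throughout the
    event-probability study; ``n_probes=8, n_paired=2`` is the eight-probe
    layout with two shared chromosomes.
    """
    if 2 * n_paired > n_probes:
        raise ValueError("too many paired chromosomes")
    labels: list[str] = []
    ch = 0
    for _ in range(n_paired):
        ch += 1
        labels += [f"chr{ch}", f"chr{ch}"]
    for _ in range(n_probes - 2 * n_paired):
        ch += 1
        labels.append(f"chr{ch}")
    return ChromosomeMap([f"p{i + 1}" for i in range(n_probes)], labels)


def event_probabilities(
    m: ChromosomeMap, sd_weight: float, cd_weight: float, gd_weight: float
) -> tuple[float, float, float]:
    """Normalize per-event weights to a valid (p_sd, p_cd, p_gd) triple.

    ``sd_weight`` is per single-gene event and ``cd_weight`` per chromosome
    event; the total mass ``G*p_sd + n_cd*p_cd_each + p_gd`` is scaled to 1.
    Returns ``(p_sd, p_cd_total, p_gd)`` as `SimulationParams` expects.
    """
    G = m.n_probes
    n_cd = len(m.multi_probe_chromosomes())
    total = G * sd_weight + n_cd * cd_weight + gd_weight
    return (
        sd_weight / total,
        n_cd * cd_weight / total,
        gd_weight / total,
    )
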