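"""Minimum edit distances between copy-number configurations.

Four event models are supported:

* ``SD`` — single-gene gains/losses only; the distance is rectilinear (L1).
* ``SD_CD`` — adds chromosome-level gains/losses.  On one chromosome the
  minimum cost is ``min_t (|t| + sum_i |x_i + t - y_i|)`` over the integer
  chromosome shift ``t`` (all CD events on a chromosome share one sign, and
  no probe mixes SD gains with SD losses in a minimal sequence); the total
  distance decomposes over chromosomes.
* ``SD_GD`` — adds whole-genome doublings to the SD model.
* ``SD_CD_GD`` — the full model.

With GD the distance is *directed* (doubling has no inverse event).  The
directed distance satisfies the recursion

    D(a, v) = min( d_sdcd(a, v),
                   min_{E in N(v)} D(a, E/2) + 1 + d_sdcd(E, v) )

where ``N(v)`` is the nearest-even set of ``v``: the configuration a final
GD event lands on must be a nearest-even neighbor of the target, and the
optimal way to reach an even landing ``E`` is SD/CD edits to ``E/2``
followed by one GD.  Unrolling the recursion per target yields a flat set of
*landing* configurations with additive offsets, which lets distances from
many sources to one target be computed in a single vectorized pass.

A breadth-first-search oracle over the truncated copy-number lattice
(:func:`bfs_distance_oracle`) provides an independent check of every model
on small instances.
"""

from __future__ import annotations

import enum
from collections import deque
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np

from .core import (
    Bounds,
    ChromosomeMap,
    Config,
    Event,
    EventKind,
    EventSequence,
    as_config,
    configs_to_array,
    l1_distance,
    nearest_even_neighbors,
)


class Model(enum.Enum):
    """Event model: which transition types the distance may use."""

    SD = "sd"
    SD_CD = "sdcd"
    SD_GD = "sdgd"
    SD_CD_GD = "sdcdgd"

    @property
    def allows_cd(self) -> bool:
        return self in (Model.SD_CD, Model.SD_CD_GD)

    @property
    def allows_gd(self) -> bool:
        return self in (Model.SD_GD, Model.SD_CD_GD)


@dataclass(frozen=True)
class ChromosomeDistanceResult:
    """Minimal SD+CD cost on one chromosome.

    ``cd_shift`` is the optimal signed number of CD events (gains if
    positive); ``sd_moves[i] = y_i - (x_i + t)`` are the per-probe SD
    residuals.  Ties over ``t`` break to the smallest ``|t|``, then to the
    negative one.
    """

    cost: int
    cd_shift: int
    sd_moves: tuple[int, ...]


def chromosome_sd_cd_distance(
    x: Sequence[int], y: Sequence[int], b: Bounds = Bounds()
) -> ChromosomeDistanceResult:
    """Minimal number of SD+CD events turning ``x`` into ``y`` (one chromosome)."""
    if len(x) != len(y):
        raise ValueError("sub-configurations must have equal length")
    x = as_config(x)
    y = as_config(y)
    if len(x) == 1:
        # CD on a singleton chromosome is indistinguishable from SD
        return ChromosomeDistanceResult(abs(x[0] - y[0]), 0, (y[0] - x[0],))
    key = (x, y, b.lb, b.ub)
    cached = _CHROM_CACHE.get(key)
    if cached is not None:
        return cached
    span = b.ub - b.lb
    best: ChromosomeDistanceResult | None = None
    for t in _shift_order(span):
        cost = abs(t) + sum(abs(xi + t - yi) for xi, yi in zip(x, y))
        if best is None or cost < best.cost:
            best = ChromosomeDistanceResult(
                cost, t, tuple(yi - (xi + t) for xi, yi in zip(x, y))
            )
    assert best is not None
    _CHROM_CACHE[key] = best
    return best


_CHROM_CACHE: dict = {}


@lru_cache(maxsize=None)
def _shift_order(span: int) -> tuple[int, ...]:
    order = [0]
    for k in range(1, span + 1):
        order.extend((-k, k))
    return tuple(order)


def sd_cd_distance(
    a: Sequence[int], b: Sequence[int], m: ChromosomeMap, bd: Bounds = Bounds()
) -> int:
    """Minimal SD+CD distance; decomposes over chromosomes (symmetric)."""
    a = as_config(a)
    b = as_config(b)
    if len(a) != m.n_probes or len(b) != m.n_probes:
        raise ValueError("configuration length does not match the probe map")
    total = 0
    for ch in m.chromosome_labels:
        sl = m.chrom_slice(ch)
        total += chromosome_sd_cd_distance(a[sl], b[sl], bd).cost
    return total


# ---------------------------------------------------------------------------
# boundary-sensitive sequence construction
# ---------------------------------------------------------------------------


def boundary_sensitive_sequence(
    a: Sequence[int],
    b: Sequence[int],
    m: ChromosomeMap,
    bd: Bounds = Bounds(),
    allow_cd: bool = True,
) -> EventSequence:
    """Minimum-length SD(+CD) event sequence whose replay stays in bounds.

    Per chromosome, CD events all share one sign.  When they are losses, a
    probe that needs SD *gains* ("bidirectional") may sit at the lower bound;
    each such probe receives one gain before the next chromosome loss.
    Probes moving in the loss direction ("unidirectional") are emitted after
    the interleaved phase, where validity is automatic.  The gain case is
    symmetric.
    """
    a = as_config(a)
    b = as_config(b)
    events: list[Event] = []
    for ch in m.chromosome_labels:
        sl = m.chrom_slice(ch)
        x, y = a[sl], b[sl]
        if allow_cd and len(x) >= 2:
            res = chromosome_sd_cd_distance(x, y, bd)
            t = res.cd_shift
        else:
            t = 0
        idx = list(range(sl.start, sl.stop))
        cur = list(x)
        gains = [max(yi - (xi + t), 0) for xi, yi in zip(x, y)]
        losses = [max((xi + t) - yi, 0) for xi, yi in zip(x, y)]

        def sd(i_local: int, kind: EventKind) -> None:
            events.append(Event(kind, idx[i_local]))
            cur[i_local] += 1 if kind is EventKind.SD_GAIN else -1

        cd_left = abs(t)
        cd_kind = EventKind.CD_GAIN if t > 0 else EventKind.CD_LOSS
        step = 1 if t > 0 else -1
        while cd_left > 0:
            if t < 0:
                # free bidirectional probes pinned at lb before the next loss
                for i in range(len(cur)):
                    if cur[i] == bd.lb and gains[i] > 0:
                        sd(i, EventKind.SD_GAIN)
                        gains[i] -= 1
            else:
                for i in range(len(cur)):
                    if cur[i] == bd.ub and losses[i] > 0:
                        sd(i, EventKind.SD_LOSS)
                        losses[i] -= 1
            events.append(Event(cd_kind, ch))
            cur = [v + step for v in cur]
            cd_left -= 1
        # remaining SD moves: always valid once the CD phase is complete
        for i in range(len(cur)):
            while gains[i] > 0:
                sd(i, EventKind.SD_GAIN)
                gains[i] -= 1
            while losses[i] > 0:
                sd(i, EventKind.SD_LOSS)
                losses[i] -= 1
    return EventSequence(source=a, target=b, events=events)


# ---------------------------------------------------------------------------
# directed distance with GD: landing sets and evaluators
# ---------------------------------------------------------------------------


class DistanceContext:
    """Caches for one (model, probe map, bounds) triple.

    Holds the per-target landing sets of the GD recursion and vectorized
    per-target evaluators, so that repeated distance queries within one tree
    inference are amortized.
    """

    def __init__(self, model: Model, m: ChromosomeMap, bd: Bounds = Bounds()):
        if m.n_probes <= 0:
            raise ValueError("empty probe map")
        self.model = model
        self.map = m
        self.bounds = bd
        self._landings: dict[Config, tuple[tuple[Config, int], ...]] = {}
        self._evaluators: dict[Config, "DirectedDistanceEvaluator"] = {}
        self._scalar: dict[tuple[Config, Config], int] = {}

    _shared: dict = {}

    @classmethod
    def shared(cls, model: Model, m: ChromosomeMap, bd: Bounds) -> "DistanceContext":
        """Process-wide context cache; amortizes landings across replicates."""
        key = (model, m, bd)
        ctx = cls._shared.get(key)
        if ctx is None:
            ctx = cls(model, m, bd)
            cls._shared[key] = ctx
        return ctx

    # -- base (GD-free) distance ------------------------------------------
    def base_distance(self, a: Config, b: Config) -> int:
        if self.model.allows_cd:
            return sd_cd_distance(a, b, self.map, self.bounds)
        return l1_distance(a, b)

    def base_distance_batch(self, X: np.ndarray, y: Config) -> np.ndarray:
        return _base_batch(
            X, configs_to_array([y]), self.map, self.bounds, self.model.allows_cd
        )[:, 0]

    # -- landing sets ------------------------------------------------------
    def landings(self, v: Config) -> tuple[tuple[Config, int], ...]:
        """Flattened GD recursion for target ``v``.

        Returns pairs ``(r, k)`` such that the directed distance from any
        source ``a`` to ``v`` equals ``min_j base(a, r_j) + k_j``.  The pair
        ``(v, 0)`` (no GD at all) is always present.
        """
        v = as_config(v)
        cached = self._landings.get(v)
        if cached is not None:
            return cached
        best: dict[Config, int] = {v: 0}
        if self.model.allows_gd:
            for e_cfg in sorted(nearest_even_neighbors(v, self.bounds)):
                half = tuple(x // 2 for x in e_cfg)
                if half == v:
                    continue  # would recurse onto the target itself
                offset = 1 + self.base_distance(e_cfg, v)
                for r, k in self.landings(half):
                    cand = k + offset
                    if cand < best.get(r, 1 << 30):
                        best[r] = cand
        result = tuple(sorted(best.items()))
        self._landings[v] = result
        return result

    # -- scalar and batch distances ---------------------------------------
    def distance(self, a: Sequence[int], v: Sequence[int]) -> int:
        """Directed minimal number of valid events transforming ``a`` into ``v``."""
        a = as_config(a)
        v = as_config(v)
        key = (a, v)
        cached = self._scalar.get(key)
        if cached is not None:
            return cached
        d = min(self.base_distance(a, r) + k for r, k in self.landings(v))
        self._scalar[key] = d
        return d

    def evaluator(self, v: Sequence[int]) -> "DirectedDistanceEvaluator":
        v = as_config(v)
        ev = self._evaluators.get(v)
        if ev is None:
            ev = DirectedDistanceEvaluator(self, v)
            self._evaluators[v] = ev
        return ev

    def distance_matrix(self, configs: Sequence[Config]) -> np.ndarray:
        """Directed distance matrix ``D[i, j] = d(configs[i] -> configs[j])``."""
        X = configs_to_array(configs)
        n = len(configs)
        D = np.zeros((n, n), dtype=np.int64)
        for j, v in enumerate(configs):
            D[:, j] = self.evaluator(v).dist_from(X)
        return D


class DirectedDistanceEvaluator:
    """Vectorized directed distance from many sources to one fixed target."""

    def __init__(self, ctx: DistanceContext, target: Config):
        self.ctx = ctx
        self.target = target
        pairs = ctx.landings(target)
        self._R = configs_to_array([r for r, _ in pairs])
        self._k = np.asarray([k for _, k in pairs], dtype=np.int64)

    def dist_from(self, sources: np.ndarray) -> np.ndarray:
        X = np.asarray(sources, dtype=np.int64)
        if X.ndim == 1:
            X = X[None, :]
        cost = _base_batch(
            X, self._R, self.ctx.map, self.ctx.bounds, self.ctx.model.allows_cd
        )
        return (cost + self._k[None, :]).min(axis=1)


class LandingTable:
    """Stacked, deduplicated landing sets for many targets.

    Computes the directed distances from a batch of sources to *all*
    registered targets in one vectorized pass: base distances to the unique
    landing rows, a gather with additive offsets, and a segment-wise
    minimum per target.
    """

    def __init__(self, ctx: DistanceContext, targets: Sequence[Config] = ()):
        self.ctx = ctx
        self.targets: list[Config] = []
        self._urow_index: dict[Config, int] = {}
        self._urows: list[Config] = []
        self._idx: list[int] = []
        self._k: list[int] = []
        self._starts: list[int] = []
        self._cache: tuple | None = None
        for t in targets:
            self.add_target(t)

    def add_target(self, cfg: Config) -> None:
        cfg = as_config(cfg)
        self._starts.append(len(self._idx))
        for r, k in self.ctx.landings(cfg):
            j = self._urow_index.get(r)
            if j is None:
                j = len(self._urows)
                self._urow_index[r] = j
                self._urows.append(r)
        for r, k in self.ctx.landings(cfg):
            self._idx.append(self._urow_index[r])
            self._k.append(k)
        self.targets.append(cfg)
        self._cache = None

    def dist_from(self, sources: np.ndarray) -> np.ndarray:
        """(m, n_targets) directed distances source -> target."""
        X = np.asarray(sources, dtype=np.int64)
        if X.ndim == 1:
            X = X[None, :]
        if self._cache is None:
            self._cache = (
                configs_to_array(self._urows),
                np.asarray(self._idx, dtype=np.int64),
                np.asarray(self._k, dtype=np.int64),
                np.asarray(self._starts, dtype=np.int64),
            )
        U, idx, k, starts = self._cache
        base = _base_batch(X, U, self.ctx.map, self.ctx.bounds, self.ctx.model.allows_cd)
        gathered = base[:, idx] + k[None, :]
        return np.minimum.reduceat(gathered, starts, axis=1)


def _base_batch(
    X: np.ndarray, R: np.ndarray, m: ChromosomeMap, bd: Bounds, allow_cd: bool
) -> np.ndarray:
    """GD-free distance between every source row of X and every row of R."""
    nsrc, p = X.shape[0], R.shape[0]
    total = np.zeros((nsrc, p), dtype=np.int64)
    for ch in m.chromosome_labels:
        sl = m.chrom_slice(ch)
        Xc = X[:, sl]
        Rc = R[:, sl]
        if not allow_cd or Xc.shape[1] == 1:
            total += np.abs(Xc[:, None, :] - Rc[None, :, :]).sum(axis=2)
        else:
            span = bd.ub - bd.lb
            best = None
            for t in range(-span, span + 1):
                c = np.abs(Xc[:, None, :] + t - Rc[None, :, :]).sum(axis=2) + abs(t)
                best = c if best is None else np.minimum(best, c)
            total += best
    return total


def sd_cd_gd_distance(
    a: Sequence[int], b: Sequence[int], m: ChromosomeMap, bd: Bounds = Bounds()
) -> int:
    """Directed minimum number of valid SD/CD/GD events from ``a`` to ``b``."""
    return DistanceContext(Model.SD_CD_GD, m, bd).distance(a, b)


def model_distance(
    a: Sequence[int],
    b: Sequence[int],
    model: Model,
    m: ChromosomeMap,
    bd: Bounds = Bounds(),
) -> int:
    """Dispatch over the four event models."""
    if not isinstance(model, Model):
        raise ValueError(f"unknown model: {model!r}")
    return DistanceContext(model, m, bd).distance(a, b)


# ---------------------------------------------------------------------------
# witness sequences under GD
# ---------------------------------------------------------------------------


def witness_sequence(
    a: Sequence[int],
    b: Sequence[int],
    ctx: DistanceContext,
) -> EventSequence:
    """An optimal boundary-sensitive event sequence from ``a`` to ``b``.

    The GD chain follows the recursion argmin (ties prefer fewer GD events,
    then the lexicographically smallest landing); SD/CD segments use the
    boundary-sensitive interleaving.  The replayed length always equals the
    reported distance.
    """
    a = as_config(a)
    b = as_config(b)
    memo: dict[Config, tuple[int, int, Config | None]] = {}
    plan = _witness_plan(a, b, ctx, memo)
    events: list[Event] = []
    _emit_plan(a, b, plan, ctx, memo, events)
    return EventSequence(source=a, target=b, events=events)


def _witness_plan(a: Config, v: Config, ctx: DistanceContext, memo: dict):
    """Return (dist, n_gd, chain) where chain is None (direct) or the even
    landing E whose half is reached recursively."""
    if v in memo:
        return memo[v]
    direct = ctx.base_distance(a, v)
    best = (direct, 0, None)
    if ctx.model.allows_gd:
        for e_cfg in sorted(nearest_even_neighbors(v, ctx.bounds)):
            half = tuple(x // 2 for x in e_cfg)
            if half == v:
                continue
            sub_d, sub_g, _ = _witness_plan(a, half, ctx, memo)
            cand = (sub_d + 1 + ctx.base_distance(e_cfg, v), sub_g + 1, e_cfg)
            if (cand[0], cand[1]) < (best[0], best[1]):
                best = cand
    memo[v] = best
    return best


def _emit_plan(
    a: Config, v: Config, plan, ctx: DistanceContext, memo: dict, events: list[Event]
) -> None:
    _, _, chain = plan
    if chain is None:
        events.extend(
            boundary_sensitive_sequence(
                a, v, ctx.map, ctx.bounds, allow_cd=ctx.model.allows_cd
            ).events
        )
        return
    e_cfg = chain
    half = tuple(x // 2 for x in e_cfg)
    _emit_plan(a, half, _witness_plan(a, half, ctx, memo), ctx, memo, events)
    events.append(Event(EventKind.GD))
    events.extend(
        boundary_sensitive_sequence(
            e_cfg, v, ctx.map, ctx.bounds, allow_cd=ctx.model.allows_cd
        ).events
    )


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------


def bfs_distance_oracle(
    a: Sequence[int],
    b: Sequence[int],
    model: Model,
    m: ChromosomeMap,
    bd: Bounds = Bounds(),
) -> int:
    """Breadth-first shortest path on the truncated copy-number lattice.

    Enumerates every valid event of the model from each visited state; used
    as the independent correctness oracle on small instances.
    """
    a = as_config(a)
    b = as_config(b)
    G = len(a)
    span = bd.ub - bd.lb + 1
    if G * np.log2(span) > 24.5:
        raise ValueError("state space too large for the BFS oracle")
    if a == b:
        return 0
    seen = {a: 0}
    queue: deque[Config] = deque([a])
    while queue:
        cur = queue.popleft()
        d = seen[cur]
        for nxt in _neighbors(cur, model, m, bd):
            if nxt not in seen:
                if nxt == b:
                    return d + 1
                seen[nxt] = d + 1
                queue.append(nxt)
    raise RuntimeError("target unreachable (cannot happen with SD events)")


def _neighbors(c: Config, model: Model, m: ChromosomeMap, bd: Bounds):
    for i, v in enumerate(c):
        if v + 1 <= bd.ub:
            yield c[:i] + (v + 1,) + c[i + 1 :]
        if v - 1 >= bd.lb:
            yield c[:i] + (v - 1,) + c[i + 1 :]
    if model.allows_cd:
        for ch in m.chromosome_labels:
            sl = m.chrom_slice(ch)
            for delta in (1, -1):
                seg = tuple(v + delta for v in c[sl])
                if all(bd.lb <= v <= bd.ub for v in seg):
                    yield c[: sl.start] + seg + c[sl.stop :]
    if model.allows_gd:
        dbl = tuple(2 * v for v in c)
        if all(v <= bd.ub for v in dbl):
            yield dbl
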