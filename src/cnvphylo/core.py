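"""Domain types and elementary operations on copy-number configurations.

A *configuration* is the vector of integer copy numbers of the assayed FISH
probes in one cell, bounded by ``[lb, ub]`` (FISH counting saturates, so the
software bound defaults to ``[0, 9]``).  Three mutational event types act on
configurations:

* **SD** — gain or loss of one copy of a single gene probe;
* **CD** — gain or loss of one copy of every probe on one chromosome
  (unequal chromosome segregation);
* **GD** — whole-genome duplication: every probe count doubles.

An event is *valid* on a configuration if the result stays within bounds; a
sequence of events is *boundary-sensitive* if every intermediate
configuration is valid.
"""

from __future__ import annotations

import enum
import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("cnvphylo")

Config = tuple[int, ...]


@dataclass(frozen=True)
class Bounds:
    """Integer copy-number floor and ceiling.

    ``lb`` must be even (default 0) so that the nearest-even set of any
    in-bounds configuration is nonempty.
    """

    lb: int = 0
    ub: int = 9

    def __post_init__(self) -> None:
        if self.lb < 0:
            raise ValueError("lb must be >= 0")
        if self.ub <= self.lb:
            raise ValueError("ub must exceed lb")
        if self.lb % 2 != 0:
            raise ValueError("lb must be even")

    def contains(self, c: Sequence[int]) -> bool:
        return all(self.lb <= v <= self.ub for v in c)

    def clamp(self, c: Sequence[int]) -> Config:
        """Clamp entries to bounds (FISH convention: counts above ub read '9+')."""
        out = tuple(min(max(int(v), self.lb), self.ub) for v in c)
        if tuple(int(v) for v in c) != out:
            warnings.warn("copy numbers clamped to bounds", stacklevel=2)
        return out


class ChromosomeMap:
    """Assignment of probe indices to chromosomes.

    Probes sharing a chromosome must occupy consecutive indices; probe order
    is the canonical coordinate order used everywhere (distances, trees,
    files).
    """

    def __init__(self, probe_names: Sequence[str], chromosomes: Sequence[str]):
        if len(probe_names) != len(chromosomes):
            raise ValueError("probe_names and chromosomes must have equal length")
        if len(probe_names) == 0:
            raise ValueError("need at least one probe")
        if len(set(probe_names)) != len(probe_names):
            raise ValueError("duplicate probe names")
        self.probe_names = tuple(str(p) for p in probe_names)
        self.chromosomes = tuple(str(c) for c in chromosomes)
        # consecutive-index check + chromosome slices
        slices: dict[str, slice] = {}
        start = 0
        for i, ch in enumerate(self.chromosomes):
            if i == 0 or ch != self.chromosomes[i - 1]:
                if ch in slices:
                    raise ValueError(
                        f"probes of chromosome {ch!r} are not contiguous"
                    )
                if i > 0:
                    prev = self.chromosomes[i - 1]
                    slices[prev] = slice(start, i)
                start = i
        slices[self.chromosomes[-1]] = slice(start, len(self.chromosomes))
        self._slices = slices

    @property
    def n_probes(self) -> int:
        return len(self.probe_names)

    @property
    def chromosome_labels(self) -> tuple[str, ...]:
        """Distinct chromosome labels in coordinate order."""
        seen: list[str] = []
        for ch in self.chromosomes:
            if not seen or seen[-1] != ch:
                seen.append(ch)
        return tuple(seen)

    def chrom_slice(self, label: str) -> slice:
        return self._slices[label]

    def chrom_of(self, probe_index: int) -> str:
        return self.chromosomes[probe_index]

    def multi_probe_chromosomes(self) -> tuple[str, ...]:
        return tuple(
            ch
            for ch in self.chromosome_labels
            if self._slices[ch].stop - self._slices[ch].start >= 2
        )

    @classmethod
    def singletons(cls, n_probes: int) -> "ChromosomeMap":
        """Every probe on its own chromosome (disables meaningful CD events)."""
        names = [f"p{i + 1}" for i in range(n_probes)]
        return cls(names, [f"chr{i + 1}" for i in range(n_probes)])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ChromosomeMap)
            and self.probe_names == other.probe_names
            and self.chromosomes == other.chromosomes
        )

    def __hash__(self) -> int:
        return hash((self.probe_names, self.chromosomes))

    def __repr__(self) -> str:
        return f"ChromosomeMap({list(self.probe_names)}, {list(self.chromosomes)})"


class EventKind(enum.Enum):
    SD_GAIN = "sd_gain"
    SD_LOSS = "sd_loss"
    CD_GAIN = "cd_gain"
    CD_LOSS = "cd_loss"
    GD = "gd"


@dataclass(frozen=True)
class Event:
    """One mutational event.

    ``target`` is a probe index for SD events, a chromosome label for CD
    events, and ``None`` for GD.
    """

    kind: EventKind
    target: int | str | None = None

    def __post_init__(self) -> None:
        if self.kind in (EventKind.SD_GAIN, EventKind.SD_LOSS):
            if not isinstance(self.target, int):
                raise ValueError("SD events name one probe index")
        elif self.kind in (EventKind.CD_GAIN, EventKind.CD_LOSS):
            if not isinstance(self.target, str):
                raise ValueError("CD events name one chromosome label")
        elif self.target is not None:
            raise ValueError("GD events take no target")


class InvalidEventError(ValueError):
    """The event would push some copy number outside [lb, ub]."""


def apply_event(
    c: Sequence[int], e: Event, m: ChromosomeMap | None = None, b: Bounds = Bounds()
) -> Config:
    """Apply one event to a configuration, enforcing validity.

    Raises :class:`InvalidEventError` when any resulting entry leaves
    ``[lb, ub]`` — the event is *invalid* on ``c``.
    """
    c = tuple(int(v) for v in c)
    if e.kind is EventKind.GD:
        out = tuple(2 * v for v in c)
    elif e.kind in (EventKind.SD_GAIN, EventKind.SD_LOSS):
        delta = 1 if e.kind is EventKind.SD_GAIN else -1
        i = int(e.target)  # type: ignore[arg-type]
        if not 0 <= i < len(c):
            raise IndexError("probe index out of range")
        out = c[:i] + (c[i] + delta,) + c[i + 1 :]
    else:
        if m is None:
            raise ValueError("CD events require a ChromosomeMap")
        delta = 1 if e.kind is EventKind.CD_GAIN else -1
        sl = m.chrom_slice(str(e.target))
        out = (
            c[: sl.start]
            + tuple(v + delta for v in c[sl])
            + c[sl.stop :]
        )
    if not b.contains(out):
        raise InvalidEventError(f"invalid event {e.kind.value} on {c}")
    return out


@dataclass
class EventSequence:
    """Ordered list of events transforming ``source`` into ``target``."""

    source: Config
    target: Config
    events: list[Event] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)

    def replay(self, m: ChromosomeMap | None = None, b: Bounds = Bounds()) -> list[Config]:
        """Replay from the source; raises if any intermediate leaves bounds.

        Returns the list of intermediate configurations (including both
        endpoints).  A successful replay certifies the sequence is
        boundary-sensitive.
        """
        states = [tuple(self.source)]
        for e in self.events:
            states.append(apply_event(states[-1], e, m, b))
        if states[-1] != tuple(self.target):
            raise ValueError("replay does not reach the target configuration")
        return states


def l1_distance(a: Sequence[int], b: Sequence[int]) -> int:
    """Rectilinear (L1) distance between two configurations."""
    if len(a) != len(b):
        raise ValueError("configurations must have equal length")
    return int(sum(abs(int(x) - int(y)) for x, y in zip(a, b)))


def is_even(c: Sequence[int]) -> bool:
    """True iff every copy number is even (an *even* configuration)."""
    return all(int(v) % 2 == 0 for v in c)


def nearest_even_neighbors(c: Sequence[int], b: Bounds = Bounds()) -> set[Config]:
    """The set N(c) of nearest even configurations.

    Each odd entry is rounded down or up to the adjacent even value; even
    entries are kept.  Members violating the bounds are discarded.  These are
    the only possible landings of a final GD event before residual SD/CD
    edits.
    """
    if not b.contains(c):
        raise ValueError("configuration out of bounds")
    choices: list[tuple[int, ...]] = []
    for v in c:
        v = int(v)
        if v % 2 == 0:
            choices.append((v,))
        else:
            choices.append(tuple(x for x in (v - 1, v + 1) if b.lb <= x <= b.ub))
    return set(itertools.product(*choices))


def as_config(c: Iterable[int]) -> Config:
    return tuple(int(v) for v in c)


def configs_to_array(configs: Sequence[Sequence[int]]) -> np.ndarray:
    return np.asarray([tuple(c) for c in configs], dtype=np.int64)
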