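import random

import pytest

from cnvphylo.core import Bounds, ChromosomeMap


@pytest.fixture
def bounds() -> Bounds:
    return Bounds(0, 9)


@pytest.fixture
def pair_map() -> ChromosomeMap:
    """Two probes sharing one chromosome."""
    return ChromosomeMap(["p1", "p2"], ["chr1", "chr1"])


@pytest.fixture
def six_probe_map() -> ChromosomeMap:
    """The six-probe layout: probes 1-2 share a chromosome."""
    from cnvphylo.simulate import table_layout

    return table_layout(6, 1)


def random_layout(rng: random.Random, n_probes: int) -> ChromosomeMap:
    """Random contiguous chromosome layout over ``n_probes`` probes."""
    labels: list[str] = []
    ch = 0
    i = 0
    while i < n_probes:
        k = rng.randint(1, n_probes - i)
        labels.extend([f"c{ch}"] * k)
        ch += 1
        i += k
    return ChromosomeMap([f"p{j}" for j in range(n_probes)], labels)


def random_config(rng: random.Random, n_probes: int, ub: int) -> tuple[int, ...]:
    return tuple(rng.randint(0, ub) for _ in range(n_probes))
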