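"""Shared fixtures: small fixture graphs and brute-force oracles."""

from __future__ import annotations

import itertools

import networkx as nx
import pytest

from commscale.network_io import Network
from commscale.potts import energy


def _net(edges) -> Network:
    return Network.from_edges(edges)


@pytest.fixture
def k3() -> Network:
    return _net([(1, 2), (2, 3), (1, 3)])


@pytest.fixture
def bridged_triangles() -> Network:
    """Two triangles joined by one bridge edge (6 nodes)."""
    return _net([(1, 2), (2, 3), (1, 3), (4, 5), (5, 6), (4, 6), (3, 4)])


@pytest.fixture
def bridged_cliques() -> Network:
    """Two 4-cliques joined by one bridge edge (8 nodes)."""
    edges = list(itertools.combinations([1, 2, 3, 4], 2))
    edges += list(itertools.combinations([5, 6, 7, 8], 2))
    edges.append((4, 5))
    return _net(edges)


@pytest.fixture
def fixture_nets(k3, bridged_triangles, bridged_cliques) -> dict[str, Network]:
    """All shipped small connected fixtures (<= 8 nodes)."""
    return {
        "k3": k3,
        "bridged_triangles": bridged_triangles,
        "bridged_cliques": bridged_cliques,
        "path5": _net([(i, i + 1) for i in range(1, 5)]),
        "cycle6": _net([(i, i % 6 + 1) for i in range(1, 7)]),
        "star5": _net([(0, i) for i in range(1, 6)]),
    }


def set_partitions(items):
    """Enumerate all set partitions (restricted-growth strings)."""
    items = list(items)
    if not items:
        yield []
        return

    def rec(idx, blocks):
        if idx == len(items):
            yield [list(b) for b in blocks]
            return
        x = items[idx]
        for b in blocks:
            b.append(x)
            yield from rec(idx + 1, blocks)
            b.pop()
        blocks.append([x])
        yield from rec(idx + 1, blocks)
        blocks.pop()

    yield from rec(0, [])


def exhaustive_min_energy(net: Network, lam: float) -> float:
    """Exact Potts optimum by enumerating every partition (<= 8 nodes)."""
    nodes = sorted(net.simple().nodes())
    assert len(nodes) <= 8, "exhaustive oracle limited to 8 nodes"
    best = float("inf")
    for blocks in set_partitions(nodes):
        assignment = {n: i for i, b in enumerate(blocks) for n in b}
        best = min(best, energy(net, assignment, lam))
    return best


@pytest.fixture
def exhaustive_oracle():
    return exhaustive_min_energy
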