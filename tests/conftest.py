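"""Shared fixtures: the worked two-leaf examples, small hand-built
networks, and a seeded random corpus."""

from __future__ import annotations

import random

import pytest

from sdcet.netcore import RootedNetwork, SemiDirectedNetwork
from sdcet import explore, partner


@pytest.fixture
def fig_loop_rooted() -> RootedNetwork:
    """Two leaves, one reticulation reached by a parallel pair from the
    root child; its semi-directed projection carries a directed loop."""
    return RootedNetwork(
        edges={0: (0, 1), 1: (1, 2), 2: (1, 2), 3: (2, 3), 4: (3, 4),
               5: (3, 5)},
        root=0, leaf_labels={4: "x1", 5: "x2"})


@pytest.fixture
def fig_loop_sd(fig_loop_rooted) -> SemiDirectedNetwork:
    return partner.to_semidirected(fig_loop_rooted)


@pytest.fixture
def fig_pair_rooted() -> RootedNetwork:
    """Two leaves, root child is the source of a 3-cycle; the projection
    has one parallel directed pair and is level-1."""
    return RootedNetwork(
        edges={0: (0, 1), 1: (1, 2), 2: (1, 3), 3: (2, 3), 4: (2, 4),
               5: (3, 5)},
        root=0, leaf_labels={4: "x1", 5: "x2"})


@pytest.fixture
def fig_pair_sd(fig_pair_rooted) -> SemiDirectedNetwork:
    return partner.to_semidirected(fig_pair_rooted)


@pytest.fixture
def fig_pair_sd_swapped(fig_pair_sd) -> SemiDirectedNetwork:
    net = fig_pair_sd.copy()
    net.leaf_labels = {v: ("x2" if lab == "x1" else "x1")
                       for v, lab in net.leaf_labels.items()}
    return net


@pytest.fixture
def single_edge() -> SemiDirectedNetwork:
    return SemiDirectedNetwork({0: (0, 1, "U")}, {0: "x1", 1: "x2"})


@pytest.fixture
def loop3_sd() -> SemiDirectedNetwork:
    """Loop network on three leaves: loop at w, w - a, a - x1, a - b,
    b - x2, b - x3.  Its rooted partner is unique (rooted at the loop)."""
    return SemiDirectedNetwork(
        edges={0: (0, 0, "D"), 1: (0, 1, "U"), 2: (1, 2, "U"),
               3: (1, 3, "U"), 4: (3, 4, "U"), 5: (3, 5, "U")},
        leaf_labels={2: "x1", 4: "x2", 5: "x3"})


def rooted_corpus(count: int = 20, max_n: int = 7, seed: int = 20240601):
    """Deterministic list of random rooted level-1 networks with varied
    (|X|, k)."""
    rng = random.Random(seed)
    nets = []
    for i in range(count):
        n = rng.randint(2, max_n)
        k = rng.randint(0, n - 1)
        labels = [f"x{j}" for j in range(1, n + 1)]
        nets.append(explore.random_level1(labels, k, seed=seed + 7 * i + 1))
    return nets


def sd_corpus(count: int = 20, max_n: int = 7, seed: int = 20240601):
    return [partner.to_semidirected(nr)
            for nr in rooted_corpus(count, max_n, seed)]
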