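import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from sputumnet.containers import AbundanceTable, Mode, State
from sputumnet.cooccurrence import CooccurrenceNetwork, CorrelationEdge, Thresholds


@pytest.fixture
def counts_table() -> AbundanceTable:
    """Small counts table with known column sums (5100, 4999, 5000)."""
    frame = pd.DataFrame(
        {
            "s1": [5000, 50, 50],
            "s2": [4000, 900, 99],
            "s3": [2500, 2400, 100],
        },
        index=["Streptococcus", "Prevotella", "Veillonella"],
        dtype=float,
    )
    return AbundanceTable(frame, Mode.COUNTS)


@pytest.fixture
def random_counts() -> AbundanceTable:
    rng = np.random.default_rng(12345)
    frame = pd.DataFrame(
        rng.integers(0, 500, size=(8, 12)).astype(float),
        index=[f"G{i}" for i in range(8)],
        columns=[f"s{j}" for j in range(12)],
    )
    return AbundanceTable(frame, Mode.COUNTS)


def network_from_edges(
    edges: list[tuple[str, str]], state: State = State.STABLE
) -> CooccurrenceNetwork:
    """Build a network with nominal rho/p values from a bare edge list."""
    thresholds = Thresholds()
    edge_objs = tuple(
        CorrelationEdge(a, b, 0.8, 0.001, 30) for a, b in edges
    )
    nodes = frozenset(g for e in edge_objs for g in e.pair)
    return CooccurrenceNetwork(state, nodes, edge_objs, thresholds)


@pytest.fixture
def triangle_network() -> CooccurrenceNetwork:
    return network_from_edges([("A", "B"), ("B", "C"), ("A", "C")])


def random_graph(rng: np.random.Generator, n_max: int = 12) -> tuple[list, list]:
    """Random Erdos-Renyi-style graph with 3..n_max nodes, no isolates required."""
    n = int(rng.integers(3, n_max + 1))
    p = rng.uniform(0.15, 0.7)
    nodes = [f"n{i}" for i in range(n)]
    edges = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return nodes, edges
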