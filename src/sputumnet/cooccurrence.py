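"""Spearman co-occurrence matrices, edge filtering and network summaries.

Pairwise Spearman rank correlations are computed between genera on the
relative-abundance table of one disease state.  Edges are kept when
|rho| strictly exceeds the correlation threshold (default 0.6) and the
two-sided p-value is strictly below the significance threshold (default
0.01).  Genera left without a passing edge are excluded from the network,
so node counts per state can differ from genus counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AbundanceTable, Mode, State

__all__ = [
    "CorrelationEdge",
    "CooccurrenceNetwork",
    "NetworkSummary",
    "Thresholds",
    "spearman_matrix",
    "spearman_from_values",
    "build_network",
    "summarize_network",
    "network_from_table",
]


@dataclass(frozen=True)
class Thresholds:
    """Edge filter: |rho| > rho_min (strict) and p < p_max (strict)."""

    rho_min: float = 0.6
    p_max: float = 0.01

    def __post_init__(self) -> None:
        if not 0 <= self.rho_min < 1:
            raise ValueError("rho_min must be in [0, 1)")
        if not 0 < self.p_max <= 1:
            raise ValueError("p_max must be in (0, 1]")


@dataclass(frozen=True)
class CorrelationEdge:
    """A signed, weighted undirected edge between two genera."""

    genus_a: str
    genus_b: str
    rho: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if self.genus_a == self.genus_b:
            raise ValueError("self-edges are not allowed")
        if self.genus_a > self.genus_b:
            a, b = self.genus_b, self.genus_a
            object.__setattr__(self, "genus_a", a)
            object.__setattr__(self, "genus_b", b)
        if abs(self.rho) > 1 + 1e-12:
            raise ValueError(f"|rho| > 1 for edge {self.genus_a}-{self.genus_b}")

    @property
    def sign(self) -> int:
        return 1 if self.rho > 0 else -1

    @property
    def pair(self) -> tuple[str, str]:
        return (self.genus_a, self.genus_b)


@dataclass(frozen=True)
class CooccurrenceNetwork:
    """Filtered co-occurrence network for one disease state."""

    state: State
    nodes: frozenset[str]
    edges: tuple[CorrelationEdge, ...]
    thresholds: Thresholds = Thresholds()

    def __post_init__(self) -> None:
        for e in self.edges:
            if e.genus_a not in self.nodes or e.genus_b not in self.nodes:
                raise ValueError(f"edge {e.pair} endpoint missing from nodes")
            if not (abs(e.rho) > self.thresholds.rho_min and e.p_value < self.thresholds.p_max):
                raise ValueError(f"edge {e.pair} does not satisfy the thresholds")
        touched = {g for e in self.edges for g in e.pair}
        if touched != set(self.nodes):
            raise ValueError("network contains isolated nodes; they must be excluded")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        """Unsigned simple graph used for all topology metrics."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        for e in sorted(self.edges, key=lambda e: e.pair):
            g.add_edge(e.genus_a, e.genus_b, rho=e.rho, p=e.p_value)
        return g


@dataclass(frozen=True)
class NetworkSummary:
    """Whole-network statistics: size, clustering, connectivity, density."""

    n_nodes: int
    n_edges: int
    avg_clustering_coefficient: float
    connectivity: float
    density: float


def spearman_matrix(
    table: AbundanceTable, method: str = "t", _min_samples: int = 4
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Pairwise Spearman rho and two-sided p-values between genera.

    Ties receive average ranks.  With ``method="t"`` (default) p-values come
    from the t-distribution approximation t = rho*sqrt((n-2)/(1-rho^2)) on
    n-2 degrees of freedom; ``method="permutation"`` enumerates all rank
    permutations exactly and is only practical for n <= 8.  Constant genera
    yield rho = 0, p = 1 for their pairs.  Returns ``(rho, p, n)`` with the
    diagonal set to rho = 1, p = 0.
    """
    if table.mode is not Mode.RELATIVE:
        raise ValueError("spearman_matrix expects a relative-mode table")
    return spearman_from_values(table.values, table.genera, method, _min_samples)


def spearman_from_values(
    values: np.ndarray,
    genera: list[str],
    method: str = "t",
    _min_samples: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """As :func:`spearman_matrix`, on a bare genus-by-sample value matrix.

    Used when correlating a genus subset of a relative table: subsetting
    must not renormalize the columns (the correlations are defined on the
    abundances relative to the full community), so no table-level
    invariants are imposed here.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    if n < _min_samples:
        raise ValueError(f"need at least {_min_samples} samples, got {n}")
    if values.shape[0] < 2:
        raise ValueError("need at least 2 genera")
    k = len(genera)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        res = stats.spearmanr(values.T)
        rho = np.atleast_2d(res.statistic)
        p = np.atleast_2d(res.pvalue)
    constant = np.array([np.all(v == v[0]) for v in values])
    rho[np.isnan(rho)] = 0.0
    p[np.isnan(p)] = 1.0
    for i in np.flatnonzero(constant):
        rho[i, :] = rho[:, i] = 0.0
        p[i, :] = p[:, i] = 1.0
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)

    if method == "permutation":
        ranks = np.array([stats.rankdata(v) for v in values])
        for i, j in combinations(range(k), 2):
            if constant[i] or constant[j]:
                continue
            p[i, j] = p[j, i] = _exact_permutation_p(ranks[i], ranks[j])
    elif method != "t":
        raise ValueError(f"unknown p-value method {method!r}")

    rho_df = pd.DataFrame(rho, index=genera, columns=genera)
    p_df = pd.DataFrame(p, index=genera, columns=genera)
    return rho_df, p_df, n


def _exact_permutation_p(ranks_a: np.ndarray, ranks_b: np.ndarray) -> float:
    """Two-sided exact permutation p-value for Spearman rho (small n only)."""
    n = len(ranks_a)
    if n > 8:
        raise ValueError("exact permutation p is only supported for n <= 8")

    def rho_of(b: np.ndarray) -> float:
        ca = ranks_a - ranks_a.mean()
        cb = b - b.mean()
        denom = np.sqrt((ca**2).sum() * (cb**2).sum())
        return float((ca * cb).sum() / denom) if denom else 0.0

    observed = abs(rho_of(ranks_b))
    count = total = 0
    for perm in permutations(ranks_b):
        total += 1
        if abs(rho_of(np.array(perm))) >= observed - 1e-12:
            count += 1
    return count / total


def build_network(
    rho: pd.DataFrame,
    p: pd.DataFrame,
    n: int,
    thresholds: Thresholds = Thresholds(),
    state: State = State.HEALTHY,
    bh_correct: bool = False,
) -> CooccurrenceNetwork:
    """Filter the correlation matrices into a network.

    An edge is kept iff |rho| > rho_min (strict) and p < p_max (strict);
    genera with no passing edge are dropped from the node set.  With
    ``bh_correct`` the p-values are Benjamini-Hochberg adjusted across the
    genus pairs before filtering (off by default).
    """
    genera = list(rho.index)
    if list(p.index) != genera or list(rho.columns) != genera or list(p.columns) != genera:
        raise ValueError("rho and p matrices must share the same genus order")
    pairs = list(combinations(range(len(genera)), 2))
    pvals = np.array([p.iat[i, j] for i, j in pairs])
    if bh_correct and pairs:
        from statsmodels.stats.multitest import multipletests

        pvals = multipletests(pvals, method="fdr_bh")[1]
    edges = []
    for (i, j), pv in zip(pairs, pvals):
        r = rho.iat[i, j]
        if abs(r) > thresholds.rho_min and pv < thresholds.p_max:
            edges.append(CorrelationEdge(genera[i], genera[j], float(r), float(pv), n))
    edges.sort(key=lambda e: e.pair)
    nodes = frozenset(g for e in edges for g in e.pair)
    return CooccurrenceNetwork(state, nodes, tuple(edges), thresholds)


def network_from_table(
    table: AbundanceTable,
    thresholds: Thresholds = Thresholds(),
    state: State = State.HEALTHY,
    bh_correct: bool = False,
    p_method: str = "t",
) -> CooccurrenceNetwork:
    """Convenience: Spearman matrix then edge filter on one state table."""
    rho, p, n = spearman_matrix(table, method=p_method)
    return build_network(rho, p, n, thresholds, state, bh_correct)


def summarize_network(net: CooccurrenceNetwork) -> NetworkSummary:
    """Node/edge counts, average clustering coefficient, connectivity, density.

    Connectivity is the average degree 2E/N; density is 2E/(N(N-1)).  The
    average clustering coefficient averages the per-node coefficient over
    all nodes.  An empty network yields an all-zero summary with a warning.
    """
    if net.n_nodes == 0:
        warnings.warn("summarizing an empty network; all statistics are zero")
        return NetworkSummary(0, 0, 0.0, 0.0, 0.0)
    from .topology import node_metrics

    metrics = node_metrics(net)
    avg_cc = float(np.mean([m.clustering_coefficient for m in metrics.values()]))
    n, e = net.n_nodes, net.n_edges
    connectivity = 2.0 * e / n
    density = 2.0 * e / (n * (n - 1)) if n > 1 else 0.0
    return NetworkSummary(n, e, avg_cc, connectivity, density)
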