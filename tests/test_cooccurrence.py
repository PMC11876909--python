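"""Spearman matrices, edge filtering and network summaries."""

import numpy as np
import pandas as pd
import pytest

from sputumnet.containers import AbundanceTable, Mode, State
from sputumnet.cooccurrence import (
    CorrelationEdge,
    Thresholds,
    build_network,
    network_from_table,
    spearman_matrix,
    summarize_network,
)
from conftest import network_from_edges


def relative_table(values, genera=None):
    values = np.asarray(values, dtype=float)
    values = values / values.sum(axis=0, keepdims=True)
    genera = genera or [f"G{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    return AbundanceTable(pd.DataFrame(values, index=genera, columns=samples), Mode.RELATIVE)


class TestSpearmanMatrix:
    def test_monotone_pair_has_rho_one(self):
        x = np.array([1, 2, 3, 4, 5], dtype=float)
        table = relative_table(np.vstack([x, 2 * x, 100 - x]))
        rho, p, n = spearman_matrix(table)
        assert n == 5
        assert rho.loc["G0", "G1"] == pytest.approx(1.0)
        assert rho.loc["G0", "G2"] == pytest.approx(-1.0)

    def test_matches_rank_formula_oracle(self):
        # no-ties case: rho = 1 - 6*sum(d^2)/(n(n^2-1))
        rng = np.random.default_rng(17)
        x = rng.permutation(6).astype(float) + 1
        y = rng.permutation(6).astype(float) + 1
        filler = rng.uniform(1, 2, 6)
        table = relative_table(np.vstack([x, y, filler]))
        rho, _, n = spearman_matrix(table)
        # ranks of relative abundances equal ranks of the raw vectors only
        # when the column sums do not reorder them; rank directly instead.
        from scipy.stats import rankdata

        rel = table.values
        d = rankdata(rel[0]) - rankdata(rel[1])
        expected = 1 - 6 * (d**2).sum() / (n * (n**2 - 1))
        assert rho.loc["G0", "G1"] == pytest.approx(expected, abs=1e-12)

    def test_p_value_matches_t_approximation(self):
        rng = np.random.default_rng(23)
        table = relative_table(rng.uniform(1, 5, size=(3, 20)))
        rho, p, n = spearman_matrix(table)
        from scipy import stats

        r = rho.loc["G0", "G1"]
        t = r * np.sqrt((n - 2) / (1 - r**2))
        expected = 2 * stats.t.sf(abs(t), n - 2)
        assert p.loc["G0", "G1"] == pytest.approx(expected, rel=1e-9)

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(9)
        values = rng.uniform(1, 5, size=(4, 15))
        t1 = relative_table(values)
        perm = rng.permutation(15)
        t2 = relative_table(values[:, perm])
        r1, p1, _ = spearman_matrix(t1)
        r2, p2, _ = spearman_matrix(t2)
        assert np.allclose(r1.values, r2.values, atol=1e-12)
        assert np.allclose(p1.values, p2.values, atol=1e-12)

    def test_too_few_samples_rejected(self):
        table = relative_table(np.ones((3, 3)))
        with pytest.raises(ValueError, match="at least 4 samples"):
            spearman_matrix(table)

    def test_exact_permutation_p_close_to_t_for_strong_signal(self):
        x = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        table = relative_table(np.vstack([x, x + 0.5, 50 - x]))
        _, p_exact, _ = spearman_matrix(table, method="permutation")
        assert p_exact.loc["G0", "G1"] < 0.01


class TestBuildNetwork:
    def _matrices(self, entries):
        genera = sorted({g for pair in entries for g in pair[:2]})
        rho = pd.DataFrame(np.eye(len(genera)), index=genera, columns=genera)
        p = pd.DataFrame(np.zeros((len(genera), len(genera))), index=genera, columns=genera)
        for a, b, r, pv in entries:
            rho.loc[a, b] = rho.loc[b, a] = r
            p.loc[a, b] = p.loc[b, a] = pv
        return rho, p

    def test_rho_below_threshold_excluded(self):
        rho, p = self._matrices([("A", "B", 0.55, 0.001)])
        net = build_network(rho, p, 30)
        assert net.n_edges == 0 and net.n_nodes == 0

    def test_negative_edge_kept_with_sign(self):
        rho, p = self._matrices([("A", "B", -0.70, 0.005)])
        net = build_network(rho, p, 30)
        assert net.n_edges == 1
        assert net.edges[0].sign == -1

    def test_p_above_threshold_excluded(self):
        rho, p = self._matrices([("A", "B", 0.65, 0.02)])
        net = build_network(rho, p, 30)
        assert net.n_edges == 0

    def test_isolated_genera_dropped_from_nodes(self):
        rho, p = self._matrices([("A", "B", 0.9, 0.001), ("C", "D", 0.1, 0.9)])
        net = build_network(rho, p, 30)
        assert net.nodes == frozenset({"A", "B"})

    def test_threshold_monotonicity(self):
        """Raising rho_min or lowering p_max never adds edges."""
        rng = np.random.default_rng(31)
        genera = [f"G{i}" for i in range(8)]
        r = np.clip((lambda m: (m + m.T) / 2)(rng.uniform(-1, 1, (8, 8))), -0.99, 0.99)
        np.fill_diagonal(r, 1.0)
        pv = (lambda m: (m + m.T) / 2)(rng.uniform(0, 0.05, (8, 8)))
        np.fill_diagonal(pv, 0.0)
        rho = pd.DataFrame(r, index=genera, columns=genera)
        p = pd.DataFrame(pv, index=genera, columns=genera)
        base = {e.pair for e in build_network(rho, p, 30, Thresholds(0.3, 0.02)).edges}
        tighter_rho = {e.pair for e in build_network(rho, p, 30, Thresholds(0.5, 0.02)).edges}
        tighter_p = {e.pair for e in build_network(rho, p, 30, Thresholds(0.3, 0.005)).edges}
        assert tighter_rho <= base
        assert tighter_p <= base


class TestSummarizeNetwork:
    def test_triangle(self, triangle_network):
        s = summarize_network(triangle_network)
        assert (s.n_nodes, s.n_edges) == (3, 3)
        assert s.avg_clustering_coefficient == pytest.approx(1.0)
        assert s.connectivity == pytest.approx(2.0)
        assert s.density == pytest.approx(1.0)

    def test_path_of_three(self):
        net = network_from_edges([("A", "B"), ("B", "C")])
        s = summarize_network(net)
        assert s.avg_clustering_coefficient == 0.0
        assert s.connectivity == pytest.approx(4 / 3)

    def test_matches_brute_force_on_random_graphs(self):
        from conftest import random_graph
        from _bruteforce import brute_force_metrics

        rng = np.random.default_rng(77)
        for _ in range(10):
            nodes, edges = random_graph(rng, n_max=10)
            connected = sorted({v for e in edges for v in e})
            if len(connected) < 2:
                continue
            net = network_from_edges(edges)
            s = summarize_network(net)
            bf = brute_force_metrics(connected, edges)
            assert s.n_nodes == len(connected)
            assert s.n_edges == len(edges)
            assert s.avg_clustering_coefficient == pytest.approx(
                np.mean([bf[v]["clustering_coefficient"] for v in connected]), abs=1e-9
            )
            assert s.connectivity == pytest.approx(2 * len(edges) / len(connected))

    def test_empty_network_warns_and_zeroes(self):
        from sputumnet.cooccurrence import CooccurrenceNetwork

        net = CooccurrenceNetwork(State.HEALTHY, frozenset(), ())
        with pytest.warns(UserWarning, match="empty network"):
            s = summarize_network(net)
        assert (s.n_nodes, s.n_edges, s.connectivity) == (0, 0, 0.0)


def test_connectivity_increases_with_planted_connectivity():
    """More planted correlation structure yields more nodes/edges/connectivity."""
    from sputumnet.containers import State
    from sputumnet.synthetic import SyntheticSpec, factor_correlation, generate_state_table
    from sputumnet.preprocess import preprocess_state_table

    genera = [f"G{i:02d}" for i in range(20)]
    states = [State.HEALTHY, State.STABLE, State.EXAC_ONE]
    n_pairs_by_state = {State.HEALTHY: 1, State.STABLE: 4, State.EXAC_ONE: 8}
    corr = {
        s: factor_correlation(
            genera,
            [{genera[2 * k]: 0.95, genera[2 * k + 1]: 0.95} for k in range(npairs)],
        )
        for s, npairs in n_pairs_by_state.items()
    }
    spec = SyntheticSpec(
        genera=genera,
        n_samples_per_state={s: 80 for s in states},
        base_log_abundance=np.zeros(20),
        latent_correlation=corr,
        seed=1234,
    )
    summaries = []
    for s in states:
        table = generate_state_table(spec, s)
        rel, _, _ = preprocess_state_table(table)
        summaries.append(summarize_network(network_from_table(rel, state=s)))
    n_edges = [s.n_edges for s in summaries]
    conn = [s.connectivity for s in summaries]
    assert n_edges[0] < n_edges[1] < n_edges[2]
    assert conn[0] <= conn[1] <= conn[2]
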