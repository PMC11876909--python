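"""Trend screening, correlation-difference tests and the pattern scan."""

import numpy as np
import pandas as pd
import pytest

from sputumnet.containers import AbundanceTable, MAIN_ORDERING, Mode, State, StateOrdering
from sputumnet.diffcorr import (
    PatternConfig,
    abundance_trend,
    correlation_difference_test,
    probiotic_pattern_scan,
    screen_pairs,
    trend_consistent,
    trend_consistent_pairs,
)


def bivariate(rng, n, rho):
    z = rng.standard_normal((n, 2))
    return z[:, 0], rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1]


class TestTrendConsistency:
    def test_strictly_increasing_selected(self):
        assert trend_consistent([0.1, 0.4, 0.7])

    def test_non_monotone_rejected(self):
        assert not trend_consistent([0.5, 0.3, 0.7])

    def test_decreasing_needs_flag(self):
        assert not trend_consistent([0.7, 0.4, 0.1])
        assert trend_consistent([0.7, 0.4, 0.1], direction="decreasing")
        assert trend_consistent([0.7, 0.4, 0.1], direction="any")

    def test_ties_need_non_strict(self):
        assert not trend_consistent([0.1, 0.1, 0.7])
        assert trend_consistent([0.1, 0.1, 0.7], strict=False)

    def test_pairs_match_brute_force(self):
        rng = np.random.default_rng(42)
        ordering = StateOrdering((State.HEALTHY, State.STABLE, State.EXAC_ONE))
        rho_by_state = {}
        for i in range(30):
            seq = rng.uniform(-1, 1, 3)
            rho_by_state[(f"A{i}", f"B{i}")] = dict(zip(ordering, seq))
        selected = set(trend_consistent_pairs(rho_by_state, ordering))
        expected = {
            pair
            for pair, rhos in rho_by_state.items()
            if rhos[State.HEALTHY] < rhos[State.STABLE] < rhos[State.EXAC_ONE]
        }
        assert selected == expected

    def test_missing_state_named(self):
        ordering = StateOrdering((State.HEALTHY, State.STABLE))
        with pytest.raises(ValueError, match="stable"):
            trend_consistent_pairs({("A", "B"): {State.HEALTHY: 0.1}}, ordering)

    def test_selection_invariant_to_genus_relabeling(self):
        rng = np.random.default_rng(10)
        ordering = StateOrdering((State.HEALTHY, State.STABLE, State.EXAC_ONE))
        seqs = {f"P{i}": rng.uniform(-1, 1, 3) for i in range(10)}
        orig = {("A" + k, "B" + k): dict(zip(ordering, v)) for k, v in seqs.items()}
        renamed = {("X" + k, "Y" + k): dict(zip(ordering, v)) for k, v in seqs.items()}
        sel_orig = {k[0][1:] for k in trend_consistent_pairs(orig, ordering)}
        sel_renamed = {k[0][1:] for k in trend_consistent_pairs(renamed, ordering)}
        assert sel_orig == sel_renamed


class TestCorrelationDifferenceTest:
    def test_identical_samples_give_zero_statistic(self):
        rng = np.random.default_rng(1)
        a, b = bivariate(rng, 30, 0.5)
        z, p = correlation_difference_test(a, b, a, b, method="fisher_z")
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_fisher_z_symmetry(self):
        rng = np.random.default_rng(2)
        a1, b1 = bivariate(rng, 40, 0.2)
        a2, b2 = bivariate(rng, 50, 0.8)
        z12, p12 = correlation_difference_test(a1, b1, a2, b2, method="fisher_z")
        z21, p21 = correlation_difference_test(a2, b2, a1, b1, method="fisher_z")
        assert z12 == pytest.approx(-z21)
        assert p12 == pytest.approx(p21)

    def test_constant_vector_rejected(self):
        rng = np.random.default_rng(3)
        a, b = bivariate(rng, 20, 0.1)
        with pytest.raises(ValueError, match="constant"):
            correlation_difference_test(a, b, np.ones(20), b, method="fisher_z")

    def test_planted_difference_detected_by_both_methods(self):
        rng = np.random.default_rng(4)
        a1, b1 = bivariate(rng, 60, 0.0)
        a2, b2 = bivariate(rng, 60, 0.9)
        for method in ("fisher_z", "anova_interaction"):
            _, p = correlation_difference_test(a1, b1, a2, b2, method=method)
            assert p < 0.01, method

    def test_null_difference_usually_not_rejected(self):
        rng = np.random.default_rng(5)
        rejections = 0
        for _ in range(50):
            a1, b1 = bivariate(rng, 50, 0.4)
            a2, b2 = bivariate(rng, 50, 0.4)
            _, p = correlation_difference_test(a1, b1, a2, b2, method="fisher_z")
            rejections += p < 0.01
        assert rejections <= 3


class TestPatternScan:
    def _rho(self, entries, genera):
        rho = pd.DataFrame(np.eye(len(genera)), index=genera, columns=genera)
        for a, b, r in entries:
            rho.loc[a, b] = rho.loc[b, a] = r
        return rho

    GENERA = ["Lactobacillus", "Bifidobacterium", "Neisseria", "Haemophilus", "Rothia"]

    def test_published_threshold_example_pattern_present(self):
        rho = self._rho(
            [
                ("Lactobacillus", "Bifidobacterium", 0.7),
                ("Lactobacillus", "Neisseria", -0.5),
                ("Bifidobacterium", "Haemophilus", -0.45),
            ],
            self.GENERA,
        )
        report = probiotic_pattern_scan(rho)
        assert report.pattern_present
        assert ("Lactobacillus", "Neisseria", -0.5) in report.anti_pairs

    def test_weak_probiotic_pair_breaks_pattern(self):
        rho = self._rho(
            [
                ("Lactobacillus", "Bifidobacterium", 0.55),
                ("Lactobacillus", "Neisseria", -0.5),
                ("Bifidobacterium", "Haemophilus", -0.45),
            ],
            self.GENERA,
        )
        assert not probiotic_pattern_scan(rho).pattern_present

    def test_probiotic_without_pathogen_hit_breaks_pattern(self):
        rho = self._rho(
            [
                ("Lactobacillus", "Bifidobacterium", 0.7),
                ("Lactobacillus", "Neisseria", -0.5),
            ],
            self.GENERA,
        )
        assert not probiotic_pattern_scan(rho).pattern_present

    def test_absent_genus_listed(self):
        genera = ["Lactobacillus", "Neisseria", "Haemophilus"]
        rho = self._rho([], genera)
        report = probiotic_pattern_scan(rho)
        assert report.absent_genera == ("Bifidobacterium",)
        assert not report.pattern_present

    def test_matches_brute_force_threshold_scan(self):
        rng = np.random.default_rng(6)
        cfg = PatternConfig()
        for _ in range(20):
            m = rng.uniform(-1, 1, (5, 5))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 1.0)
            rho = pd.DataFrame(m, index=self.GENERA, columns=self.GENERA)
            report = probiotic_pattern_scan(rho, cfg)
            expected_pos = [
                ("Bifidobacterium", "Lactobacillus", rho.loc["Bifidobacterium", "Lactobacillus"])
            ]
            expected_pos = [t for t in expected_pos if t[2] > cfg.pos_threshold]
            got_pos = [tuple(t) for t in report.probiotic_pairs]
            assert len(got_pos) == len(expected_pos)
            for a, b, r in report.anti_pairs:
                assert a in cfg.probiotic_genera and b in cfg.pathogen_genera
                assert r < -cfg.neg_threshold

    def test_disjoint_sets_enforced(self):
        with pytest.raises(ValueError, match="disjoint"):
            PatternConfig(probiotic_genera={"A"}, pathogen_genera={"A"})


class TestScreenPairs:
    def _cohort(self, rho_by_state, n=60, seed=0):
        rng = np.random.default_rng(seed)
        tables = {}
        for state, rho in rho_by_state.items():
            a, b = bivariate(rng, n, rho)
            filler = rng.standard_normal(n)
            values = np.exp(np.vstack([a, b, filler]))
            values /= values.sum(axis=0, keepdims=True)
            frame = pd.DataFrame(
                values,
                index=["GenusA", "GenusB", "GenusC"],
                columns=[f"{state.value}{j}" for j in range(n)],
            )
            tables[state] = AbundanceTable(frame, Mode.RELATIVE)
        return tables

    def test_planted_increasing_pair_selected_with_significant_transition(self):
        ordering = StateOrdering((State.HEALTHY, State.STABLE, State.EXAC_ONE))
        tables = self._cohort(
            {State.HEALTHY: 0.0, State.STABLE: 0.45, State.EXAC_ONE: 0.9}, n=80
        )
        results = screen_pairs(tables, ordering, method="fisher_z")
        by_pair = {(r.genus_a, r.genus_b): r for r in results}
        target = by_pair[("GenusA", "GenusB")]
        assert target.trend_consistent
        assert target.min_transition_p < 0.01
        assert [s for s, _, _, _ in target.transitions] == [State.HEALTHY, State.STABLE]

    def test_missing_state_table_rejected(self):
        ordering = StateOrdering((State.HEALTHY, State.STABLE))
        with pytest.raises(ValueError, match="missing table"):
            screen_pairs({State.HEALTHY: None}, ordering)


class TestAbundanceTrend:
    def _tables(self, means_by_state, n=20):
        tables = {}
        for state, mean in means_by_state.items():
            other = 1.0 - mean
            frame = pd.DataFrame(
                np.vstack([np.full(n, mean), np.full(n, other)]),
                index=["Target", "Rest"],
                columns=[f"{state.value}{j}" for j in range(n)],
            )
            tables[state] = AbundanceTable(frame, Mode.RELATIVE)
        return tables

    def test_flat_verdict(self):
        ordering = StateOrdering((State.HEALTHY, State.STABLE))
        tables = self._tables({State.HEALTHY: 0.2, State.STABLE: 0.2})
        out = abundance_trend(tables, ["Target"], ordering)
        assert out["Target"]["verdict"] == "flat"

    def test_decreasing_verdict(self):
        ordering = StateOrdering((State.HEALTHY, State.STABLE, State.EXAC_ONE))
        tables = self._tables(
            {State.HEALTHY: 0.4, State.STABLE: 0.3, State.EXAC_ONE: 0.1}
        )
        out = abundance_trend(tables, ["Target"], ordering)
        assert out["Target"]["verdict"] == "decreasing"
        assert out["Target"]["means"][State.EXAC_ONE] == pytest.approx(0.1)

    def test_means_match_column_averages(self):
        rng = np.random.default_rng(7)
        ordering = StateOrdering((State.HEALTHY, State.STABLE))
        tables = {}
        for state in ordering:
            values = rng.dirichlet(np.ones(4), size=15).T
            frame = pd.DataFrame(
                values, index=list("ABCD"), columns=[f"{state.value}{j}" for j in range(15)]
            )
            tables[state] = AbundanceTable(frame, Mode.RELATIVE)
        out = abundance_trend(tables, list("ABCD"), ordering)
        for genus in "ABCD":
            for state in ordering:
                expected = tables[state].data.loc[genus].mean()
                assert out[genus]["means"][state] == pytest.approx(expected, abs=1e-12)
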