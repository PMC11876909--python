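"""Differential correlation across disease states and the probiotic pattern.

Three analyses run on per-state relative-abundance tables:

* trend screening — genus pairs whose Spearman correlation changes
  monotonically along a severity ordering of states;
* correlation-difference testing between two states, either as a
  rank-based linear-model interaction F-test (default: rank(b) ~ rank(a) +
  state + rank(a):state, the ANOVA-style framing of "does the association
  differ by state") or as the Fisher z test on the difference of
  atanh-transformed correlations;
* the probiotic-pathogen pattern scan — a positively correlated probiotic
  pair (default Lactobacillus-Bifidobacterium, rho > 0.6) where each
  probiotic is also negatively correlated (rho < -0.4) with at least one
  configured pathogen (default Neisseria, Haemophilus).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AbundanceTable, Mode, State, StateOrdering
from .cooccurrence import spearman_from_values, spearman_matrix

__all__ = [
    "DiffCorrResult",
    "PatternConfig",
    "PatternReport",
    "trend_consistent",
    "trend_consistent_pairs",
    "correlation_difference_test",
    "screen_pairs",
    "probiotic_pattern_scan",
    "abundance_trend",
]


# -- trend screening -----------------------------------------------------------


def trend_consistent(
    rho_sequence: list[float], direction: str = "increasing", strict: bool = True
) -> bool:
    """Is a correlation sequence monotone along the severity ordering?

    ``direction`` is ``increasing`` (default, the direction of the
    headline probiotic pair), ``decreasing``, or ``any`` (either).
    ``strict`` demands strict monotonicity; otherwise ties are allowed.
    """
    if len(rho_sequence) < 2:
        raise ValueError("need at least two correlations to assess a trend")
    pairs = list(zip(rho_sequence[:-1], rho_sequence[1:]))
    if strict:
        inc = all(b > a for a, b in pairs)
        dec = all(b < a for a, b in pairs)
    else:
        inc = all(b >= a for a, b in pairs)
        dec = all(b <= a for a, b in pairs)
    if direction == "increasing":
        return inc
    if direction == "decreasing":
        return dec
    if direction == "any":
        return inc or dec
    raise ValueError(f"unknown direction {direction!r}")


def trend_consistent_pairs(
    rho_by_state: dict[tuple[str, str], dict[State, float]],
    ordering: StateOrdering,
    direction: str = "increasing",
    strict: bool = True,
) -> list[tuple[str, str]]:
    """Select the genus pairs whose rho sequence is monotone along ``ordering``.

    ``rho_by_state`` maps each (genus_a, genus_b) pair to its per-state
    Spearman correlations; a missing state raises ``ValueError`` naming it.
    """
    selected = []
    for pair, rhos in rho_by_state.items():
        seq = []
        for state in ordering:
            if state not in rhos:
                raise ValueError(f"pair {pair} lacks a correlation for state {state.value}")
            seq.append(rhos[state])
        if trend_consistent(seq, direction=direction, strict=strict):
            selected.append(pair)
    return selected


# -- correlation-difference testing --------------------------------------------


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    return float(stats.spearmanr(x, y).statistic)


def fisher_z_test(
    x_a1: np.ndarray, x_b1: np.ndarray, x_a2: np.ndarray, x_b2: np.ndarray
) -> tuple[float, float]:
    """Fisher z test for a correlation difference between two states.

    Returns ``(statistic, p)`` for z = (atanh(rho_1) - atanh(rho_2)) /
    sqrt(1/(n_1-3) + 1/(n_2-3)) against a two-sided standard normal.
    Correlations are Spearman, matching the network stage.
    """
    r1 = _spearman_rho(x_a1, x_b1)
    r2 = _spearman_rho(x_a2, x_b2)
    n1, n2 = len(x_a1), len(x_a2)
    if n1 < 4 or n2 < 4:
        raise ValueError("fisher_z needs at least 4 samples per state")
    r1 = min(max(r1, -1 + 1e-15), 1 - 1e-15)
    r2 = min(max(r2, -1 + 1e-15), 1 - 1e-15)
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    p = 2 * stats.norm.sf(abs(z))
    return z, float(p)


def anova_interaction_test(
    x_a1: np.ndarray, x_b1: np.ndarray, x_a2: np.ndarray, x_b2: np.ndarray
) -> tuple[float, float]:
    """Rank-based interaction F-test for a correlation difference.

    Abundances of both genera are rank-transformed within each state, then
    the pooled linear model rank(b) ~ rank(a) + state + rank(a):state is
    fitted; the returned p is the F-test of the interaction term (one
    degree of freedom, so F = t^2 of the interaction coefficient).
    """
    import statsmodels.api as sm

    ra1, rb1 = stats.rankdata(x_a1), stats.rankdata(x_b1)
    ra2, rb2 = stats.rankdata(x_a2), stats.rankdata(x_b2)
    # Center ranks within state so slopes are comparable across group sizes.
    ra1 = (ra1 - ra1.mean()) / len(ra1)
    rb1 = (rb1 - rb1.mean()) / len(rb1)
    ra2 = (ra2 - ra2.mean()) / len(ra2)
    rb2 = (rb2 - rb2.mean()) / len(rb2)
    ra = np.concatenate([ra1, ra2])
    rb = np.concatenate([rb1, rb2])
    group = np.concatenate([np.zeros(len(ra1)), np.ones(len(ra2))])
    design = np.column_stack([np.ones_like(ra), ra, group, ra * group])
    fit = sm.OLS(rb, design).fit()
    f = float(fit.tvalues[3] ** 2)
    return f, float(fit.pvalues[3])


def correlation_difference_test(
    x_a1: np.ndarray,
    x_b1: np.ndarray,
    x_a2: np.ndarray,
    x_b2: np.ndarray,
    method: str = "anova_interaction",
) -> tuple[float, float]:
    """Test whether the genus a-genus b correlation differs between states.

    ``(x_a1, x_b1)`` are the two genera's abundance vectors in the first
    state, ``(x_a2, x_b2)`` in the second.  Returns ``(statistic, p)``.
    A constant vector in either state raises ``ValueError`` (its
    correlation is undefined).
    """
    for name, v in (("x_a1", x_a1), ("x_b1", x_b1), ("x_a2", x_a2), ("x_b2", x_b2)):
        v = np.asarray(v, dtype=float)
        if len(v) < 4:
            raise ValueError(f"{name}: need at least 4 samples per state")
        if np.all(v == v[0]):
            raise ValueError(f"{name} is constant; correlation undefined")
    if method == "fisher_z":
        return fisher_z_test(x_a1, x_b1, x_a2, x_b2)
    if method == "anova_interaction":
        return anova_interaction_test(x_a1, x_b1, x_a2, x_b2)
    raise ValueError(f"unknown method {method!r}")


# -- pair-level screening over a cohort ----------------------------------------


@dataclass(frozen=True)
class DiffCorrResult:
    """Per genus-pair screening outcome across an ordered set of states."""

    genus_a: str
    genus_b: str
    rho_by_state: dict[State, tuple[float, int]]
    trend_consistent: bool
    transitions: tuple[tuple[State, State, float, str], ...]

    @property
    def min_transition_p(self) -> float:
        return min((t[2] for t in self.transitions), default=float("nan"))


def screen_pairs(
    tables_by_state: dict[State, AbundanceTable],
    ordering: StateOrdering,
    method: str = "anova_interaction",
    direction: str = "increasing",
    strict: bool = True,
    genera: list[str] | None = None,
) -> list[DiffCorrResult]:
    """Screen every genus pair for a severity-consistent correlation trend.

    For each pair present in every state's table, per-state Spearman
    correlations are computed, monotonicity along ``ordering`` is assessed
    and each consecutive state transition is tested with
    :func:`correlation_difference_test`.  Transition tests that cannot run
    (constant genus in a state) record p = NaN.
    """
    for state in ordering:
        if state not in tables_by_state:
            raise ValueError(f"missing table for state {state.value}")
    shared = set(tables_by_state[ordering.states[0]].genera)
    for state in ordering:
        shared &= set(tables_by_state[state].genera)
    if genera is not None:
        shared &= set(genera)
    shared_sorted = sorted(shared)

    rho_maps: dict[State, pd.DataFrame] = {}
    n_by_state: dict[State, int] = {}
    for state in ordering:
        # Subset without renormalizing: correlations are defined on the
        # abundances relative to the full community.
        sub = tables_by_state[state].data.loc[shared_sorted].to_numpy()
        rho, _, n = spearman_from_values(sub, shared_sorted)
        rho_maps[state] = rho
        n_by_state[state] = n

    results = []
    for a, b in combinations(shared_sorted, 2):
        rho_by_state = {
            state: (float(rho_maps[state].loc[a, b]), n_by_state[state])
            for state in ordering
        }
        seq = [rho_by_state[state][0] for state in ordering]
        consistent = trend_consistent(seq, direction=direction, strict=strict)
        transitions = []
        for s1, s2 in ordering.transitions():
            t1, t2 = tables_by_state[s1], tables_by_state[s2]
            try:
                _, p = correlation_difference_test(
                    t1.data.loc[a].to_numpy(),
                    t1.data.loc[b].to_numpy(),
                    t2.data.loc[a].to_numpy(),
                    t2.data.loc[b].to_numpy(),
                    method=method,
                )
            except ValueError:
                p = float("nan")
            transitions.append((s1, s2, p, method))
        results.append(
            DiffCorrResult(a, b, rho_by_state, consistent, tuple(transitions))
        )
    return results


# -- probiotic-pathogen pattern ------------------------------------------------


@dataclass(frozen=True)
class PatternConfig:
    """Thresholds and genus sets for the probiotic-pathogen pattern scan."""

    probiotic_genera: frozenset[str] = frozenset({"Lactobacillus", "Bifidobacterium"})
    pathogen_genera: frozenset[str] = frozenset({"Neisseria", "Haemophilus"})
    pos_threshold: float = 0.6
    neg_threshold: float = 0.4

    def __post_init__(self) -> None:
        object.__setattr__(self, "probiotic_genera", frozenset(self.probiotic_genera))
        object.__setattr__(self, "pathogen_genera", frozenset(self.pathogen_genera))
        if self.probiotic_genera & self.pathogen_genera:
            raise ValueError("probiotic and pathogen sets must be disjoint")
        for name in ("pos_threshold", "neg_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass(frozen=True)
class PatternReport:
    """Outcome of the probiotic-pathogen pattern scan in one state."""

    state: State
    probiotic_pairs: tuple[tuple[str, str, float], ...]
    anti_pairs: tuple[tuple[str, str, float], ...]
    absent_genera: tuple[str, ...]
    pattern_present: bool


def probiotic_pattern_scan(
    rho: pd.DataFrame,
    config: PatternConfig = PatternConfig(),
    state: State = State.EXAC_ONE,
) -> PatternReport:
    """Scan a Spearman matrix for the probiotic-pair / pathogen pattern.

    Reports (i) probiotic-probiotic pairs with rho > ``pos_threshold``,
    (ii) probiotic-pathogen pairs with rho < -``neg_threshold``, and
    (iii) the verdict: at least one pair from (i) AND every present
    probiotic anti-correlated with at least one pathogen.  Configured
    genera absent from the matrix are listed and excluded from the verdict.
    """
    available = set(rho.index)
    probiotics = sorted(config.probiotic_genera & available)
    pathogens = sorted(config.pathogen_genera & available)
    absent = tuple(sorted((config.probiotic_genera | config.pathogen_genera) - available))

    probiotic_pairs = []
    for a, b in combinations(probiotics, 2):
        r = float(rho.loc[a, b])
        if r > config.pos_threshold:
            probiotic_pairs.append((a, b, r))
    anti_pairs = []
    for a in probiotics:
        for b in pathogens:
            r = float(rho.loc[a, b])
            if r < -config.neg_threshold:
                anti_pairs.append((a, b, r))

    hit_probiotics = {a for a, _, _ in anti_pairs}
    present = (
        len(probiotics) >= 2
        and bool(probiotic_pairs)
        and bool(pathogens)
        and all(p in hit_probiotics for p in probiotics)
    )
    return PatternReport(
        state=state,
        probiotic_pairs=tuple(probiotic_pairs),
        anti_pairs=tuple(anti_pairs),
        absent_genera=absent,
        pattern_present=present,
    )


# -- abundance trends ----------------------------------------------------------


def abundance_trend(
    tables_by_state: dict[State, AbundanceTable],
    genera: list[str],
    ordering: StateOrdering,
) -> dict[str, dict]:
    """Per-state mean relative abundance and a monotonicity verdict.

    For each genus the per-state mean relative abundance is computed along
    ``ordering`` and classified as ``increasing``, ``decreasing``, ``flat``
    or ``mixed`` (non-strict monotonicity; ``flat`` means all means equal).
    A genus absent from a state's table contributes mean 0 there.
    """
    for state in ordering:
        if state not in tables_by_state:
            raise ValueError(f"missing table for state {state.value}")
        if tables_by_state[state].mode is not Mode.RELATIVE:
            raise ValueError("abundance_trend needs relative-mode tables")
    out: dict[str, dict] = {}
    for genus in genera:
        means = {}
        for state in ordering:
            table = tables_by_state[state]
            if genus in table.data.index and table.n_samples:
                means[state] = float(table.data.loc[genus].mean())
            else:
                means[state] = 0.0
        seq = [means[s] for s in ordering]
        pairs = list(zip(seq[:-1], seq[1:]))
        if all(b == a for a, b in pairs):
            verdict = "flat"
        elif all(b >= a for a, b in pairs):
            verdict = "increasing"
        elif all(b <= a for a, b in pairs):
            verdict = "decreasing"
        else:
            verdict = "mixed"
        out[genus] = {"means": means, "verdict": verdict}
    return out
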