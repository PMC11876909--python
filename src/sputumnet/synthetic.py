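"""Synthetic multi-state genus-count cohorts with planted structure.

The generator emulates genus-level 16S sputum tables: for each sample a
latent Gaussian vector is drawn with a state-specific correlation matrix,
mapped through a softmax to a composition (logistic-normal), thinned by
per-genus dropout (zero inflation) with renormalization, and finally
converted to counts by a multinomial draw at a sequencing depth sampled
uniformly from a range.  Planted pairwise latent correlations, planted
core genera and a planted anaerobic hub give every downstream stage a
known ground truth, so the whole pipeline is testable without any
sequencing download.

Correlation matrices are conveniently built from factor loadings
(:func:`factor_correlation`), which guarantees positive semi-definiteness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AbundanceTable, Mode, SampleMetadata, State

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "factor_correlation",
    "generate_state_table",
    "generate_cohort",
    "demo_cohort_spec",
    "write_cohort",
]

#: Canonical state order used to derive per-state random substreams.
_STATE_RANK = {s: i for i, s in enumerate(State)}


def _validate_correlation(c: np.ndarray, n: int, label: str) -> None:
    if c.shape != (n, n):
        raise ValueError(f"{label}: correlation matrix must be {n}x{n}, got {c.shape}")
    if not np.allclose(c, c.T, atol=1e-10):
        raise ValueError(f"{label}: correlation matrix is not symmetric")
    if not np.allclose(np.diag(c), 1.0, atol=1e-10):
        raise ValueError(f"{label}: correlation matrix diagonal must be 1")
    eigvals = np.linalg.eigvalsh(c)
    if eigvals.min() < -1e-8:
        raise ValueError(
            f"{label}: correlation matrix is not positive semi-definite "
            f"(min eigenvalue {eigvals.min():.3g})"
        )


@dataclass
class SyntheticSpec:
    """Full specification of a synthetic multi-state cohort.

    Parameters
    ----------
    genera
        Genus names, shared by every state.
    n_samples_per_state
        Samples to draw per state (0 allowed: empty table, full genus list).
    base_log_abundance
        Mean of the latent Gaussian per genus (softmax of this vector is
        roughly the expected composition).
    latent_correlation
        Per-state genus-by-genus correlation matrix of the latent Gaussian
        (symmetric, unit diagonal, eigenvalues >= -1e-8).
    depth_range
        Inclusive (min, max) sequencing depth; depths are uniform integers.
    zero_inflation
        Per-genus dropout probability in [0, 1); dropout zeroes the genus
        pre-multinomial and renormalizes the composition.
    state_log_offset
        Optional per-state additive shift of the latent mean, used to plant
        abundance trends across severity; defaults to zero.
    seed
        Base seed; every (spec, seed) pair reproduces byte-identical tables.
    """

    genera: list[str]
    n_samples_per_state: dict[State, int]
    base_log_abundance: np.ndarray
    latent_correlation: dict[State, np.ndarray]
    depth_range: tuple[int, int] = (5000, 20000)
    zero_inflation: np.ndarray | float = 0.0
    state_log_offset: dict[State, np.ndarray] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.genera)
        if n == 0 or len(set(self.genera)) != n:
            raise ValueError("genera must be non-empty and unique")
        self.base_log_abundance = np.asarray(self.base_log_abundance, dtype=float)
        if self.base_log_abundance.shape != (n,):
            raise ValueError("base_log_abundance must have one entry per genus")
        if np.isscalar(self.zero_inflation) or np.ndim(self.zero_inflation) == 0:
            self.zero_inflation = np.full(n, float(self.zero_inflation))
        self.zero_inflation = np.asarray(self.zero_inflation, dtype=float)
        if self.zero_inflation.shape != (n,):
            raise ValueError("zero_inflation must be scalar or one entry per genus")
        if ((self.zero_inflation < 0) | (self.zero_inflation >= 1)).any():
            raise ValueError("zero_inflation probabilities must be in [0, 1)")
        dmin, dmax = self.depth_range
        if dmin < 1 or dmax < dmin:
            raise ValueError("depth_range must satisfy 1 <= min <= max")
        self.n_samples_per_state = {
            State(s): int(k) for s, k in self.n_samples_per_state.items()
        }
        if any(k < 0 for k in self.n_samples_per_state.values()):
            raise ValueError("n_samples_per_state values must be >= 0")
        self.latent_correlation = {
            State(s): np.asarray(c, dtype=float) for s, c in self.latent_correlation.items()
        }
        for state in self.n_samples_per_state:
            if state not in self.latent_correlation:
                raise ValueError(f"no latent_correlation for state {state.value}")
            _validate_correlation(self.latent_correlation[state], n, state.value)
        if self.state_log_offset is not None:
            self.state_log_offset = {
                State(s): np.asarray(v, dtype=float)
                for s, v in self.state_log_offset.items()
            }
            for state, v in self.state_log_offset.items():
                if v.shape != (n,):
                    raise ValueError(f"state_log_offset[{state.value}] has wrong length")

    @property
    def n_genera(self) -> int:
        return len(self.genera)

    def offset(self, state: State) -> np.ndarray:
        if self.state_log_offset and state in self.state_log_offset:
            return self.state_log_offset[state]
        return np.zeros(self.n_genera)


@dataclass(frozen=True)
class GroundTruth:
    """Planted facts derivable from a :class:`SyntheticSpec`."""

    planted_edges: dict[State, frozenset[tuple[str, str]]]
    edge_strength: float
    core_genera: frozenset[str]
    anaerobe_labels: dict[str, str]


def factor_correlation(
    genera: list[str], factors: list[dict[str, float]]
) -> np.ndarray:
    """Build a PSD correlation matrix from factor loadings.

    Each factor maps genus name -> loading; the implied correlation is
    C = L L^T off the diagonal with unit diagonal (residual variances
    absorb the remainder), which is positive semi-definite as long as each
    genus's squared loadings sum to at most 1.
    """
    n = len(genera)
    index = {g: i for i, g in enumerate(genera)}
    loadings = np.zeros((n, len(factors)))
    for f, factor in enumerate(factors):
        for genus, lam in factor.items():
            if genus not in index:
                raise ValueError(f"factor references unknown genus {genus!r}")
            loadings[index[genus], f] = lam
    communality = (loadings**2).sum(axis=1)
    if (communality > 1 + 1e-12).any():
        bad = [genera[i] for i in np.flatnonzero(communality > 1 + 1e-12)]
        raise ValueError(f"squared factor loadings exceed 1 for: {bad}")
    c = loadings @ loadings.T
    np.fill_diagonal(c, 1.0)
    return c


def _state_rng(spec: SyntheticSpec, state: State) -> np.random.Generator:
    return np.random.default_rng([spec.seed, _STATE_RANK[state]])


def _correlation_transform(c: np.ndarray) -> np.ndarray:
    """Matrix L with L L^T = C, valid for singular PSD matrices."""
    w, v = np.linalg.eigh(c)
    return v * np.sqrt(np.clip(w, 0.0, None))


def generate_state_table(spec: SyntheticSpec, state: State) -> AbundanceTable:
    """Draw one state's genus-by-sample count table.

    Per sample: latent z ~ N(base + offset, correlation), composition
    p = softmax(z), per-genus dropout with renormalization (skipped in the
    degenerate case where every genus drops out), depth ~ U{depth_range},
    counts ~ Multinomial(depth, p).  Deterministic given the spec seed.
    """
    state = State(state)
    if state not in spec.n_samples_per_state:
        raise ValueError(f"state {state.value} not present in the spec")
    n = spec.n_genera
    k = spec.n_samples_per_state[state]
    rng = _state_rng(spec, state)
    transform = _correlation_transform(spec.latent_correlation[state])
    mean = spec.base_log_abundance + spec.offset(state)
    dmin, dmax = spec.depth_range

    counts = np.zeros((n, k))
    for j in range(k):
        z = mean + transform @ rng.standard_normal(n)
        z = z - z.max()
        p = np.exp(z)
        p /= p.sum()
        drop = rng.random(n) < spec.zero_inflation
        if not drop.all():
            p = np.where(drop, 0.0, p)
            p /= p.sum()
        depth = int(rng.integers(dmin, dmax + 1))
        counts[:, j] = rng.multinomial(depth, p)

    columns = [f"{state.value}_s{j + 1:03d}" for j in range(k)]
    frame = pd.DataFrame(counts, index=list(spec.genera), columns=columns)
    return AbundanceTable(frame, Mode.COUNTS)


def _derive_ground_truth(spec: SyntheticSpec, edge_strength: float) -> GroundTruth:
    planted: dict[State, frozenset[tuple[str, str]]] = {}
    for state, c in spec.latent_correlation.items():
        pairs = set()
        for i in range(spec.n_genera):
            for j in range(i + 1, spec.n_genera):
                if abs(c[i, j]) >= edge_strength:
                    a, b = sorted((spec.genera[i], spec.genera[j]))
                    pairs.add((a, b))
        planted[state] = frozenset(pairs)

    # A genus is designed-core when its expected share clears the 0.001
    # abundance cutoff with a 4x margin in every populated state (the
    # latent log-normal has unit variance, so a 4x margin keeps downward
    # swings below the cutoff rare) and dropout is low enough that the
    # >70% prevalence rule cannot be missed by sampling noise.
    core = set()
    states = [s for s, k in spec.n_samples_per_state.items() if k > 0]
    for i, genus in enumerate(spec.genera):
        ok = bool(states)
        for state in states:
            mean = spec.base_log_abundance + spec.offset(state)
            share = float(np.exp(mean[i]) / np.exp(mean).sum())
            if share < 0.004:
                ok = False
        if ok and spec.zero_inflation[i] <= 0.1:
            core.add(genus)

    from .keystone import default_registry

    registry = default_registry()
    labels = {g: registry.oxygen_class(g) for g in spec.genera}
    return GroundTruth(planted, edge_strength, frozenset(core), labels)


def generate_cohort(
    spec: SyntheticSpec, edge_strength: float = 0.6
) -> tuple[dict[State, AbundanceTable], GroundTruth]:
    """Generate one table per state plus the planted ground truth.

    Tables share the genus list; ``edge_strength`` declares the latent
    |correlation| at or above which a pair counts as a planted edge.
    """
    tables = {
        state: generate_state_table(spec, state)
        for state in spec.n_samples_per_state
    }
    return tables, _derive_ground_truth(spec, edge_strength)


def cohort_metadata(tables: dict[State, AbundanceTable]) -> list[SampleMetadata]:
    """Metadata rows (sample, state, depth) for a generated cohort."""
    records = []
    for state, table in tables.items():
        sums = table.data.sum(axis=0)
        for sample in table.samples:
            records.append(SampleMetadata(sample, state, int(sums[sample])))
    return records


def write_cohort(
    tables: dict[State, AbundanceTable],
    truth: GroundTruth,
    outdir: str | PathLike,
) -> list[Path]:
    """Write per-state abundance TSVs, a metadata TSV and ground-truth TSVs."""
    from .tables_io import write_abundance_table, write_metadata

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for state in sorted(tables, key=lambda s: _STATE_RANK[s]):
        path = outdir / f"abundance_{state.value}.tsv"
        write_abundance_table(tables[state], path)
        written.append(path)
    meta_path = outdir / "metadata.tsv"
    write_metadata(cohort_metadata(tables), meta_path)
    written.append(meta_path)

    edge_rows = []
    for state in sorted(truth.planted_edges, key=lambda s: _STATE_RANK[s]):
        for a, b in sorted(truth.planted_edges[state]):
            edge_rows.append({"state": state.value, "genus_a": a, "genus_b": b})
    edges_path = outdir / "truth_planted_edges.tsv"
    pd.DataFrame(edge_rows, columns=["state", "genus_a", "genus_b"]).to_csv(
        edges_path, sep="\t", index=False
    )
    written.append(edges_path)

    core_path = outdir / "truth_core_genera.tsv"
    pd.DataFrame({"genus": sorted(truth.core_genera)}).to_csv(
        core_path, sep="\t", index=False
    )
    written.append(core_path)

    oxy_path = outdir / "truth_oxygen_labels.tsv"
    pd.DataFrame(
        [{"genus": g, "oxygen_class": c} for g, c in sorted(truth.anaerobe_labels.items())],
        columns=["genus", "oxygen_class"],
    ).to_csv(oxy_path, sep="\t", index=False)
    written.append(oxy_path)
    return written


def edge_recovery_spec(
    seed: int = 0,
    n_samples: int = 100,
    n_genera: int = 30,
    n_planted_pairs: int = 10,
    latent_rho: float = 0.9,
    state: State = State.STABLE,
) -> tuple[SyntheticSpec, frozenset[tuple[str, str]]]:
    """Benchmark spec for planted-edge recovery: paired factors + null genera.

    The first ``2 * n_planted_pairs`` genera form disjoint pairs with latent
    correlation ``latent_rho``; the rest are uncorrelated.  All genera share
    the same base abundance.  Dropout (0.2) is planted only on the null
    genera: independent dropout on a correlated genus sends ~2x its rate of
    samples to arbitrary ranks and would measure the dropout rate rather
    than correlation recovery, and in real tables the reliably detected
    genera are the ones whose correlations are measurable at all.
    Returns the spec and the planted pair set.
    """
    if 2 * n_planted_pairs > n_genera:
        raise ValueError("need n_genera >= 2 * n_planted_pairs")
    genera = [f"G{i:02d}" for i in range(n_genera)]
    loading = float(np.sqrt(abs(latent_rho)))
    factors = [
        {genera[2 * k]: loading, genera[2 * k + 1]: loading * np.sign(latent_rho)}
        for k in range(n_planted_pairs)
    ]
    corr = factor_correlation(genera, factors)
    dropout = np.zeros(n_genera)
    dropout[2 * n_planted_pairs:] = 0.2
    spec = SyntheticSpec(
        genera=genera,
        n_samples_per_state={state: n_samples},
        base_log_abundance=np.zeros(n_genera),
        latent_correlation={state: corr},
        zero_inflation=dropout,
        seed=seed,
    )
    planted = frozenset(
        (genera[2 * k], genera[2 * k + 1]) for k in range(n_planted_pairs)
    )
    return spec, planted


# -- the demo cohort -----------------------------------------------------------

#: Expected composition of the demo community (softmax-normalized).  Values
#: follow the rank-abundance profile typical of sputum genus tables: a few
#: dominant commensals, a mid tail, and rare genera subject to dropout.
_DEMO_PROFILE: list[tuple[str, float, float]] = [
    # (genus, expected share before normalization, dropout probability)
    # Abundant community members are effectively always detected in real
    # sputum tables; biological dropout concentrates in the rare tail.
    ("Streptococcus", 0.15, 0.00),
    ("Prevotella", 0.12, 0.00),
    ("Veillonella", 0.10, 0.00),
    ("Rothia", 0.06, 0.00),
    ("Neisseria", 0.05, 0.00),
    ("Haemophilus", 0.05, 0.00),
    ("Actinomyces", 0.04, 0.00),
    ("Fusobacterium", 0.03, 0.05),
    ("Leptotrichia", 0.02, 0.05),
    ("Porphyromonas", 0.02, 0.05),
    ("Lactobacillus", 0.015, 0.00),
    ("Bifidobacterium", 0.012, 0.00),
    ("Parvimonas", 0.015, 0.00),
    ("Moraxella", 0.02, 0.00),
    ("Corynebacterium", 0.015, 0.00),
    ("Kingella", 0.01, 0.00),
    ("Pseudomonas", 0.01, 0.00),
    ("Acinetobacter", 0.01, 0.00),
    ("Stenotrophomonas", 0.01, 0.00),
    ("Campylobacter", 0.008, 0.20),
    ("Capnocytophaga", 0.006, 0.20),
    ("Selenomonas", 0.005, 0.25),
    ("Aggregatibacter", 0.004, 0.30),
    ("Oribacterium", 0.003, 0.30),
    ("Atopobium", 0.002, 0.40),
    ("Tannerella", 0.0015, 0.40),
    ("Megasphaera", 0.001, 0.50),
    ("Dialister", 0.0008, 0.50),
    ("Moryella", 0.0004, 0.60),
    ("Treponema", 0.0002, 0.60),
]

#: Latent Lactobacillus-Bifidobacterium correlation per state: the planted
#: probiotic-pair association strengthens with severity.
_DEMO_PROBIOTIC_RHO = {
    State.HEALTHY: 0.0,
    State.STABLE: 0.45,
    State.EXAC_ONE: 0.85,
    State.EXAC_MULTI: 0.95,
}
#: Pathogen loading against the probiotic factor in exacerbation states.
#: Compositional closure attenuates negative associations between
#: proportions, so the latent anti-correlation (about -0.8) is planted
#: well below the -0.4 detection threshold it must reach after closure.
_DEMO_PATHOGEN_LOADING = {
    State.HEALTHY: 0.0,
    State.STABLE: 0.0,
    State.EXAC_ONE: -0.9,
    State.EXAC_MULTI: -0.9,
}

#: Planted anaerobic hub (exac_multi only): Parvimonas is the factor itself,
#: three tight spokes and three looser spokes, all strict aerobes, so only
#: the hub can satisfy the keystone anaerobe criterion.
_DEMO_HUB = "Parvimonas"
_DEMO_HUB_SPOKES = {
    "Moraxella": 0.85,
    "Corynebacterium": 0.85,
    "Kingella": 0.85,
    "Pseudomonas": 0.70,
    "Acinetobacter": 0.70,
    "Stenotrophomonas": 0.70,
}


def demo_cohort_spec(seed: int = 0, n_per_state: int = 100) -> SyntheticSpec:
    """The planted demonstration cohort used by the end-to-end pipeline demo.

    30 genera, ``n_per_state`` samples in each of the four main severity
    states, depth uniform in [5000, 20000].  Planted structure:

    * a strong Prevotella-Veillonella association (latent 0.9) in every
      state and a Streptococcus-Rothia association (latent 0.81) in the
      disease states, so network size grows with severity;
    * a probiotic pair whose latent correlation rises with severity
      (0 -> 0.45 -> 0.85 -> 0.95) and pathogen anti-correlations around
      -0.6 in the exacerbation states (the probiotic-pathogen pattern);
    * an anaerobic hub genus (Parvimonas) wired to six aerobic spokes in
      the multiple-exacerbation state only, making it an exclusive
      keystone there;
    * probiotic abundances that fall, and pathogen abundances that rise,
      with severity.
    """
    genera = [g for g, _, _ in _DEMO_PROFILE]
    base = np.log([share for _, share, _ in _DEMO_PROFILE])
    dropout = np.array([z for _, _, z in _DEMO_PROFILE])

    states = [State.HEALTHY, State.STABLE, State.EXAC_ONE, State.EXAC_MULTI]
    correlation: dict[State, np.ndarray] = {}
    for state in states:
        factors: list[dict[str, float]] = [
            {"Prevotella": 0.95, "Veillonella": 0.95},
        ]
        if state is not State.HEALTHY:
            factors.append({"Streptococcus": 0.9, "Rothia": 0.9})
        a = float(np.sqrt(_DEMO_PROBIOTIC_RHO[state]))
        c = _DEMO_PATHOGEN_LOADING[state]
        if a > 0 or c != 0:
            factors.append(
                {
                    "Lactobacillus": a,
                    "Bifidobacterium": a,
                    "Neisseria": c,
                    "Haemophilus": c,
                }
            )
        if state is State.EXAC_MULTI:
            factors.append({_DEMO_HUB: 1.0, **_DEMO_HUB_SPOKES})
        correlation[state] = factor_correlation(genera, factors)

    index = {g: i for i, g in enumerate(genera)}
    offsets = {}
    probiotic_shift = {
        State.HEALTHY: 0.7, State.STABLE: 0.0,
        State.EXAC_ONE: -0.5, State.EXAC_MULTI: -1.0,
    }
    pathogen_shift = {
        State.HEALTHY: -0.7, State.STABLE: 0.0,
        State.EXAC_ONE: 0.4, State.EXAC_MULTI: 0.8,
    }
    for state in states:
        off = np.zeros(len(genera))
        for g in ("Lactobacillus", "Bifidobacterium"):
            off[index[g]] = probiotic_shift[state]
        for g in ("Neisseria", "Haemophilus"):
            off[index[g]] = pathogen_shift[state]
        offsets[state] = off

    return SyntheticSpec(
        genera=genera,
        n_samples_per_state={s: n_per_state for s in states},
        base_log_abundance=base,
        latent_correlation=correlation,
        depth_range=(5000, 20000),
        zero_inflation=dropout,
        state_log_offset=offsets,
        seed=seed,
    )
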