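"""Sample/genus filtering, relative abundance, core microbiome, Shannon index.

The pipeline applies, per disease state: a minimum sequencing-depth sample
filter (default: drop samples with fewer than 5000 reads), a zero-inflation
genus filter (drop genera absent from more than 70% of samples), conversion
to relative abundance, and the core-microbiome rule (a genus is core when
its relative abundance is at least 0.001 in more than 70% of samples).
Boundary strictness follows the rules' wording: "fewer than 5000" and
"more than 70%" are strict; the 0.001 abundance cutoff is inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AbundanceTable, Mode, State

__all__ = [
    "FilterConfig",
    "CoreMicrobiomeResult",
    "filter_samples",
    "filter_zero_inflated",
    "to_relative",
    "core_microbiome",
    "shared_core",
    "shannon_diversity",
    "preprocess_state_table",
]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the sample, zero-inflation and core-microbiome rules."""

    min_reads_per_sample: int = 5000
    max_zero_prevalence: float = 0.70
    core_min_rel_abundance: float = 0.001
    core_min_prevalence: float = 0.70

    def __post_init__(self) -> None:
        if self.min_reads_per_sample < 0:
            raise ValueError("min_reads_per_sample must be >= 0")
        for name in ("max_zero_prevalence", "core_min_rel_abundance", "core_min_prevalence"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass(frozen=True)
class CoreMicrobiomeResult:
    """Core-microbiome verdict for one state.

    ``prevalence`` maps every genus to the fraction of samples where its
    relative abundance meets the ``core_min_rel_abundance`` cutoff;
    ``core_genera`` keeps the genera whose prevalence strictly exceeds
    ``core_min_prevalence``, ordered by prevalence descending (ties by name).
    """

    state: State | None
    core_genera: tuple[str, ...]
    prevalence: dict[str, float]


def filter_samples(table: AbundanceTable, config: FilterConfig = FilterConfig()) -> AbundanceTable:
    """Drop samples whose total read count is below the depth threshold.

    Strict reading of the rule: a sample is excluded when its column sum is
    *fewer than* ``min_reads_per_sample``; a sum exactly at the threshold is
    retained.  Requires a counts-mode table (relative tables carry no depth).
    """
    if table.mode is not Mode.COUNTS:
        raise ValueError("filter_samples needs a counts-mode table (read totals unavailable)")
    sums = table.data.sum(axis=0)
    keep = [s for s in table.samples if sums[s] >= config.min_reads_per_sample]
    return AbundanceTable(table.data.loc[:, keep].copy(), table.mode)


def filter_zero_inflated(
    table: AbundanceTable, config: FilterConfig = FilterConfig()
) -> AbundanceTable:
    """Drop genera whose zero fraction strictly exceeds ``max_zero_prevalence``.

    A genus observed as zero in exactly the threshold fraction of samples
    (e.g. 70%) is retained.  No-sample tables pass through unchanged.
    """
    if table.n_samples == 0:
        return table.copy()
    zero_frac = (table.data.to_numpy() == 0).mean(axis=1)
    keep = [g for g, zf in zip(table.genera, zero_frac) if zf <= config.max_zero_prevalence]
    return AbundanceTable(table.data.loc[keep].copy(), table.mode)


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Divide each sample column by its total; mode becomes ``relative``.

    Raises ``ValueError`` naming the first all-zero sample, for which a
    relative composition is undefined.
    """
    if table.mode is Mode.RELATIVE:
        return table.copy()
    sums = table.data.sum(axis=0)
    zero = [s for s in table.samples if sums[s] == 0]
    if zero:
        raise ValueError(f"cannot normalize all-zero sample column {zero[0]!r}")
    return AbundanceTable(table.data.div(sums, axis=1), Mode.RELATIVE)


def core_microbiome(
    table: AbundanceTable,
    config: FilterConfig = FilterConfig(),
    state: State | None = None,
) -> CoreMicrobiomeResult:
    """Apply the core-microbiome rule to a relative-abundance table.

    A genus is core iff its relative abundance is >= ``core_min_rel_abundance``
    in strictly more than ``core_min_prevalence`` of the samples.  The
    prevalence map is reported for every genus, core or not.
    """
    if table.mode is not Mode.RELATIVE:
        raise ValueError("core_microbiome needs a relative-mode table")
    if table.n_samples == 0:
        prevalence = {g: 0.0 for g in table.genera}
        return CoreMicrobiomeResult(state, (), prevalence)
    hits = (table.data.to_numpy() >= config.core_min_rel_abundance).mean(axis=1)
    prevalence = {g: float(p) for g, p in zip(table.genera, hits)}
    core = [g for g in table.genera if prevalence[g] > config.core_min_prevalence]
    core.sort(key=lambda g: (-prevalence[g], g))
    return CoreMicrobiomeResult(state, tuple(core), prevalence)


def shared_core(results: list[CoreMicrobiomeResult]) -> tuple[str, ...]:
    """Intersect core sets across states, ordered by mean prevalence descending.

    Ties break lexicographically.  Raises on an empty input list.
    """
    if not results:
        raise ValueError("shared_core needs at least one CoreMicrobiomeResult")
    common = set(results[0].core_genera)
    for res in results[1:]:
        common &= set(res.core_genera)

    def mean_prev(g: str) -> float:
        return float(np.mean([res.prevalence.get(g, 0.0) for res in results]))

    return tuple(sorted(common, key=lambda g: (-mean_prev(g), g)))


def shannon_diversity(table: AbundanceTable) -> dict[str, float]:
    """Shannon alpha diversity per sample, in bits (log base 2).

    H(sample) = -sum_i p_i log2 p_i over the genera with p_i > 0, so a
    single-genus sample scores 0 and a uniform community over n genera
    scores log2(n).
    """
    if table.mode is not Mode.RELATIVE:
        raise ValueError("shannon_diversity needs a relative-mode table")
    out: dict[str, float] = {}
    values = table.data.to_numpy()
    for j, sample in enumerate(table.samples):
        p = values[:, j]
        p = p[p > 0]
        out[sample] = float(-(p * np.log2(p)).sum()) if p.size else 0.0
    return out


def preprocess_state_table(
    table: AbundanceTable,
    config: FilterConfig = FilterConfig(),
    state: State | None = None,
) -> tuple[AbundanceTable, CoreMicrobiomeResult, dict[str, float]]:
    """Run the standard per-state chain and return its three products.

    Order: depth filter -> zero-inflation filter -> relative abundance ->
    core microbiome; Shannon diversity is computed on the relative table.
    Returns ``(relative_table, core_result, shannon_by_sample)``.
    """
    counts = filter_samples(table, config)
    counts = filter_zero_inflated(counts, config)
    rel = to_relative(counts) if counts.n_samples else AbundanceTable(counts.data, Mode.RELATIVE)
    core = core_microbiome(rel, config, state)
    shannon = shannon_diversity(rel)
    return rel, core, shannon
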