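"""End-to-end pipeline: filters -> networks -> keystones -> differential
correlation -> probiotic pattern, with a flat key=value configuration and a
machine-readable run manifest.

Every output file is a pure function of the inputs plus the configuration
(no timestamps, sorted orders throughout), so a rerun with the same config
and seed reproduces a byte-identical result bundle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path

import pandas as pd

from . import __version__
from .containers import (
    AbundanceTable,
    MAIN_ORDERING,
    SampleMetadata,
    State,
    StateOrdering,
    parse_state,
    split_by_state,
)
from .cooccurrence import (
    CooccurrenceNetwork,
    Thresholds,
    network_from_table,
    spearman_matrix,
    summarize_network,
)
from .diffcorr import (
    DiffCorrResult,
    PatternConfig,
    PatternReport,
    abundance_trend,
    probiotic_pattern_scan,
    screen_pairs,
)
from .keystone import (
    KeystoneRecord,
    KeystoneThresholds,
    OxygenRegistry,
    classify_keystones,
    default_registry,
    exclusive_keystones,
    keystone_frame,
)
from .preprocess import FilterConfig, CoreMicrobiomeResult, preprocess_state_table, shared_core
from .tables_io import write_abundance_table, write_edge_list, write_network_graphml
from .topology import node_metrics

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "report"]

_STATE_RANK = {s: i for i, s in enumerate(State)}


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable threshold of the pipeline, with published defaults.

    Defaults reproduce the printed panel: 5000-read sample filter, 70%
    zero-inflation filter, core rule (0.001 in >70%), edge filter
    (|rho| > 0.6, p < 0.01), keystone panel (degree > 2, CC >= 0,
    closeness > 0.3, TC > 0.3, betweenness > 0) and pattern thresholds
    (0.6 positive, 0.4 negative).
    """

    filters: FilterConfig = field(default_factory=FilterConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    keystone_thresholds: KeystoneThresholds = field(default_factory=KeystoneThresholds)
    pattern: PatternConfig = field(default_factory=PatternConfig)
    ordering: StateOrdering = MAIN_ORDERING
    registry_path: str | None = None
    diffcorr_method: str = "anova_interaction"
    trend_direction: str = "increasing"
    trend_strict: bool = True
    bh_correct: bool = False
    seed: int = 0

    def registry(self) -> OxygenRegistry:
        if self.registry_path:
            return OxygenRegistry.from_tsv(self.registry_path)
        return default_registry()

    # -- flat key=value serialization -----------------------------------------

    def to_flat(self) -> dict[str, str]:
        return {
            "min_reads_per_sample": str(self.filters.min_reads_per_sample),
            "max_zero_prevalence": repr(self.filters.max_zero_prevalence),
            "core_min_rel_abundance": repr(self.filters.core_min_rel_abundance),
            "core_min_prevalence": repr(self.filters.core_min_prevalence),
            "rho_min": repr(self.thresholds.rho_min),
            "p_max": repr(self.thresholds.p_max),
            "min_degree": str(self.keystone_thresholds.min_degree),
            "min_cc": repr(self.keystone_thresholds.min_cc),
            "min_closeness": repr(self.keystone_thresholds.min_closeness),
            "min_tc": repr(self.keystone_thresholds.min_tc),
            "min_betweenness": repr(self.keystone_thresholds.min_betweenness),
            "probiotic_genera": ",".join(sorted(self.pattern.probiotic_genera)),
            "pathogen_genera": ",".join(sorted(self.pattern.pathogen_genera)),
            "pos_threshold": repr(self.pattern.pos_threshold),
            "neg_threshold": repr(self.pattern.neg_threshold),
            "state_ordering": ",".join(s.value for s in self.ordering),
            "registry_path": self.registry_path or "",
            "diffcorr_method": self.diffcorr_method,
            "trend_direction": self.trend_direction,
            "trend_strict": str(self.trend_strict).lower(),
            "bh_correct": str(self.bh_correct).lower(),
            "seed": str(self.seed),
        }

    @classmethod
    def from_flat(cls, flat: dict[str, str]) -> "PipelineConfig":
        known = set(cls().to_flat())
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(cls().to_flat())
        d.update({k: str(v) for k, v in flat.items()})

        def _bool(s: str) -> bool:
            if s.lower() in {"true", "1", "yes"}:
                return True
            if s.lower() in {"false", "0", "no"}:
                return False
            raise ValueError(f"not a boolean: {s!r}")

        return cls(
            filters=FilterConfig(
                min_reads_per_sample=int(d["min_reads_per_sample"]),
                max_zero_prevalence=float(d["max_zero_prevalence"]),
                core_min_rel_abundance=float(d["core_min_rel_abundance"]),
                core_min_prevalence=float(d["core_min_prevalence"]),
            ),
            thresholds=Thresholds(float(d["rho_min"]), float(d["p_max"])),
            keystone_thresholds=KeystoneThresholds(
                min_degree=int(d["min_degree"]),
                min_cc=float(d["min_cc"]),
                min_closeness=float(d["min_closeness"]),
                min_tc=float(d["min_tc"]),
                min_betweenness=float(d["min_betweenness"]),
            ),
            pattern=PatternConfig(
                probiotic_genera=frozenset(
                    g for g in d["probiotic_genera"].split(",") if g
                ),
                pathogen_genera=frozenset(
                    g for g in d["pathogen_genera"].split(",") if g
                ),
                pos_threshold=float(d["pos_threshold"]),
                neg_threshold=float(d["neg_threshold"]),
            ),
            ordering=StateOrdering(
                tuple(parse_state(s) for s in d["state_ordering"].split(",") if s)
            ),
            registry_path=d["registry_path"] or None,
            diffcorr_method=d["diffcorr_method"],
            trend_direction=d["trend_direction"],
            trend_strict=_bool(d["trend_strict"]),
            bh_correct=_bool(d["bh_correct"]),
            seed=int(d["seed"]),
        )

    @classmethod
    def from_file(cls, path: str | PathLike) -> "PipelineConfig":
        flat: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, _, value = line.partition("=")
            flat[key.strip()] = value.strip()
        return cls.from_flat(flat)

    def write(self, path: str | PathLike) -> None:
        lines = [f"{k} = {v}" for k, v in self.to_flat().items()]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class PipelineResult:
    """In-memory result bundle of one pipeline run."""

    config: PipelineConfig
    relative_tables: dict[State, AbundanceTable]
    core_results: dict[State, CoreMicrobiomeResult]
    shared_core: tuple[str, ...]
    shannon: dict[State, dict[str, float]]
    networks: dict[State, CooccurrenceNetwork]
    summaries: dict[State, "NetworkSummary"]
    keystones: dict[State, list[KeystoneRecord]]
    exclusive: dict[State, frozenset[str]]
    shared_keystones: frozenset[str]
    diffcorr: list[DiffCorrResult]
    patterns: dict[State, PatternReport]
    abundance_trends: dict[str, dict]


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc


def run_pipeline(
    tables_by_state: dict[State, AbundanceTable] | None = None,
    config: PipelineConfig = PipelineConfig(),
    table: AbundanceTable | None = None,
    metadata: list[SampleMetadata] | None = None,
    outdir: str | PathLike | None = None,
) -> PipelineResult:
    """Run every stage on a cohort and optionally write the result bundle.

    Input is either ``tables_by_state`` (one counts table per state) or a
    pooled ``table`` plus ``metadata`` assigning samples to states.  When
    ``outdir`` is given, per-state filtered tables, core/Shannon TSVs,
    GraphML + edge lists + summaries, keystone and differential-correlation
    tables, the pattern report and a run manifest are written there.
    """
    if tables_by_state is None:
        if table is None or metadata is None:
            raise ValueError("provide tables_by_state, or table plus metadata")
        tables_by_state = _stage("split_by_state", split_by_state, table, metadata)
    states = sorted(tables_by_state, key=lambda s: _STATE_RANK[s])

    relative: dict[State, AbundanceTable] = {}
    cores: dict[State, CoreMicrobiomeResult] = {}
    shannon: dict[State, dict[str, float]] = {}
    for state in states:
        t = tables_by_state[state]
        logger.info("state %s: %d genera x %d samples before filtering",
                    state.value, t.n_genera, t.n_samples)
        rel, core, sh = _stage(
            f"preprocess[{state.value}]", preprocess_state_table, t, config.filters, state
        )
        logger.info("state %s: %d genera x %d samples after filtering",
                    state.value, rel.n_genera, rel.n_samples)
        relative[state], cores[state], shannon[state] = rel, core, sh

    shared = _stage("shared_core", shared_core, [cores[s] for s in states])

    networks: dict[State, CooccurrenceNetwork] = {}
    summaries = {}
    keystones: dict[State, list[KeystoneRecord]] = {}
    registry = config.registry()
    rho_by_state: dict[State, pd.DataFrame] = {}
    for state in states:
        rel = relative[state]
        if rel.n_samples < 4 or rel.n_genera < 2:
            logger.warning("state %s has too few samples/genera for a network", state.value)
            networks[state] = CooccurrenceNetwork(
                state, frozenset(), (), config.thresholds
            )
            summaries[state] = summarize_network(networks[state])
            keystones[state] = []
            continue
        rho, p, n = _stage(f"spearman[{state.value}]", spearman_matrix, rel)
        rho_by_state[state] = rho
        from .cooccurrence import build_network

        net = _stage(
            f"network[{state.value}]", build_network,
            rho, p, n, config.thresholds, state, config.bh_correct,
        )
        networks[state] = net
        summaries[state] = _stage(f"summary[{state.value}]", summarize_network, net)
        metrics = _stage(f"topology[{state.value}]", node_metrics, net)
        keystones[state] = _stage(
            f"keystones[{state.value}]", classify_keystones,
            metrics, registry, config.keystone_thresholds, state,
        )
        logger.info("state %s: %d nodes, %d edges, %d keystones", state.value,
                    net.n_nodes, net.n_edges,
                    sum(r.is_keystone for r in keystones[state]))

    if len(states) >= 2:
        exclusive, shared_ks = _stage(
            "exclusive_keystones", exclusive_keystones, keystones
        )
    else:
        exclusive, shared_ks = {states[0]: frozenset()}, frozenset()
    # Annotate records with their cross-state exclusivity verdict.
    for state in states:
        keystones[state] = [
            dataclasses.replace(
                r, exclusive=(r.is_keystone and r.genus in exclusive.get(state, frozenset()))
            )
            for r in keystones[state]
        ]

    ordering_states = [s for s in config.ordering if s in relative]
    diff: list[DiffCorrResult] = []
    trends: dict[str, dict] = {}
    patterns: dict[State, PatternReport] = {}
    if len(ordering_states) >= 2:
        sub_ordering = StateOrdering(tuple(ordering_states))
        usable = {
            s: relative[s] for s in ordering_states
            if relative[s].n_samples >= 4 and relative[s].n_genera >= 2
        }
        if len(usable) == len(ordering_states):
            diff = _stage(
                "diffcorr", screen_pairs, usable, sub_ordering,
                config.diffcorr_method, config.trend_direction, config.trend_strict,
            )
            watch = sorted(config.pattern.probiotic_genera | config.pattern.pathogen_genera)
            trends = _stage("abundance_trend", abundance_trend, usable, watch, sub_ordering)
    for state in states:
        if state in rho_by_state:
            patterns[state] = _stage(
                f"pattern[{state.value}]", probiotic_pattern_scan,
                rho_by_state[state], config.pattern, state,
            )

    result = PipelineResult(
        config=config,
        relative_tables=relative,
        core_results=cores,
        shared_core=shared,
        shannon=shannon,
        networks=networks,
        summaries=summaries,
        keystones=keystones,
        exclusive=exclusive,
        shared_keystones=shared_ks,
        diffcorr=diff,
        patterns=patterns,
        abundance_trends=trends,
    )
    if outdir is not None:
        write_bundle(result, outdir)
    return result


def write_bundle(result: PipelineResult, outdir: str | PathLike) -> None:
    """Write the full result bundle as TSV/GraphML/JSON files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    states = sorted(result.relative_tables, key=lambda s: _STATE_RANK[s])

    for state in states:
        sv = state.value
        write_abundance_table(result.relative_tables[state], outdir / f"relative_{sv}.tsv")
        core = result.core_results[state]
        pd.DataFrame(
            [
                {"genus": g, "prevalence": core.prevalence[g], "is_core": g in core.core_genera}
                for g in sorted(core.prevalence)
            ],
            columns=["genus", "prevalence", "is_core"],
        ).to_csv(outdir / f"core_{sv}.tsv", sep="\t", index=False, float_format="%.17g")
        pd.DataFrame(
            sorted(result.shannon[state].items()), columns=["sample", "shannon_bits"]
        ).to_csv(outdir / f"shannon_{sv}.tsv", sep="\t", index=False, float_format="%.17g")

        net = result.networks[state]
        write_edge_list(net, outdir / f"edges_{sv}.tsv")
        node_attrs = {
            r.genus: {
                "degree": r.metrics.degree,
                "clustering_coefficient": r.metrics.clustering_coefficient,
                "closeness": r.metrics.closeness,
                "betweenness": r.metrics.betweenness,
                "topological_coefficient": r.metrics.topological_coefficient,
                "oxygen_class": r.oxygen_class,
                "is_keystone": r.is_keystone,
            }
            for r in result.keystones[state]
        }
        write_network_graphml(net, outdir / f"network_{sv}.graphml", node_attrs)
        s = result.summaries[state]
        pd.DataFrame(
            [dataclasses.asdict(s)],
        ).to_csv(outdir / f"summary_{sv}.tsv", sep="\t", index=False, float_format="%.17g")
        keystone_frame(result.keystones[state]).to_csv(
            outdir / f"keystones_{sv}.tsv", sep="\t", index=False, float_format="%.17g"
        )

    pd.DataFrame({"genus": list(result.shared_core)}).to_csv(
        outdir / "shared_core.tsv", sep="\t", index=False
    )
    rows = [
        {"state": s.value, "exclusive_keystones": ",".join(sorted(result.exclusive.get(s, ())))}
        for s in states
    ]
    rows.append({"state": "shared", "exclusive_keystones": ",".join(sorted(result.shared_keystones))})
    pd.DataFrame(rows, columns=["state", "exclusive_keystones"]).to_csv(
        outdir / "exclusive_keystones.tsv", sep="\t", index=False
    )

    diff_rows = []
    for r in sorted(result.diffcorr, key=lambda r: (r.genus_a, r.genus_b)):
        row = {"genus_a": r.genus_a, "genus_b": r.genus_b}
        for state, (rho, n) in r.rho_by_state.items():
            row[f"rho_{state.value}"] = rho
        row["trend_consistent"] = r.trend_consistent
        for s1, s2, p, method in r.transitions:
            row[f"p_{s1.value}_to_{s2.value}"] = p
        row["method"] = r.transitions[0][3] if r.transitions else ""
        diff_rows.append(row)
    pd.DataFrame(diff_rows).to_csv(
        outdir / "diffcorr.tsv", sep="\t", index=False, float_format="%.17g"
    )

    pattern_rows = []
    for state in states:
        if state not in result.patterns:
            continue
        rep = result.patterns[state]
        pattern_rows.append(
            {
                "state": state.value,
                "pattern_present": rep.pattern_present,
                "probiotic_pairs": ";".join(f"{a}-{b}:{r:.3f}" for a, b, r in rep.probiotic_pairs),
                "anti_pairs": ";".join(f"{a}-{b}:{r:.3f}" for a, b, r in rep.anti_pairs),
                "absent_genera": ",".join(rep.absent_genera),
            }
        )
    pd.DataFrame(
        pattern_rows,
        columns=["state", "pattern_present", "probiotic_pairs", "anti_pairs", "absent_genera"],
    ).to_csv(outdir / "pattern.tsv", sep="\t", index=False)

    trend_rows = []
    for genus in sorted(result.abundance_trends):
        entry = result.abundance_trends[genus]
        row = {"genus": genus, "verdict": entry["verdict"]}
        for state, mean in entry["means"].items():
            row[f"mean_{state.value}"] = mean
        trend_rows.append(row)
    pd.DataFrame(trend_rows).to_csv(
        outdir / "abundance_trends.tsv", sep="\t", index=False, float_format="%.17g"
    )

    manifest = {
        "package": "sputumnet",
        "version": __version__,
        "config": result.config.to_flat(),
        "states": [s.value for s in states],
        "outputs": sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def report(result: PipelineResult) -> str:
    """Human-readable summary: the textual analogue of the result tables."""
    lines = []
    states = sorted(result.relative_tables, key=lambda s: _STATE_RANK[s])
    lines.append("Per-state networks")
    for state in states:
        s = result.summaries.get(state)
        ks = result.keystones.get(state, [])
        n_ks = sum(r.is_keystone for r in ks)
        if s is None:
            lines.append(f"  {state.value}: MISSING")
            continue
        lines.append(
            f"  {state.value}: {s.n_nodes} nodes, {s.n_edges} edges, "
            f"avg clustering {s.avg_clustering_coefficient:.3f}, "
            f"connectivity {s.connectivity:.3f}, {n_ks} keystone genera"
        )
    lines.append("Core microbiome shared across states: "
                 + (", ".join(result.shared_core) if result.shared_core else "(none)"))
    lines.append("Keystones shared across states: "
                 + (", ".join(sorted(result.shared_keystones)) if result.shared_keystones else "(none)"))
    lines.append("Exclusive keystones")
    for state in states:
        excl = sorted(result.exclusive.get(state, ()))
        lines.append(f"  {state.value}: " + (", ".join(excl) if excl else "(none)"))
    consistent = [r for r in result.diffcorr if r.trend_consistent]
    lines.append(f"Trend-consistent genus pairs: {len(consistent)}"
                 + ("" if result.diffcorr else " (diffcorr MISSING)"))
    for r in consistent:
        rhos = ", ".join(
            f"{state.value}={rho:.2f}" for state, (rho, _) in r.rho_by_state.items()
        )
        lines.append(f"  {r.genus_a}-{r.genus_b}: {rhos}; min transition p = {r.min_transition_p:.2g}")
    lines.append("Probiotic-pathogen pattern")
    for state in states:
        rep = result.patterns.get(state)
        if rep is None:
            lines.append(f"  {state.value}: MISSING")
        else:
            lines.append(f"  {state.value}: {'present' if rep.pattern_present else 'absent'}")
    return "\n".join(lines) + "\n"
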