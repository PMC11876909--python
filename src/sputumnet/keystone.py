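"""Keystone-genus classification and cross-state keystone comparison.

A genus is called keystone when it passes a five-threshold topological
panel AND a biological criterion (being an anaerobe).  Default panel,
applied to the node metrics of the state's co-occurrence network:
degree strictly above 2, clustering coefficient at or above 0 (vacuously
true for real coefficients, retained verbatim for fidelity to the published
panel), closeness strictly above 0.3, topological coefficient strictly
above 0.3, and betweenness strictly above 0.  The anaerobe criterion
admits both facultative and obligate anaerobes.

Oxygen classes come from a curated, user-overridable registry shipped as a
TSV (``data/oxygen_registry.tsv``); genera absent from the registry are
classed ``unknown`` and never keystone.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from os import PathLike

import pandas as pd

from .containers import State
from .topology import NodeMetrics

__all__ = [
    "KeystoneThresholds",
    "OxygenClass",
    "OxygenRegistry",
    "KeystoneRecord",
    "classify_keystones",
    "exclusive_keystones",
    "default_registry",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KeystoneThresholds:
    """The five-threshold topological panel.

    Strictness mirrors the published wording: degree, closeness,
    topological coefficient and betweenness comparisons are strict (>),
    the clustering-coefficient comparison is non-strict (>=).
    """

    min_degree: int = 2
    min_cc: float = 0.0
    min_closeness: float = 0.3
    min_tc: float = 0.3
    min_betweenness: float = 0.0

    def passes(self, m: NodeMetrics) -> bool:
        return (
            m.degree > self.min_degree
            and m.clustering_coefficient >= self.min_cc
            and m.closeness > self.min_closeness
            and m.topological_coefficient > self.min_tc
            and m.betweenness > self.min_betweenness
        )


OxygenClass = str
OXYGEN_CLASSES = frozenset(
    {"aerobe", "facultative_anaerobe", "obligate_anaerobe", "microaerophile", "unknown"}
)
ANAEROBE_CLASSES = frozenset({"facultative_anaerobe", "obligate_anaerobe"})


class OxygenRegistry:
    """Case-insensitive genus -> oxygen-class lookup."""

    def __init__(self, mapping: dict[str, OxygenClass]):
        self._map: dict[str, OxygenClass] = {}
        for genus, cls in mapping.items():
            cls = cls.strip().lower()
            if cls not in OXYGEN_CLASSES:
                raise ValueError(
                    f"unknown oxygen class {cls!r} for genus {genus!r}; "
                    f"accepted: {sorted(OXYGEN_CLASSES)}"
                )
            self._map[genus.strip().lower()] = cls

    @classmethod
    def from_tsv(cls, path: str | PathLike) -> "OxygenRegistry":
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        if not {"genus", "oxygen_class"} <= set(df.columns):
            raise ValueError(f"registry {path} needs columns genus, oxygen_class")
        return cls(dict(zip(df["genus"], df["oxygen_class"])))

    def oxygen_class(self, genus: str) -> OxygenClass:
        return self._map.get(genus.strip().lower(), "unknown")

    def is_anaerobe(self, genus: str) -> bool:
        return self.oxygen_class(genus) in ANAEROBE_CLASSES

    def override(self, genus: str, oxygen_class: OxygenClass) -> None:
        if oxygen_class not in OXYGEN_CLASSES:
            raise ValueError(f"unknown oxygen class {oxygen_class!r}")
        self._map[genus.strip().lower()] = oxygen_class

    def __len__(self) -> int:
        return len(self._map)


def default_registry() -> OxygenRegistry:
    """The curated registry shipped with the package (editable TSV)."""
    with resources.as_file(
        resources.files("sputumnet").joinpath("data/oxygen_registry.tsv")
    ) as path:
        return OxygenRegistry.from_tsv(path)


@dataclass(frozen=True)
class KeystoneRecord:
    """Per-genus keystone verdict in one state's network."""

    genus: str
    state: State
    metrics: NodeMetrics
    oxygen_class: OxygenClass
    passes_topology: bool
    is_anaerobe: bool
    is_keystone: bool
    exclusive: bool | None = None  # set by exclusive_keystones

    def __post_init__(self) -> None:
        if self.is_keystone != (self.passes_topology and self.is_anaerobe):
            raise ValueError("is_keystone must equal passes_topology AND is_anaerobe")


def classify_keystones(
    metrics: dict[str, NodeMetrics],
    registry: OxygenRegistry,
    thresholds: KeystoneThresholds = KeystoneThresholds(),
    state: State = State.HEALTHY,
) -> list[KeystoneRecord]:
    """Apply the topological panel and anaerobe criterion to every node.

    Genera missing from the registry get oxygen class ``unknown`` (a
    warning is logged) and therefore cannot be keystone.  Records are
    sorted by degree descending, ties by genus name.
    """
    records = []
    for genus, m in metrics.items():
        cls = registry.oxygen_class(genus)
        if cls == "unknown":
            logger.warning("genus %r absent from oxygen registry; classed unknown", genus)
        passes = thresholds.passes(m)
        anaerobe = cls in ANAEROBE_CLASSES
        records.append(
            KeystoneRecord(
                genus=genus,
                state=state,
                metrics=m,
                oxygen_class=cls,
                passes_topology=passes,
                is_anaerobe=anaerobe,
                is_keystone=passes and anaerobe,
            )
        )
    records.sort(key=lambda r: (-r.metrics.degree, r.genus))
    return records


def exclusive_keystones(
    records_by_state: dict[State, list[KeystoneRecord]],
) -> tuple[dict[State, frozenset[str]], frozenset[str]]:
    """Split keystone sets into per-state exclusive sets and the shared set.

    A genus is exclusive to a state when it is keystone there and in none
    of the other supplied states; the shared set holds genera keystone in
    every supplied state.  Needs at least two states.
    """
    if len(records_by_state) < 2:
        raise ValueError("exclusive_keystones needs records for at least 2 states")
    keystone_sets = {
        state: {r.genus for r in records if r.is_keystone}
        for state, records in records_by_state.items()
    }
    exclusive: dict[State, frozenset[str]] = {}
    for state, genera in keystone_sets.items():
        others = set().union(
            *(s for st, s in keystone_sets.items() if st != state)
        ) if len(keystone_sets) > 1 else set()
        exclusive[state] = frozenset(genera - others)
    shared = frozenset(set.intersection(*keystone_sets.values()))
    return exclusive, shared


def keystone_frame(records: list[KeystoneRecord]) -> pd.DataFrame:
    """Flatten keystone records to the TSV layout used by the CLI."""
    rows = []
    for r in records:
        rows.append(
            {
                "genus": r.genus,
                "state": r.state.value,
                "degree": r.metrics.degree,
                "clustering_coefficient": r.metrics.clustering_coefficient,
                "closeness": r.metrics.closeness,
                "betweenness": r.metrics.betweenness,
                "topological_coefficient": r.metrics.topological_coefficient,
                "oxygen_class": r.oxygen_class,
                "passes_topology": r.passes_topology,
                "is_keystone": r.is_keystone,
                "exclusive": "" if r.exclusive is None else r.exclusive,
            }
        )
    columns = [
        "genus", "state", "degree", "clustering_coefficient", "closeness",
        "betweenness", "topological_coefficient", "oxygen_class",
        "passes_topology", "is_keystone", "exclusive",
    ]
    return pd.DataFrame(rows, columns=columns)
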