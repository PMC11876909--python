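"""Core in-memory containers shared by every pipeline stage.

The pipeline's universal currency is the :class:`AbundanceTable`, a
genus-by-sample matrix of non-negative counts or relative abundances,
wrapped around a :class:`pandas.DataFrame`.  Samples are assigned to one
of five disease states (healthy, stable COPD, one exacerbation, multiple
exacerbations, post-therapy) via :class:`SampleMetadata` records.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "State",
    "Mode",
    "AbundanceTable",
    "SampleMetadata",
    "StateOrdering",
    "MAIN_ORDERING",
    "VALIDATION_ORDERING",
    "parse_state",
]

_REL_TOL = 1e-9


class State(str, enum.Enum):
    """Disease state of a sputum sample cohort."""

    HEALTHY = "healthy"
    STABLE = "stable"
    EXAC_ONE = "exac_one"
    EXAC_MULTI = "exac_multi"
    POST_THERAPY = "post_therapy"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Accepted case-insensitive synonyms for state labels found in study metadata.
#: "exacerbation" without an exacerbation count maps to ``exac_one``.
_STATE_SYNONYMS: dict[str, State] = {
    "healthy": State.HEALTHY,
    "control": State.HEALTHY,
    "stable": State.STABLE,
    "stable_copd": State.STABLE,
    "exac_one": State.EXAC_ONE,
    "exacerbation": State.EXAC_ONE,
    "one_exacerbation": State.EXAC_ONE,
    "single_exacerbation": State.EXAC_ONE,
    "exac_multi": State.EXAC_MULTI,
    "multiple_exacerbations": State.EXAC_MULTI,
    "multi_exacerbation": State.EXAC_MULTI,
    "post_therapy": State.POST_THERAPY,
    "posttherapy": State.POST_THERAPY,
    "post_treatment": State.POST_THERAPY,
}


def parse_state(label: str | State) -> State:
    """Normalize a free-form state label to a :class:`State`.

    Matching is case-insensitive; spaces and hyphens are treated as
    underscores.  Raises ``ValueError`` listing the accepted labels when
    the label is unknown.
    """
    if isinstance(label, State):
        return label
    key = str(label).strip().lower().replace(" ", "_").replace("-", "_")
    try:
        return _STATE_SYNONYMS[key]
    except KeyError:
        accepted = sorted({s.value for s in State} | set(_STATE_SYNONYMS))
        raise ValueError(
            f"unknown state label {label!r}; accepted labels: {', '.join(accepted)}"
        ) from None


class Mode(str, enum.Enum):
    COUNTS = "counts"
    RELATIVE = "relative"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _check_identifier(name: str, kind: str) -> None:
    if "\t" in name or "\n" in name or "\r" in name:
        raise ValueError(f"{kind} identifier {name!r} contains a tab or newline")


@dataclass
class AbundanceTable:
    """Genus-by-sample abundance matrix.

    Parameters
    ----------
    data
        DataFrame with genus names as the index and sample identifiers as
        columns.  Entries must be non-negative and finite.
    mode
        ``Mode.COUNTS`` for raw read counts, ``Mode.RELATIVE`` for
        per-sample proportions (each column then sums to 1 within 1e-9).
    """

    data: pd.DataFrame
    mode: Mode = Mode.COUNTS

    def __post_init__(self) -> None:
        self.mode = Mode(self.mode)
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame (genus x sample)")
        self.data = self.data.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate genus names: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        for g in self.data.index:
            _check_identifier(g, "genus")
        for s in self.data.columns:
            _check_identifier(s, "sample")
        values = self.data.to_numpy()
        if values.size and not np.all(np.isfinite(values)):
            raise ValueError("abundance table contains non-finite entries")
        if values.size and (values < 0).any():
            raise ValueError("abundance table contains negative entries")
        if self.mode is Mode.RELATIVE and self.data.shape[1]:
            sums = values.sum(axis=0)
            bad = np.flatnonzero(np.abs(sums - 1.0) > _REL_TOL)
            if bad.size:
                name = self.data.columns[bad[0]]
                raise ValueError(
                    f"relative-mode column {name!r} sums to {sums[bad[0]]!r}, not 1"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def genera(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def n_genera(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, samples: Sequence[str]) -> "AbundanceTable":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return AbundanceTable(self.data.loc[:, list(samples)].copy(), self.mode)

    def subset_genera(self, genera: Sequence[str]) -> "AbundanceTable":
        missing = [g for g in genera if g not in self.data.index]
        if missing:
            raise KeyError(f"genera not in table: {missing}")
        return AbundanceTable(self.data.loc[list(genera)].copy(), self.mode)

    def copy(self) -> "AbundanceTable":
        return AbundanceTable(self.data.copy(), self.mode)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbundanceTable):
            return NotImplemented
        return self.mode is other.mode and self.data.equals(other.data)


@dataclass(frozen=True)
class SampleMetadata:
    """One metadata row: sample identifier, disease state, optional depth."""

    sample_id: str
    state: State
    total_reads: int | None = None

    def __post_init__(self) -> None:
        _check_identifier(self.sample_id, "sample")
        object.__setattr__(self, "state", parse_state(self.state))
        if self.total_reads is not None and self.total_reads < 0:
            raise ValueError("total_reads must be non-negative")


@dataclass(frozen=True)
class StateOrdering:
    """Ordered disease states encoding increasing severity."""

    states: tuple[State, ...]

    def __post_init__(self) -> None:
        states = tuple(parse_state(s) for s in self.states)
        if len(states) < 2:
            raise ValueError("a state ordering needs at least 2 states")
        if len(set(states)) != len(states):
            raise ValueError("state ordering contains repeats")
        object.__setattr__(self, "states", states)

    def __iter__(self):
        return iter(self.states)

    def __len__(self) -> int:
        return len(self.states)

    def transitions(self) -> list[tuple[State, State]]:
        """Consecutive (earlier, later) state pairs along the ordering."""
        return list(zip(self.states[:-1], self.states[1:]))


#: Main-cohort severity ordering: healthy < stable < one < multiple exacerbations.
MAIN_ORDERING = StateOrdering(
    (State.HEALTHY, State.STABLE, State.EXAC_ONE, State.EXAC_MULTI)
)

#: Validation-cohort ordering (post-therapy samples are compared separately).
VALIDATION_ORDERING = StateOrdering((State.HEALTHY, State.STABLE, State.EXAC_ONE))


def group_samples_by_state(
    metadata: Iterable[SampleMetadata],
) -> dict[State, list[str]]:
    """Map each state to its sample identifiers, preserving input order."""
    out: dict[State, list[str]] = {}
    seen: set[str] = set()
    for rec in metadata:
        if rec.sample_id in seen:
            raise ValueError(f"duplicate metadata row for sample {rec.sample_id!r}")
        seen.add(rec.sample_id)
        out.setdefault(rec.state, []).append(rec.sample_id)
    return out


def split_by_state(
    table: AbundanceTable, metadata: Iterable[SampleMetadata]
) -> dict[State, AbundanceTable]:
    """Split a table into per-state tables using metadata assignments.

    Every sample in the table must have exactly one metadata row; extra
    metadata rows (samples absent from the table) are ignored.
    """
    groups = group_samples_by_state(metadata)
    assigned = {s for ids in groups.values() for s in ids}
    missing = [s for s in table.samples if s not in assigned]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    out: dict[State, AbundanceTable] = {}
    for state, ids in groups.items():
        present = [s for s in ids if s in table.data.columns]
        if present:
            out[state] = table.subset_samples(present)
    return out
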