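"""Readers and writers for abundance tables, metadata, networks and results.

Canonical on-disk format is tab-separated text: abundance tables have the
sample identifiers in the first row and genus names in the first column;
metadata tables carry ``sample_id``, ``state`` and optionally
``total_reads`` columns.  Networks export to GraphML (via networkx) and to
a flat edge-list TSV.  A minimal BIOM-JSON (format 1.0) reader is provided
as a convenience adapter.
"""

from __future__ import annotations

import json
import math
from os import PathLike
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd

from .containers import AbundanceTable, Mode, SampleMetadata, parse_state

if TYPE_CHECKING:  # pragma: no cover
    from .cooccurrence import CooccurrenceNetwork

__all__ = [
    "read_abundance_table",
    "write_abundance_table",
    "read_metadata",
    "write_metadata",
    "read_biom_json",
    "write_edge_list",
    "write_network_graphml",
]


class TableParseError(ValueError):
    """A malformed cell or header in a tab-separated input file."""


def read_abundance_table(path: str | PathLike, mode: str | Mode) -> AbundanceTable:
    """Read a genus-by-sample TSV into a validated :class:`AbundanceTable`.

    The first row holds sample identifiers, the first column genus names.
    A non-numeric body cell raises :class:`TableParseError` naming the
    offending genus and sample; duplicate identifiers raise ``ValueError``.
    """
    raw = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False, na_filter=False
    )

    def parse(cell: str) -> float:
        # Python's float() round-trips IEEE doubles exactly; pandas'
        # to_numeric fast path can be off by one ulp.
        try:
            return float(cell)
        except ValueError:
            return float("nan")

    numeric = raw.apply(lambda col: col.map(parse))
    bad = np.argwhere(numeric.isna().to_numpy() & (raw.to_numpy() != ""))
    if bad.size:
        r, c = bad[0]
        raise TableParseError(
            f"non-numeric cell {raw.iat[r, c]!r} at genus {raw.index[r]!r}, "
            f"sample {raw.columns[c]!r} in {path}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise TableParseError(
            f"empty cell at genus {raw.index[r]!r}, sample {raw.columns[c]!r} in {path}"
        )
    return AbundanceTable(numeric, Mode(mode))


def write_abundance_table(table: AbundanceTable, path: str | PathLike) -> None:
    """Write a table as TSV at full float precision (round-trip safe)."""
    out = table.data.copy()
    out.index.name = "genus"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_metadata(path: str | PathLike) -> list[SampleMetadata]:
    """Read a sample metadata TSV (``sample_id``, ``state``[, ``total_reads``]).

    State labels are normalized case-insensitively; an unknown label
    raises ``ValueError`` listing the accepted values.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "state"}
    missing = required - set(df.columns)
    if missing:
        raise TableParseError(f"metadata file {path} lacks columns: {sorted(missing)}")
    records: list[SampleMetadata] = []
    for _, row in df.iterrows():
        total_reads: int | None = None
        if "total_reads" in df.columns and row["total_reads"] != "":
            try:
                total_reads = int(float(row["total_reads"]))
            except ValueError:
                raise TableParseError(
                    f"non-numeric total_reads {row['total_reads']!r} for sample "
                    f"{row['sample_id']!r} in {path}"
                ) from None
        records.append(
            SampleMetadata(row["sample_id"], parse_state(row["state"]), total_reads)
        )
    if len({r.sample_id for r in records}) != len(records):
        raise ValueError(f"duplicate sample_id rows in {path}")
    return records


def write_metadata(records: Iterable[SampleMetadata], path: str | PathLike) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "state": r.state.value,
            "total_reads": "" if r.total_reads is None else r.total_reads,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["sample_id", "state", "total_reads"]).to_csv(
        path, sep="\t", index=False
    )


def read_biom_json(path: str | PathLike, mode: str | Mode = Mode.COUNTS) -> AbundanceTable:
    """Load a BIOM format 1.0 (JSON) table as an :class:`AbundanceTable`.

    Supports both ``dense`` and ``sparse`` matrix encodings.  Observation
    ids become genus names and sample ids become columns.
    """
    with open(path) as fh:
        doc = json.load(fh)
    genera = [obs["id"] for obs in doc["rows"]]
    samples = [s["id"] for s in doc["columns"]]
    n_r, n_c = doc["shape"]
    if (n_r, n_c) != (len(genera), len(samples)):
        raise TableParseError(f"BIOM shape {doc['shape']} does not match row/column lists")
    values = np.zeros((n_r, n_c))
    if doc.get("matrix_type", "dense") == "sparse":
        for r, c, v in doc["data"]:
            values[int(r), int(c)] = v
    else:
        values[:] = np.asarray(doc["data"], dtype=float)
    frame = pd.DataFrame(values, index=genera, columns=samples)
    return AbundanceTable(frame, Mode(mode))


# -- network export ------------------------------------------------------------


def _edge_rows(net: "CooccurrenceNetwork") -> list[dict]:
    rows = []
    for e in sorted(net.edges, key=lambda e: (e.genus_a, e.genus_b)):
        rows.append(
            {
                "genus_a": e.genus_a,
                "genus_b": e.genus_b,
                "rho": e.rho,
                "p": e.p_value,
                "sign": "+" if e.rho > 0 else "-",
            }
        )
    return rows


def write_edge_list(net: "CooccurrenceNetwork", path: str | PathLike) -> None:
    """Write the network as a flat TSV: genus_a, genus_b, rho, p, sign."""
    pd.DataFrame(
        _edge_rows(net), columns=["genus_a", "genus_b", "rho", "p", "sign"]
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_network_graphml(
    net: "CooccurrenceNetwork",
    path: str | PathLike,
    node_attributes: dict[str, dict[str, float | bool | str]] | None = None,
) -> None:
    """Export the network to GraphML with edge rho/p/sign attributes.

    ``node_attributes`` maps genus -> attribute dict (e.g. topology metrics
    and keystone flags) merged onto the nodes.  Node and edge insertion is
    sorted so identical networks serialize byte-identically.
    """
    import networkx as nx

    g = nx.Graph()
    g.graph["state"] = net.state.value
    for node in sorted(net.nodes):
        attrs = dict(node_attributes.get(node, {})) if node_attributes else {}
        g.add_node(node, **attrs)
    for row in _edge_rows(net):
        g.add_edge(
            row["genus_a"],
            row["genus_b"],
            rho=float(row["rho"]),
            p=float(row["p"]),
            sign=row["sign"],
        )
    nx.write_graphml(g, Path(path))


def read_edge_list(path: str | PathLike) -> pd.DataFrame:
    """Read a flat edge-list TSV written by :func:`write_edge_list`."""
    df = pd.read_csv(path, sep="\t", dtype={"genus_a": str, "genus_b": str})
    for col in ("rho", "p"):
        if col in df.columns and not df.empty:
            bad = df[col].map(lambda v: not math.isfinite(float(v)))
            if bad.any():
                raise TableParseError(f"non-finite {col} in {path}")
    return df
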