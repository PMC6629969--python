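"""Attributed directed-graph I/O and the data model shared by all modules.

The in-memory network container is a :class:`networkx.DiGraph` restricted to a
*simple* digraph (no self-loops, no parallel edges) over opaque string node
ids.  Per-neuron attributes — 3-D soma position in micrometres and birth time
in minutes — live in an :class:`AttributeTable` backed by a pandas DataFrame.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("netgame")

ATTRIBUTE_COLUMNS = ["neuron_id", "x_um", "y_um", "z_um", "birth_time_min"]


class ParseError(ValueError):
    """A malformed input line or field, reported with its location."""


class MissingAttributeError(KeyError):
    """Graph nodes absent from the attribute table."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"attribute table missing nodes: {', '.join(self.missing)}")


def validate_graph(g: nx.DiGraph) -> None:
    """Raise ``ValueError`` if *g* violates the simple-digraph data model."""
    if not g.is_directed():
        raise ValueError("network must be a directed graph")
    if g.is_multigraph():
        raise ValueError("network must be a simple graph (no parallel edges)")
    loops = list(nx.selfloop_edges(g))
    if loops:
        raise ValueError(f"self-loops not allowed: {loops[:5]}")


@dataclass(frozen=True)
class AttributeTable:
    """Per-neuron soma position (µm) and birth time (min).

    Wraps a DataFrame indexed by neuron id with columns
    ``x_um, y_um, z_um, birth_time_min``; exposes vectorised pair features.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        df = self.frame
        required = {"x_um", "y_um", "z_um", "birth_time_min"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"attribute table missing columns: {sorted(missing)}")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate neuron ids: {dup}")
        vals = df[["x_um", "y_um", "z_um", "birth_time_min"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite coordinate or birth time in attribute table")
        if (df["birth_time_min"] < 0).any():
            raise ValueError("birth times must be non-negative")

    @property
    def ids(self) -> list[str]:
        return list(self.frame.index)

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, node: str) -> bool:
        return node in self.frame.index

    def position(self, node: str) -> np.ndarray:
        return self.frame.loc[node, ["x_um", "y_um", "z_um"]].to_numpy(dtype=float)

    def birth_time(self, node: str) -> float:
        return float(self.frame.loc[node, "birth_time_min"])

    def distance(self, i: str, j: str) -> float:
        """Euclidean soma distance D_ij in µm (0 for i == j)."""
        return float(np.linalg.norm(self.position(i) - self.position(j)))

    def birth_diff(self, i: str, j: str) -> float:
        """Absolute birth-time difference B_ij in minutes."""
        return abs(self.birth_time(i) - self.birth_time(j))

    def subset(self, nodes) -> "AttributeTable":
        return AttributeTable(self.frame.loc[list(nodes)].copy())

    def unit_scaled(self) -> "AttributeTable":
        """Rescale positions and birth times to unit range.

        Positions are divided by the largest single-axis extent (so the
        cloud fits a unit box and distances stay isotropic), birth times by
        their range.  Use when the utility game needs link costs (D, B) and
        structural terms (S, P, C, Be) on commensurate scales; the raw
        µm/min units otherwise dominate the utility.
        """
        df = self.frame.copy()
        pos = df[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        extent = float(np.max(pos.max(axis=0) - pos.min(axis=0)))
        if extent > 0:
            df[["x_um", "y_um", "z_um"]] = (pos - pos.min(axis=0)) / extent
        bt = df["birth_time_min"].to_numpy(dtype=float)
        span = float(bt.max() - bt.min())
        if span > 0:
            df["birth_time_min"] = (bt - bt.min()) / span
        return AttributeTable(df)


def read_edge_list(path, *, undirected: bool = False) -> nx.DiGraph:
    """Read a whitespace-separated ``source target`` edge list into a digraph.

    Lines starting with ``#`` (and blank lines) are skipped.  Self-loops are
    dropped and duplicate edges collapsed, each with a logged warning — both
    occur routinely in connectome exports.  With ``undirected=True`` every
    edge is symmetrised on read.
    """
    path = Path(path)
    g = nx.DiGraph()
    n_dup = n_loop = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise ParseError(f"{path}:{lineno}: expected 'source target', got {raw!r}")
            u, v = tokens[0], tokens[1]
            g.add_node(u)
            g.add_node(v)
            if u == v:
                n_loop += 1
                continue
            pairs = [(u, v), (v, u)] if undirected else [(u, v)]
            for a, b in pairs:
                if g.has_edge(a, b):
                    if not (undirected and (a, b) != (u, v)):
                        n_dup += 1
                else:
                    g.add_edge(a, b)
    if n_loop:
        logger.warning("%s: dropped %d self-loop(s)", path, n_loop)
    if n_dup:
        logger.warning("%s: collapsed %d duplicate edge(s)", path, n_dup)
    validate_graph(g)
    return g


def read_attributes(path, graph: nx.DiGraph | None = None) -> AttributeTable:
    """Read the neuron attribute CSV; check coverage of *graph* if given.

    Rows for neurons not in the graph are accepted with a warning; graph
    nodes absent from the table raise :class:`MissingAttributeError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"neuron_id": str})
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing_cols = set(ATTRIBUTE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ParseError(f"{path}: missing columns {sorted(missing_cols)}")
    for col in ATTRIBUTE_COLUMNS[1:]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            bad = df.loc[coerced.isna(), "neuron_id"].tolist()
            raise ParseError(f"{path}: non-numeric {col} for neuron(s) {bad}")
        df[col] = coerced
    df = df.set_index("neuron_id")
    table = AttributeTable(df)
    if graph is not None:
        nodes = set(graph.nodes)
        missing = nodes - set(table.ids)
        if missing:
            raise MissingAttributeError(missing)
        extra = set(table.ids) - nodes
        if extra:
            logger.warning(
                "%s: %d attribute row(s) for neurons not in the network", path, len(extra)
            )
            table = table.subset(sorted(nodes))
    return table


def write_edge_list(graph: nx.DiGraph, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# source target\n")
        for u, v in sorted(graph.edges):
            fh.write(f"{u} {v}\n")


def write_graphml(graph: nx.DiGraph, path) -> None:
    nx.write_graphml(graph, str(path))


def read_graphml(path) -> nx.DiGraph:
    g = nx.DiGraph(nx.read_graphml(str(path)))
    validate_graph(g)
    return g


def write_attributes(table: AttributeTable, path) -> None:
    df = table.frame.reset_index()
    if df.columns[0] != "neuron_id":
        df = df.rename(columns={df.columns[0]: "neuron_id"})
    df.to_csv(path, index=False)


def write_report(report: dict, path) -> None:
    """Serialize a structured result to JSON (numpy scalars coerced)."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def write_outputs(graph: nx.DiGraph, report: dict, out_dir, stem: str = "network") -> dict:
    """Write the standard output bundle: GraphML + edge list + JSON report.

    Returns the mapping of artefact name to path.  Round trip guarantee:
    re-reading either graph serialization reproduces the node and edge sets.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "graphml": out_dir / f"{stem}.graphml",
        "edgelist": out_dir / f"{stem}.edges",
        "report": out_dir / f"{stem}.json",
    }
    write_graphml(graph, paths["graphml"])
    write_edge_list(graph, paths["edgelist"])
    write_report(report, paths["report"])
    return paths
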