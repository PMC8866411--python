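"""Readers and writers for braingraphs: CSV edge lists and GraphML.

The CSV edge-list dialect is one edge per row under a fixed
``node1,node2,weight`` header, with ``#`` comment lines.  Rows are written
sorted by canonical ``(u, v)`` so identical graphs serialize to
byte-identical files.  GraphML output follows the standard undirected
schema with a ``weight`` edge attribute and a ``label`` node attribute.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .graph_model import (
    Edge,
    Parcellation,
    ValidationError,
    WeightedBraingraph,
    canonical_edge,
)

logger = logging.getLogger(__name__)

_HEADER = ("node1", "node2", "weight")


@dataclass(frozen=True)
class EdgeListDialect:
    """CSV dialect for edge-list files: delimiter, fixed header, comments."""

    delimiter: str = ","
    header: tuple[str, str, str] = _HEADER
    comment_prefix: str = "#"


DEFAULT_DIALECT = EdgeListDialect()


def read_edgelist(
    path: str | Path,
    parcellation: Parcellation,
    subject_id: str,
    resolution_name: str | None = None,
    dialect: EdgeListDialect = DEFAULT_DIALECT,
) -> WeightedBraingraph:
    """Read a CSV edge list into a canonical, validated braingraph.

    Zero-weight rows are accepted and dropped with a warning (absence of
    an edge encodes weight 0, so such rows are redundant).  Duplicate rows
    for the same unordered pair, malformed rows, and node ids outside the
    parcellation raise :class:`ValidationError`.
    """
    path = Path(path)
    if resolution_name is None:
        resolution_name = parcellation.resolution_name
    edges: dict[Edge, float] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=dialect.delimiter)
        saw_header = False
        for lineno, row in enumerate(reader, start=1):
            if not row or (row[0].startswith(dialect.comment_prefix)):
                continue
            if not saw_header:
                if tuple(c.strip() for c in row) != dialect.header:
                    raise ValidationError(
                        f"{path}:{lineno}: expected header "
                        f"{','.join(dialect.header)!r}, got {','.join(row)!r}"
                    )
                saw_header = True
                continue
            if len(row) != 3:
                raise ValidationError(f"{path}:{lineno}: expected 3 columns, got {len(row)}")
            try:
                u, v = int(row[0]), int(row[1])
                w = float(row[2])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: malformed row {row!r}") from exc
            key = canonical_edge(u, v)
            if key in edges:
                raise ValidationError(f"{path}:{lineno}: duplicate edge {key}")
            if w == 0.0:
                logger.warning("%s:%d: dropping zero-weight row for edge %s", path, lineno, key)
                continue
            edges[key] = w
        if not saw_header:
            raise ValidationError(f"{path}: missing edge-list header")
    graph = WeightedBraingraph(subject_id, resolution_name, parcellation, edges)
    return graph.validate()


def write_edgelist(
    graph: WeightedBraingraph,
    path: str | Path,
    precision: int = 6,
    dialect: EdgeListDialect = DEFAULT_DIALECT,
) -> Path:
    """Write a braingraph as a sorted CSV edge list.

    Rows are sorted by ``(u, v)`` ascending and weights rendered with
    exactly ``precision`` decimals, so reading the file back recovers the
    graph up to weight rounding.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter)
        writer.writerow(dialect.header)
        for (u, v) in sorted(graph.edges):
            writer.writerow([u, v, f"{graph.edges[(u, v)]:.{precision}f}"])
    return path


def write_graphml(graph: WeightedBraingraph, path: str | Path) -> Path:
    """Write a braingraph as standard undirected GraphML.

    Nodes carry a ``label`` attribute; edges carry a ``weight`` attribute;
    subject id and resolution are stored as graph attributes.  All
    parcellation nodes are written, including isolated ones, so the node
    universe round-trips.
    """
    path = Path(path)
    g = nx.Graph(subject_id=graph.subject_id, resolution_name=graph.resolution_name)
    for node_id, label in graph.parcellation.nodes:
        g.add_node(node_id, label=label)
    for (u, v), w in graph.edges.items():
        g.add_edge(u, v, weight=float(w))
    nx.write_graphml(g, path)
    return path


def read_graphml(
    path: str | Path,
    parcellation: Parcellation | None = None,
    subject_id: str | None = None,
) -> WeightedBraingraph:
    """Read an undirected GraphML braingraph.

    When ``parcellation`` is omitted it is reconstructed from the file's
    nodes and their ``label`` attributes.  Directed GraphML and edges
    lacking a ``weight`` attribute are rejected.
    """
    path = Path(path)
    try:
        g = nx.read_graphml(path, node_type=int)
    except Exception as exc:  # malformed XML or schema
        raise ValidationError(f"{path}: not readable as GraphML ({exc})") from exc
    if g.is_directed():
        raise ValidationError(f"{path}: directed GraphML is not supported")
    resolution_name = g.graph.get("resolution_name", "unknown")
    if subject_id is None:
        subject_id = str(g.graph.get("subject_id", path.stem))
    if parcellation is None:
        nodes = tuple(
            (n, str(g.nodes[n].get("label", f"roi_{n:04d}"))) for n in sorted(g.nodes)
        )
        parcellation = Parcellation(resolution_name, nodes)
    edges: dict[Edge, float] = {}
    for u, v, data in g.edges(data=True):
        if "weight" not in data:
            raise ValidationError(f"{path}: edge ({u},{v}) lacks a weight attribute")
        edges[canonical_edge(u, v)] = float(data["weight"])
    graph = WeightedBraingraph(subject_id, parcellation.resolution_name, parcellation, edges)
    return graph.validate()


def augmented_name(
    subject_id: str,
    resolution_name: str,
    subset_index: int,
    n_subsets: int,
    width: int = 3,
) -> str:
    """Deterministic name for the ``subset_index``-th augmented graph.

    Returns ``"<subject>_<resolution>_s<zero-padded index>"``; the index
    must lie in the half-open range ``[0, n_subsets)``.
    """
    if not 0 <= subset_index < n_subsets:
        raise ValidationError(
            f"subset index {subset_index} out of range [0, {n_subsets})"
        )
    return f"{subject_id}_{resolution_name}_s{subset_index:0{width}d}"


def write_parcellation(parcellation: Parcellation, path: str | Path) -> Path:
    """Write a parcellation as a ``node_id,label`` CSV."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["node_id", "label"])
        for node_id, label in parcellation.nodes:
            writer.writerow([node_id, label])
    return path


def read_parcellation(path: str | Path, resolution_name: str | None = None) -> Parcellation:
    """Read a ``node_id,label`` CSV parcellation."""
    path = Path(path)
    nodes = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [c.strip() for c in header[:2]] != ["node_id", "label"]:
            raise ValidationError(f"{path}: expected header 'node_id,label'")
        for row in reader:
            if not row:
                continue
            nodes.append((int(row[0]), row[1]))
    if resolution_name is None:
        resolution_name = f"scale{len(nodes)}"
    return Parcellation(resolution_name, tuple(nodes))
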