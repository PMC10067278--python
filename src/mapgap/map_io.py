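"""Read, validate and write systems maps.

A map is stored as two CSV tables: a node table (``id,label,levels``) and a
directed edge table (``source,target``).  A node may belong to several
social-ecological levels; the ``levels`` cell holds delimiter-separated level
names (semicolon by default).  Level names are case-insensitive and normalized
to lowercase.  Edge direction is read and preserved, but every coverage
computation downstream treats an edge symmetrically in its two endpoints.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

from .errors import FormatError, IntegrityError, ValidationError

logger = logging.getLogger(__name__)

#: The four levels of the social-ecological model, ordered from most proximal
#: to the person (individual) to most distal (societal).
LEVELS: tuple[str, ...] = ("individual", "relationship", "community", "societal")

_LEVEL_SET = frozenset(LEVELS)


@dataclass(frozen=True)
class Node:
    """A factor of the systems map.

    Parameters
    ----------
    id : str
        Opaque identifier, unique within a map.
    label : str
        Free-text factor name, e.g. ``"Bullying"`` or ``"ACEs of siblings"``.
    levels : frozenset of str
        Non-empty subset of :data:`LEVELS`.  A factor may sit at several
        levels at once (e.g. a community- and societal-level policy factor).
    """

    id: str
    label: str
    levels: frozenset

    def __post_init__(self):
        if not self.levels:
            raise ValidationError(f"node {self.id!r}: empty level set")
        unknown = set(self.levels) - _LEVEL_SET
        if unknown:
            raise ValidationError(
                f"node {self.id!r}: unknown level(s) {sorted(unknown)}; "
                f"allowed: {list(LEVELS)}"
            )


@dataclass(frozen=True)
class Edge:
    """A directed causal link: ``source`` contributes to ``target``."""

    source: str
    target: str


@dataclass
class ValidationReport:
    """Findings from :func:`validate_map`: warnings are advisory, errors fatal."""

    warnings: list = field(default_factory=list)
    errors: list = field(default_factory=list)

    def __bool__(self) -> bool:
        return bool(self.warnings or self.errors)

    @property
    def ok(self) -> bool:
        return not self.errors


class SystemsMap:
    """A directed map of factors with social-ecological level tags.

    Nodes are kept in insertion order; edges are deduplicated on the ordered
    pair ``(source, target)`` — the reverse pair, if present, is a distinct
    edge of the map.
    """

    def __init__(self, nodes: Iterable[Node], edges: Iterable[Edge]):
        self._nodes: dict[str, Node] = {}
        for node in nodes:
            if node.id in self._nodes:
                raise IntegrityError(f"duplicate node id {node.id!r}")
            self._nodes[node.id] = node
        self._edges: list[Edge] = []
        seen: set[tuple[str, str]] = set()
        n_dupes = 0
        for edge in edges:
            for endpoint in (edge.source, edge.target):
                if endpoint not in self._nodes:
                    raise IntegrityError(
                        f"edge ({edge.source!r}, {edge.target!r}) references "
                        f"unknown node {endpoint!r}"
                    )
            key = (edge.source, edge.target)
            if key in seen:
                n_dupes += 1
                continue
            seen.add(key)
            self._edges.append(edge)
        if n_dupes:
            logger.warning("dropped %d duplicate edge row(s)", n_dupes)

    @property
    def nodes(self) -> tuple[Node, ...]:
        return tuple(self._nodes.values())

    @property
    def edges(self) -> tuple[Edge, ...]:
        return tuple(self._edges)

    @property
    def node_ids(self) -> tuple[str, ...]:
        return tuple(self._nodes)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._nodes

    def __getitem__(self, node_id: str) -> Node:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise KeyError(f"unknown node id {node_id!r}") from None

    def neighbors(self, node_id: str) -> tuple[str, ...]:
        """Ids of all in- and out-neighbors of ``node_id`` (self excluded, deduplicated)."""
        if node_id not in self._nodes:
            raise KeyError(f"unknown node id {node_id!r}")
        out: dict[str, None] = {}
        for e in self._edges:
            if e.source == node_id and e.target != node_id:
                out.setdefault(e.target)
            if e.target == node_id and e.source != node_id:
                out.setdefault(e.source)
        return tuple(out)

    def to_networkx(self) -> nx.DiGraph:
        """Export as a :class:`networkx.DiGraph` with ``label`` and ``levels`` attributes."""
        g = nx.DiGraph()
        for node in self.nodes:
            g.add_node(node.id, label=node.label, levels=";".join(sorted(node.levels)))
        g.add_edges_from((e.source, e.target) for e in self.edges)
        return g

    def __repr__(self) -> str:
        return f"SystemsMap(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


def _require_columns(fieldnames, required, path):
    missing = [c for c in required if c not in (fieldnames or [])]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def _parse_levels(cell: str, delimiter: str, node_id: str) -> frozenset:
    tokens = [t.strip().lower() for t in cell.split(delimiter)]
    tokens = [t for t in tokens if t]
    if not tokens:
        raise ValidationError(f"node {node_id!r}: empty levels cell")
    return frozenset(tokens)


def read_map(nodes_path, edges_path, level_delimiter: str = ";") -> SystemsMap:
    """Read a systems map from a node CSV and an edge CSV.

    The node table needs columns ``id,label,levels``; the edge table needs
    ``source,target``.  Duplicate edge rows are collapsed to one edge with a
    logged warning; an edge naming an unknown node is an integrity error.
    """
    nodes_path, edges_path = Path(nodes_path), Path(edges_path)
    nodes: list[Node] = []
    with nodes_path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader.fieldnames, ("id", "label", "levels"), nodes_path)
        for row in reader:
            node_id = row["id"].strip()
            nodes.append(
                Node(
                    id=node_id,
                    label=row["label"].strip(),
                    levels=_parse_levels(row["levels"], level_delimiter, node_id),
                )
            )
    known = {n.id for n in nodes}
    edges: list[Edge] = []
    bad_rows: list[str] = []
    with edges_path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader.fieldnames, ("source", "target"), edges_path)
        for lineno, row in enumerate(reader, start=2):
            src, tgt = row["source"].strip(), row["target"].strip()
            unknown = [x for x in (src, tgt) if x not in known]
            if unknown:
                bad_rows.append(f"line {lineno}: ({src!r}, {tgt!r}) unknown {unknown}")
                continue
            edges.append(Edge(src, tgt))
    if bad_rows:
        raise IntegrityError(
            f"{edges_path}: {len(bad_rows)} edge row(s) reference unknown nodes:\n  "
            + "\n  ".join(bad_rows)
        )
    return SystemsMap(nodes, edges)


def write_map(smap: SystemsMap, nodes_path, edges_path, level_delimiter: str = ";") -> None:
    """Write the map back in the same CSV dialect :func:`read_map` reads."""
    with Path(nodes_path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "label", "levels"])
        for node in smap.nodes:
            writer.writerow([node.id, node.label, level_delimiter.join(sorted(node.levels))])
    with Path(edges_path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "target"])
        for edge in smap.edges:
            writer.writerow([edge.source, edge.target])


def write_graphml(smap: SystemsMap, path) -> None:
    """Export the map as GraphML (node attributes: label, levels as a string)."""
    nx.write_graphml(smap.to_networkx(), str(path))


def validate_map(smap: SystemsMap) -> ValidationReport:
    """Report self-loops (warnings, retained) and isolated nodes (warnings).

    Structural invariants — endpoint referential integrity, unique node ids,
    non-empty level sets — are enforced at construction time, so a map object
    that exists already satisfies them; this reporting pass surfaces the
    advisory findings a human reviewer should see.
    """
    report = ValidationReport()
    incident: set[str] = set()
    for edge in smap.edges:
        if edge.source == edge.target:
            report.warnings.append(f"self-loop on node {edge.source!r} (retained)")
        incident.add(edge.source)
        incident.add(edge.target)
    for node in smap.nodes:
        if node.id not in incident:
            report.warnings.append(f"isolated node {node.id!r} ({node.label!r})")
    return report
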