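"""Embedded property-graph store with schema validation and TSV/JSON/GML I/O.

The store replaces a server-backed graph database with an in-memory typed
property graph: nodes carry a label and an attribute map, directed edges carry
a relationship type and an attribute map.  A :class:`SchemaDefinition`
constrains which labels exist and which (type, source label, target label)
triples are legal; the bundled default schema defines the full clinical
proteomics data model (36 node labels, 47 relationship types).

Parallel edges with identical (source, target, type) are collapsed into one
edge; a numeric ``score`` attribute, when present on both sides, keeps its
maximum (redundant knowledge sources reporting the same association should
not multiply edges, and the strongest evidence wins).
"""

from __future__ import annotations

import json
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx
import yaml

__all__ = [
    "SchemaDefinition",
    "PropertyGraph",
    "GraphPattern",
    "ViolationReport",
    "LoadResult",
    "GraphFormatError",
    "SchemaViolationError",
    "ReferentialError",
    "default_schema",
    "load_graph_tsv",
    "validate_schema",
    "export_graph",
    "import_graph",
]


class GraphFormatError(ValueError):
    """A graph file is malformed (missing column, bad stanza, bad format)."""


class SchemaViolationError(ValueError):
    """Data contradicts the active schema."""


class ReferentialError(ValueError):
    """An edge references a node that does not exist."""


# ---------------------------------------------------------------------------
# schema
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SchemaDefinition:
    """Allowed node labels, relationship triples and required attributes."""

    node_labels: frozenset
    relationship_types: frozenset  # of (type_name, source_label, target_label)
    required_attributes: Mapping[str, tuple] = field(default_factory=dict)

    def __post_init__(self):
        for label in self.node_labels:
            if not label or not isinstance(label, str):
                raise SchemaViolationError(f"invalid node label: {label!r}")
        for name, src, tgt in self.relationship_types:
            if not name:
                raise SchemaViolationError("empty relationship type name")
            for endpoint in (src, tgt):
                if endpoint not in self.node_labels:
                    raise SchemaViolationError(
                        f"relationship {name} endpoint {endpoint!r} is not a declared node label"
                    )

    @property
    def type_names(self) -> frozenset:
        return frozenset(name for name, _, _ in self.relationship_types)

    def allows_label(self, label: str) -> bool:
        return label in self.node_labels

    def allows_edge(self, type_name: str, source_label: str, target_label: str) -> bool:
        return (type_name, source_label, target_label) in self.relationship_types

    @classmethod
    def from_yaml(cls, path) -> "SchemaDefinition":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SchemaDefinition":
        labels = frozenset(raw["node_labels"])
        triples = frozenset(
            (name, src, tgt)
            for name, pairs in raw["relationship_types"].items()
            for src, tgt in pairs
        )
        required = {
            label: tuple(attrs) for label, attrs in (raw.get("required_attributes") or {}).items()
        }
        return cls(node_labels=labels, relationship_types=triples, required_attributes=required)


def default_schema() -> SchemaDefinition:
    """The bundled clinical proteomics data model (36 labels, 47 types)."""
    ref = resources.files("protokg.defaults").joinpath("data_model.yml")
    with resources.as_file(ref) as path:
        return SchemaDefinition.from_yaml(path)


# ---------------------------------------------------------------------------
# property graph
# ---------------------------------------------------------------------------


@dataclass
class GraphPattern:
    """Neighborhood query: expand from seeds up to ``max_hops`` hops.

    Empty/None filters mean "no restriction".
    """

    seed_ids: set
    edge_types: set | None = None
    target_labels: set | None = None
    max_hops: int = 1

    def __post_init__(self):
        if self.max_hops < 1:
            raise ValueError("max_hops must be >= 1")


@dataclass
class ViolationReport:
    node_violations: list = field(default_factory=list)  # (node_id, label)
    edge_violations: list = field(default_factory=list)  # (source, target, type, triple)

    @property
    def ok(self) -> bool:
        return not self.node_violations and not self.edge_violations

    def __len__(self) -> int:
        return len(self.node_violations) + len(self.edge_violations)


class PropertyGraph:
    """Typed nodes plus typed directed edges, both with attribute maps."""

    def __init__(self, schema: SchemaDefinition | None = None, validate: bool = False):
        self.schema = schema
        self.validate = validate
        self._nodes: dict = {}  # node_id -> (label, attrs dict)
        self._edges: dict = {}  # (source, target, type) -> attrs dict

    # -- construction -------------------------------------------------------

    def add_node(self, node_id: str, label: str, attributes: Mapping | None = None) -> bool:
        """Insert or update a node. Returns True when an existing node was
        updated (duplicate-id collapse, last-write-wins on attributes)."""
        if self.validate and self.schema is not None and not self.schema.allows_label(label):
            raise SchemaViolationError(f"label {label!r} not in schema")
        existed = node_id in self._nodes
        if existed:
            old_label, old_attrs = self._nodes[node_id]
            merged = dict(old_attrs)
            merged.update(attributes or {})
            self._nodes[node_id] = (label, merged)
        else:
            self._nodes[node_id] = (label, dict(attributes or {}))
        return existed

    def add_edge(self, source: str, target: str, type_name: str,
                 attributes: Mapping | None = None) -> None:
        if source not in self._nodes or target not in self._nodes:
            raise ReferentialError(
                f"edge {source}-[{type_name}]->{target} references a missing node"
            )
        if self.validate and self.schema is not None:
            triple = (type_name, self.label_of(source), self.label_of(target))
            if not self.schema.allows_edge(*triple):
                raise SchemaViolationError(f"edge triple {triple} not in schema")
        key = (source, target, type_name)
        attrs = dict(attributes or {})
        if key in self._edges:
            old = self._edges[key]
            # collapse multi-edge: max numeric score, last write wins otherwise
            if "score" in old and "score" in attrs:
                try:
                    attrs["score"] = max(old["score"], attrs["score"])
                except TypeError:
                    pass
            merged = dict(old)
            merged.update(attrs)
            self._edges[key] = merged
        else:
            self._edges[key] = attrs

    # -- accessors ----------------------------------------------------------

    @property
    def node_ids(self):
        return list(self._nodes)

    @property
    def nodes(self) -> dict:
        return dict(self._nodes)

    @property
    def edges(self) -> list:
        """Edges as (source, target, type, attrs) tuples in insertion order."""
        return [(s, t, ty, dict(a)) for (s, t, ty), a in self._edges.items()]

    def __contains__(self, node_id) -> bool:
        return node_id in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def label_of(self, node_id: str) -> str:
        return self._nodes[node_id][0]

    def attributes_of(self, node_id: str) -> dict:
        return dict(self._nodes[node_id][1])

    def nodes_by_label(self, label: str) -> list:
        return [nid for nid, (lab, _) in self._nodes.items() if lab == label]

    def edge_attributes(self, source: str, target: str, type_name: str) -> dict:
        return dict(self._edges[(source, target, type_name)])

    def neighbors(self, node_id: str, edge_types: Iterable | None = None,
                  direction: str = "both") -> set:
        """Adjacent (neighbor_id, edge_type) pairs via permitted types."""
        if node_id not in self._nodes:
            raise KeyError(f"unknown node id {node_id!r}")
        if direction not in ("in", "out", "both"):
            raise ValueError(f"direction must be in/out/both, got {direction!r}")
        allowed = set(edge_types) if edge_types else None
        out = set()
        for (s, t, ty) in self._edges:
            if allowed is not None and ty not in allowed:
                continue
            if s == node_id and direction in ("out", "both"):
                out.add((t, ty))
            if t == node_id and direction in ("in", "both"):
                out.add((s, ty))
        return out

    # -- queries ------------------------------------------------------------

    def subgraph_by_pattern(self, pattern: GraphPattern) -> "PropertyGraph":
        """Induced subgraph of nodes reachable from the seeds within
        ``max_hops`` via permitted edge types, optionally pruned to
        ``target_labels`` (seeds always kept)."""
        missing = [s for s in pattern.seed_ids if s not in self._nodes]
        if missing:
            raise KeyError(f"unknown seed ids: {sorted(missing)}")
        frontier = set(pattern.seed_ids)
        reached = set(frontier)
        for _ in range(pattern.max_hops):
            nxt = set()
            for nid in frontier:
                for nbr, _ty in self.neighbors(nid, edge_types=pattern.edge_types):
                    if nbr not in reached:
                        nxt.add(nbr)
            if not nxt:
                break
            reached |= nxt
            frontier = nxt
        if pattern.target_labels:
            reached = {
                nid for nid in reached
                if nid in pattern.seed_ids or self.label_of(nid) in pattern.target_labels
            }
        return self.induced_subgraph(reached, edge_types=pattern.edge_types)

    def induced_subgraph(self, node_ids: Iterable, edge_types: Iterable | None = None
                         ) -> "PropertyGraph":
        keep = set(node_ids)
        allowed = set(edge_types) if edge_types else None
        sub = PropertyGraph(schema=self.schema, validate=False)
        for nid in self._nodes:
            if nid in keep:
                label, attrs = self._nodes[nid]
                sub.add_node(nid, label, attrs)
        for (s, t, ty), attrs in self._edges.items():
            if s in keep and t in keep and (allowed is None or ty in allowed):
                sub.add_edge(s, t, ty, attrs)
        return sub

    def to_networkx(self, directed: bool = True) -> "nx.Graph":
        g = nx.DiGraph() if directed else nx.Graph()
        for nid, (label, attrs) in self._nodes.items():
            g.add_node(nid, label=label, **attrs)
        for (s, t, ty), attrs in self._edges.items():
            g.add_edge(s, t, type=ty, **attrs)
        return g


def validate_schema(graph: PropertyGraph, schema: SchemaDefinition | None = None
                    ) -> ViolationReport:
    """Report every node with an unknown label and every edge whose
    (type, source label, target label) triple is not in the schema."""
    schema = schema or graph.schema
    if schema is None:
        raise ValueError("no schema attached to graph and none supplied")
    report = ViolationReport()
    for nid, (label, attrs) in graph.nodes.items():
        if not schema.allows_label(label):
            report.node_violations.append((nid, label))
            continue
        for req in schema.required_attributes.get(label, ()):  # pragma: no branch
            if req not in attrs:
                report.node_violations.append((nid, f"{label}: missing attribute {req}"))
    for s, t, ty, _attrs in graph.edges:
        src_label = graph.label_of(s)
        tgt_label = graph.label_of(t)
        if not schema.allows_label(src_label) or not schema.allows_label(tgt_label):
            continue  # already reported as node violations
        if not schema.allows_edge(ty, src_label, tgt_label):
            report.edge_violations.append((s, t, ty, (ty, src_label, tgt_label)))
    return report


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------
# UTF-8, tab-separated, header row. Cell escaping: backslash, tab and newline
# are written as \\ , \t and \n. Empty cells denote absent attributes.
# Attribute scalars that parse as int/float are restored as numbers.


def _escape(value: str) -> str:
    return (
        str(value)
        .replace("\\", "\\\\")
        .replace("\t", "\\t")
        .replace("\n", "\\n")
        .replace("\r", "\\r")
    )


def _unescape(cell: str) -> str:
    out = []
    i = 0
    while i < len(cell):
        c = cell[i]
        if c == "\\" and i + 1 < len(cell):
            nxt = cell[i + 1]
            out.append({"t": "\t", "n": "\n", "r": "\r", "\\": "\\"}.get(nxt, nxt))
            i += 2
        else:
            out.append(c)
            i += 1
    return "".join(out)


def _parse_scalar(cell: str):
    try:
        return int(cell)
    except ValueError:
        pass
    try:
        return float(cell)
    except ValueError:
        return cell


def _format_scalar(value) -> str:
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _read_tsv_rows(path) -> tuple:
    with open(path, encoding="utf-8", newline="") as fh:
        text = fh.read()
    lines = [ln for ln in text.split("\n") if ln != ""]
    if not lines:
        raise GraphFormatError(f"{path}: empty file")
    header = [_unescape(c) for c in lines[0].split("\t")]
    rows = [[_unescape(c) for c in ln.split("\t")] for ln in lines[1:]]
    return header, rows


@dataclass
class LoadResult:
    graph: PropertyGraph
    collapsed_nodes: int = 0
    dropped_edges: int = 0
    warnings: list = field(default_factory=list)


def load_graph_tsv(nodes_path, edges_path, schema: SchemaDefinition | None = None,
                   validate: bool = True) -> LoadResult:
    """Load a graph from the two-file TSV dialect.

    Nodes file columns: ID, LABEL plus attribute columns; edges file columns:
    START_ID, END_ID, TYPE plus attribute columns.  With ``validate`` on,
    schema violations and dangling edges raise; with it off, dangling edges
    are dropped with a warning count.
    """
    header, rows = _read_tsv_rows(nodes_path)
    for col in ("ID", "LABEL"):
        if col not in header:
            raise GraphFormatError(f"{nodes_path}: missing mandatory column {col}")
    id_ix, label_ix = header.index("ID"), header.index("LABEL")
    attr_cols = [(i, name) for i, name in enumerate(header) if name not in ("ID", "LABEL")]
    graph = PropertyGraph(schema=schema, validate=validate and schema is not None)
    result = LoadResult(graph=graph)
    for row in rows:
        attrs = {
            name: _parse_scalar(row[i]) for i, name in attr_cols if i < len(row) and row[i] != ""
        }
        if graph.add_node(row[id_ix], row[label_ix], attrs):
            result.collapsed_nodes += 1

    header, rows = _read_tsv_rows(edges_path)
    for col in ("START_ID", "END_ID", "TYPE"):
        if col not in header:
            raise GraphFormatError(f"{edges_path}: missing mandatory column {col}")
    s_ix, e_ix, t_ix = header.index("START_ID"), header.index("END_ID"), header.index("TYPE")
    attr_cols = [
        (i, name) for i, name in enumerate(header) if name not in ("START_ID", "END_ID", "TYPE")
    ]
    bad_rows = []
    for rownum, row in enumerate(rows, start=2):
        s, t, ty = row[s_ix], row[e_ix], row[t_ix]
        attrs = {
            name: _parse_scalar(row[i]) for i, name in attr_cols if i < len(row) and row[i] != ""
        }
        if s not in graph or t not in graph:
            if validate:
                bad_rows.append((rownum, s, t, ty))
                continue
            result.dropped_edges += 1
            result.warnings.append(f"line {rownum}: edge {s}-[{ty}]->{t} references missing node")
            continue
        graph.add_edge(s, t, ty, attrs)
    if bad_rows:
        raise ReferentialError(
            f"{edges_path}: edges reference absent nodes at rows {bad_rows}"
        )
    return result


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

_GML_SAFE = str.maketrans({c: "_" for c in " -./:()[]{}"})


def _gml_key(name: str) -> str:
    # GML keys must be alphanumeric; non-conforming characters map to '_'
    key = name.translate(_GML_SAFE)
    return "".join(ch if ch.isalnum() or ch == "_" else "_" for ch in key)


def export_graph(graph: PropertyGraph, path, format: str = "tsv") -> list:
    """Write the graph under ``path``; returns the list of files written.

    ``tsv`` writes ``nodes.tsv``/``edges.tsv`` into the directory ``path``;
    ``json`` writes a single file with "nodes"/"edges" arrays; ``gml`` and
    ``graphml`` write Cytoscape-compatible files (attribute names mangled to
    alphanumerics for GML).
    """
    path = Path(path)
    if format == "tsv":
        path.mkdir(parents=True, exist_ok=True)
        node_attrs = sorted({k for _nid, (_l, a) in graph.nodes.items() for k in a})
        nodes_file = path / "nodes.tsv"
        with open(nodes_file, "w", encoding="utf-8", newline="") as fh:
            fh.write("\t".join(["ID", "LABEL"] + node_attrs) + "\n")
            for nid, (label, attrs) in graph.nodes.items():
                cells = [_escape(nid), _escape(label)] + [
                    _escape(_format_scalar(attrs[k])) if k in attrs else "" for k in node_attrs
                ]
                fh.write("\t".join(cells) + "\n")
        edge_attrs = sorted({k for _s, _t, _ty, a in graph.edges for k in a})
        edges_file = path / "edges.tsv"
        with open(edges_file, "w", encoding="utf-8", newline="") as fh:
            fh.write("\t".join(["START_ID", "END_ID", "TYPE"] + edge_attrs) + "\n")
            for s, t, ty, attrs in graph.edges:
                cells = [_escape(s), _escape(t), _escape(ty)] + [
                    _escape(_format_scalar(attrs[k])) if k in attrs else "" for k in edge_attrs
                ]
                fh.write("\t".join(cells) + "\n")
        return [nodes_file, edges_file]
    if format == "json":
        payload = {
            "nodes": [
                {"id": nid, "label": label, "attributes": attrs}
                for nid, (label, attrs) in graph.nodes.items()
            ],
            "edges": [
                {"source": s, "target": t, "type": ty, "attributes": attrs}
                for s, t, ty, attrs in graph.edges
            ],
        }
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return [path]
    if format in ("gml", "graphml"):
        g = graph.to_networkx(directed=True)
        path.parent.mkdir(parents=True, exist_ok=True)
        if format == "gml":
            g = nx.relabel_nodes(g, {n: str(n) for n in g})
            mangled = nx.DiGraph()
            for n, data in g.nodes(data=True):
                mangled.add_node(n, **{_gml_key(k): v for k, v in data.items()})
            for u, v, data in g.edges(data=True):
                mangled.add_edge(u, v, **{_gml_key(k): v for k, v in data.items()})
            nx.write_gml(mangled, path)
        else:
            nx.write_graphml(g, path)
        return [path]
    raise ValueError(f"unknown export format {format!r}")


def import_graph(path, format: str = "tsv", schema: SchemaDefinition | None = None,
                 validate: bool = False) -> PropertyGraph:
    """Inverse of :func:`export_graph` for the tsv and json dialects."""
    path = Path(path)
    if format == "tsv":
        return load_graph_tsv(path / "nodes.tsv", path / "edges.tsv", schema=schema,
                              validate=validate).graph
    if format == "json":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        graph = PropertyGraph(schema=schema, validate=validate and schema is not None)
        for node in payload["nodes"]:
            graph.add_node(node["id"], node["label"], node.get("attributes") or {})
        for edge in payload["edges"]:
            graph.add_edge(edge["source"], edge["target"], edge["type"],
                           edge.get("attributes") or {})
        return graph
    raise ValueError(f"unknown import format {format!r}")
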