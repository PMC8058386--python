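"""Readers and writers for pathway files: XGMML, GraphML and a JSON dialect.

All three formats carry the same attributes (``node_type``, ``sign``,
``operator``, ``members``, ``branch``, the boolean ``sink`` flag) and any
extra attributes are preserved round-trip as opaque annotations.  Attribute
names are matched case-insensitively on read.  Writers emit elements sorted
by node id so that two writes of the same pathway are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
from lxml import etree

from .pathway import (
    Pathway,
    PathwayEdge,
    PathwayNode,
    PathwayValidationError,
    require_valid,
)

FORMATS = ("xgmml", "graphml", "json")

_XGMML_NS = "http://www.cs.rpi.edu/XGMML"

# attribute names owned by the data model; everything else is an annotation
_RESERVED = {"label", "node_type", "operator", "members", "branch", "sign", "sink"}


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in FORMATS:
            raise ValueError(f"unknown pathway format {fmt!r}; expected one of {FORMATS}")
        return fmt
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in FORMATS:
        return suffix
    raise ValueError(f"cannot infer pathway format from {path!r}; pass format=")


def _node_attrs(node: PathwayNode) -> dict[str, str]:
    """Flat, ordered string attributes for serialization."""
    attrs: dict[str, str] = {"node_type": node.node_type}
    if node.operator is not None:
        attrs["operator"] = node.operator
    if node.members:
        attrs["members"] = ",".join(node.members)
    if node.branch is not None:
        attrs["branch"] = node.branch
    if node.sign is not None:
        attrs["sign"] = node.sign
    for key in sorted(node.annotations):
        attrs[key] = str(node.annotations[key])
    return attrs


def _build_node(node_id: str, label: str, attrs: dict[str, str], sink: bool) -> PathwayNode:
    lowered = {k.lower(): v for k, v in attrs.items()}
    node_type = lowered.pop("node_type", "sink" if sink else "gene")
    operator = lowered.pop("operator", None)
    members = tuple(m for m in lowered.pop("members", "").split(",") if m)
    branch = lowered.pop("branch", None)
    sign = lowered.pop("sign", None)
    lowered.pop("sink", None)
    lowered.pop("label", None)
    return PathwayNode(
        id=node_id,
        label=label or node_id,
        node_type=node_type,
        operator=operator,
        members=members,
        branch=branch,
        sign=sign,
        annotations=lowered,
    )


def _sorted_nodes(pathway: Pathway) -> list[PathwayNode]:
    return [pathway.nodes[k] for k in sorted(pathway.nodes)]


def _sorted_edges(pathway: Pathway) -> list[PathwayEdge]:
    return sorted(pathway.edges, key=lambda e: (e.source, e.target, e.sign))


# ---------------------------------------------------------------------------
# JSON dialect


def _to_json_obj(pathway: Pathway) -> dict:
    return {
        "name": pathway.name,
        "version": pathway.version,
        "sink": pathway.sink,
        "nodes": [
            {"id": n.id, "label": n.label, **_node_attrs(n)} for n in _sorted_nodes(pathway)
        ],
        "edges": [
            {"source": e.source, "target": e.target, "sign": e.sign}
            for e in _sorted_edges(pathway)
        ],
    }


def _from_json_obj(obj: dict) -> Pathway:
    sink = obj.get("sink")
    if sink is None:
        raise PathwayValidationError("pathway JSON lacks a 'sink' field")
    nodes = []
    for raw in obj.get("nodes", []):
        raw = dict(raw)
        node_id = raw.pop("id")
        label = raw.pop("label", node_id)
        nodes.append(_build_node(node_id, label, raw, sink=node_id == sink))
    edges = [
        PathwayEdge(e["source"], e["target"], e.get("sign", "activation"))
        for e in obj.get("edges", [])
    ]
    return Pathway(
        name=obj.get("name", ""),
        version=obj.get("version", ""),
        nodes=nodes,
        edges=edges,
        sink=sink,
    )


# ---------------------------------------------------------------------------
# XGMML (Cytoscape-style)


def _write_xgmml(pathway: Pathway, path: Path) -> None:
    root = etree.Element(
        "graph",
        attrib={"label": pathway.name, "directed": "1"},
        nsmap={None: _XGMML_NS},
    )
    meta = etree.SubElement(root, "att", name="version", value=pathway.version)
    meta.set("type", "string")
    for node in _sorted_nodes(pathway):
        el = etree.SubElement(root, "node", id=node.id, label=node.label)
        attrs = _node_attrs(node)
        attrs["sink"] = "1" if node.id == pathway.sink else "0"
        for key in attrs:
            att = etree.SubElement(el, "att", name=key, value=attrs[key])
            att.set("type", "string")
    for edge in _sorted_edges(pathway):
        el = etree.SubElement(
            root, "edge", source=edge.source, target=edge.target,
            label=f"{edge.source} ({edge.sign}) {edge.target}",
        )
        att = etree.SubElement(el, "att", name="sign", value=edge.sign)
        att.set("type", "string")
    data = etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )
    path.write_bytes(data)


def _read_xgmml(path: Path) -> Pathway:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise PathwayValidationError(f"cannot parse XGMML file {path}: {exc}") from exc
    root = tree.getroot()

    def local(tag: str) -> str:
        return etree.QName(tag).localname if "}" in tag else tag

    if local(root.tag) != "graph":
        raise PathwayValidationError(f"{path}: root element is not <graph>")
    name = root.get("label", "")
    version = ""
    nodes: list[tuple[str, str, dict[str, str]]] = []
    edges: list[PathwayEdge] = []
    sink = None
    for el in root:
        tag = local(el.tag)
        if tag == "att" and el.get("name", "").lower() == "version":
            version = el.get("value", "")
        elif tag == "node":
            node_id = el.get("id")
            if node_id is None:
                raise PathwayValidationError(f"{path}: <node> without id")
            attrs = {
                a.get("name", ""): a.get("value", "")
                for a in el
                if local(a.tag) == "att"
            }
            if attrs.get("sink", attrs.get("SINK", "0")).lower() in {"1", "true", "yes"}:
                sink = node_id
            nodes.append((node_id, el.get("label", node_id), attrs))
        elif tag == "edge":
            source, target = el.get("source"), el.get("target")
            if source is None or target is None:
                raise PathwayValidationError(f"{path}: <edge> missing endpoints")
            sign = "activation"
            for a in el:
                if local(a.tag) == "att" and a.get("name", "").lower() == "sign":
                    sign = a.get("value", sign)
            edges.append(PathwayEdge(source, target, sign))
    if sink is None:
        raise PathwayValidationError(f"{path}: no node is flagged as the sink")
    built = [
        _build_node(node_id, label, attrs, sink=node_id == sink)
        for node_id, label, attrs in nodes
    ]
    return Pathway(name=name, version=version, nodes=built, edges=edges, sink=sink)


# ---------------------------------------------------------------------------
# GraphML (via networkx)


def _write_graphml(pathway: Pathway, path: Path) -> None:
    g = nx.DiGraph(name=pathway.name, version=pathway.version, sink=pathway.sink)
    for node in _sorted_nodes(pathway):
        attrs = _node_attrs(node)
        attrs["label"] = node.label
        g.add_node(node.id, **attrs)
    for edge in _sorted_edges(pathway):
        g.add_edge(edge.source, edge.target, sign=edge.sign)
    nx.write_graphml(g, path, encoding="utf-8")


def _read_graphml(path: Path) -> Pathway:
    try:
        g = nx.read_graphml(path)
    except Exception as exc:  # networkx wraps lxml/expat errors variously
        raise PathwayValidationError(f"cannot parse GraphML file {path}: {exc}") from exc
    sink = g.graph.get("sink")
    if sink is None:
        raise PathwayValidationError(f"{path}: graph lacks a 'sink' attribute")
    nodes = []
    for node_id, data in g.nodes(data=True):
        data = {k: str(v) for k, v in data.items()}
        label = data.pop("label", node_id)
        nodes.append(_build_node(node_id, label, data, sink=node_id == sink))
    edges = [
        PathwayEdge(u, v, d.get("sign", "activation")) for u, v, d in g.edges(data=True)
    ]
    return Pathway(
        name=g.graph.get("name", ""),
        version=str(g.graph.get("version", "")),
        nodes=nodes,
        edges=edges,
        sink=sink,
    )


# ---------------------------------------------------------------------------
# public API


def read_pathway(path: str | Path, format: str | None = None) -> Pathway:
    """Read and validate a pathway file.

    Parameters
    ----------
    path
        File to read.
    format
        ``"xgmml"``, ``"graphml"`` or ``"json"``; inferred from the file
        extension when omitted.

    Raises
    ------
    PathwayValidationError
        On parse failure, a missing sink designation, or any model violation
        (unknown node type / edge sign / operator, cycles, ...), with the
        offending element named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"pathway file not found: {path}")
    fmt = _infer_format(path, format)
    if fmt == "json":
        try:
            obj = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise PathwayValidationError(f"cannot parse JSON file {path}: {exc}") from exc
        pathway = _from_json_obj(obj)
    elif fmt == "xgmml":
        pathway = _read_xgmml(path)
    else:
        pathway = _read_graphml(path)
    return require_valid(pathway)


def write_pathway(pathway: Pathway, path: str | Path, format: str | None = None) -> None:
    """Write a pathway with deterministic (sorted, byte-stable) output."""
    require_valid(pathway)
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        path.write_text(json.dumps(_to_json_obj(pathway), indent=1) + "\n")
    elif fmt == "xgmml":
        _write_xgmml(pathway, path)
    else:
        _write_graphml(pathway, path)
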