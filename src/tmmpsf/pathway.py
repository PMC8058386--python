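"""Typed pathway graphs for telomere-maintenance signalling.

A :class:`Pathway` is a directed acyclic graph of typed nodes — genes,
complexes, operator (linker) nodes, process/event nodes and a single sink —
connected by signed (activation / inhibition) edges.  The sink's propagated
signal summarises the activity of the whole pathway; everything downstream
(scoring, influence analysis, phenotyping) consumes this data model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

NODE_TYPES = frozenset({"gene", "complex", "linker", "process", "sink"})
EDGE_SIGNS = frozenset({"activation", "inhibition"})
LINKER_OPERATORS = frozenset({"min", "max", "sum"})


class PathwayValidationError(ValueError):
    """Raised when a pathway (or a serialized pathway file) violates the model."""


@dataclass(frozen=True)
class PathwayNode:
    """A single pathway node.

    Parameters
    ----------
    id
        Unique identifier within the pathway.
    label
        Display name (defaults to ``id``).
    node_type
        One of ``gene``, ``complex``, ``linker``, ``process``, ``sink``.
    operator
        Signal-combination operator (``min``/``max``/``sum``); required for
        linker nodes and forbidden elsewhere.
    members
        Gene node ids constituting a complex; only for complex nodes.
    branch
        Optional event-block tag, e.g. ``"hTR maturation"``.
    sign
        Net effect annotation (``"+"``/``"-"``) carried by gene nodes.
    annotations
        Opaque extra attributes preserved on round-trip.
    """

    id: str
    label: str = ""
    node_type: str = "gene"
    operator: str | None = None
    members: tuple[str, ...] = ()
    branch: str | None = None
    sign: str | None = None
    annotations: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.label:
            object.__setattr__(self, "label", self.id)
        object.__setattr__(self, "members", tuple(self.members))
        object.__setattr__(self, "annotations", dict(self.annotations))


@dataclass(frozen=True)
class PathwayEdge:
    """Signed directed interaction between two nodes."""

    source: str
    target: str
    sign: str = "activation"


class Pathway:
    """A named, versioned DAG with one designated sink node."""

    def __init__(
        self,
        name: str,
        nodes: Iterable[PathwayNode],
        edges: Iterable[PathwayEdge],
        sink: str,
        version: str = "",
    ) -> None:
        self.name = name
        self.version = version
        self.sink = sink
        self.nodes: dict[str, PathwayNode] = {}
        for node in nodes:
            if node.id in self.nodes:
                raise PathwayValidationError(f"duplicate node id {node.id!r}")
            self.nodes[node.id] = node
        self.edges: list[PathwayEdge] = list(edges)
        self._graph: nx.DiGraph | None = None

    # -- container conveniences -------------------------------------------------

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, node_id: str) -> PathwayNode:
        try:
            return self.nodes[node_id]
        except KeyError:
            raise KeyError(f"no node {node_id!r} in pathway {self.name!r}") from None

    @property
    def graph(self) -> nx.DiGraph:
        """The pathway as a :class:`networkx.DiGraph` (cached)."""
        if self._graph is None:
            g = nx.DiGraph()
            g.add_nodes_from(self.nodes)
            g.add_edges_from((e.source, e.target, {"sign": e.sign}) for e in self.edges)
            self._graph = g
        return self._graph

    def invalidate_cache(self) -> None:
        self._graph = None

    def gene_nodes(self) -> list[PathwayNode]:
        """All nodes of type ``gene``, sorted by id."""
        return sorted(
            (n for n in self.nodes.values() if n.node_type == "gene"),
            key=lambda n: n.id,
        )

    def gene_ids(self) -> list[str]:
        return [n.id for n in self.gene_nodes()]

    def parents(self, node_id: str) -> list[tuple[str, str]]:
        """Incoming ``(parent id, edge sign)`` pairs, sorted by parent id."""
        return sorted(
            (e.source, e.sign) for e in self.edges if e.target == node_id
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Pathway({self.name!r}, version={self.version!r}, "
            f"{len(self.nodes)} nodes, {len(self.edges)} edges)"
        )


def validate_pathway(pathway: Pathway) -> list[dict[str, str]]:
    """Check every structural invariant of the pathway model.

    Returns a list of violations (empty when valid); each violation is a dict
    with ``rule`` and ``element`` keys plus a human-readable ``message``.
    Violations are data, not exceptions, so callers can report them all.
    """
    violations: list[dict[str, str]] = []

    def flag(rule: str, element: str, message: str) -> None:
        violations.append({"rule": rule, "element": element, "message": message})

    for node in pathway.nodes.values():
        if node.node_type not in NODE_TYPES:
            flag("unknown_node_type", node.id, f"node type {node.node_type!r}")
        if node.node_type == "linker":
            if node.operator is None:
                flag("linker_missing_operator", node.id, "linker without operator")
            elif node.operator not in LINKER_OPERATORS:
                flag("unknown_operator", node.id, f"operator {node.operator!r}")
        elif node.operator is not None:
            flag("operator_on_non_linker", node.id, "operator on non-linker node")
        if node.node_type == "complex":
            if not node.members:
                # NuRD-style complexes without a published subunit list are
                # allowed but marked so callers can decide.
                pass
            for member in node.members:
                if member not in pathway.nodes:
                    flag("unknown_member", node.id, f"member {member!r} not in pathway")
                elif pathway.nodes[member].node_type != "gene":
                    flag("non_gene_member", node.id, f"member {member!r} is not a gene node")
        elif node.members:
            flag("members_on_non_complex", node.id, "members on non-complex node")

    ids = set(pathway.nodes)
    for edge in pathway.edges:
        name = f"{edge.source}->{edge.target}"
        if edge.source not in ids:
            flag("unknown_edge_source", name, f"source {edge.source!r} not in pathway")
        if edge.target not in ids:
            flag("unknown_edge_target", name, f"target {edge.target!r} not in pathway")
        if edge.source == edge.target:
            flag("self_loop", name, "self loop")
        if edge.sign not in EDGE_SIGNS:
            flag("unknown_edge_sign", name, f"edge sign {edge.sign!r}")

    if pathway.sink not in ids:
        flag("missing_sink", pathway.sink or "<none>", "designated sink not in pathway")
    else:
        sink_node = pathway.nodes[pathway.sink]
        if sink_node.node_type != "sink":
            flag("sink_not_sink_type", pathway.sink, "designated sink has wrong node type")
        if any(e.source == pathway.sink for e in pathway.edges):
            flag("sink_has_outgoing", pathway.sink, "sink has outgoing edges")

    others = [
        n.id
        for n in pathway.nodes.values()
        if n.node_type == "sink" and n.id != pathway.sink
    ]
    for node_id in others:
        flag("multiple_sinks", node_id, "more than one sink-type node")

    graph = pathway.graph
    if not violations or all(v["rule"].startswith(("linker", "operator")) for v in violations):
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            path = [cycle[0][0]] + [edge[1] for edge in cycle]
            flag("not_a_dag", "->".join(path), "cycle detected")
        elif pathway.sink in ids:
            # every source node must be able to reach the sink
            for node_id in sorted(ids):
                if graph.in_degree(node_id) == 0 and node_id != pathway.sink:
                    if not nx.has_path(graph, node_id, pathway.sink):
                        flag("source_cannot_reach_sink", node_id, "no path to sink")
    return violations


def require_valid(pathway: Pathway) -> Pathway:
    """Raise :class:`PathwayValidationError` listing all violations, if any."""
    violations = validate_pathway(pathway)
    if violations:
        lines = "; ".join(f"{v['rule']}[{v['element']}]" for v in violations)
        raise PathwayValidationError(
            f"pathway {pathway.name!r} is invalid: {lines}"
        )
    return pathway


def topological_order(pathway: Pathway) -> list[str]:
    """Deterministic topological order: ties broken by ascending node id."""
    graph = pathway.graph
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        path = [cycle[0][0]] + [edge[1] for edge in cycle]
        raise PathwayValidationError(
            f"pathway {pathway.name!r} contains a cycle: {path}"
        )
    return list(nx.lexicographical_topological_sort(graph))
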