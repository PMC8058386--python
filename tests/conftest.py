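"""Shared fixtures: toy pathways, random DAG generation and oracle evaluators."""

from __future__ import annotations

import math
import random

import pytest

from tmmpsf.pathway import Pathway, PathwayEdge, PathwayNode

SIGNAL_MIN, SIGNAL_MAX = 1e-6, 1e6


def _clip(x: float) -> float:
    return min(max(x, SIGNAL_MIN), SIGNAL_MAX)


def brute_force_psf(pathway: Pathway, fc: dict[str, float]) -> dict[str, float]:
    """Independent recursive evaluator of the propagation semantics.

    Memoized top-down recursion from each node to its parents; no use of a
    topological order.  Serves as the oracle for the iterative engine.
    """
    memo: dict[str, float] = {}

    def signal(node_id: str) -> float:
        if node_id in memo:
            return memo[node_id]
        node = pathway.nodes[node_id]
        own = float(fc.get(node_id, 1.0)) if node.node_type == "gene" else 1.0
        incoming = sorted(
            (e.source, e.sign) for e in pathway.edges if e.target == node_id
        )
        if not incoming:
            result = _clip(own)
        else:
            contribs = [
                _clip(signal(src)) if sign == "activation" else 1.0 / _clip(signal(src))
                for src, sign in incoming
            ]
            if node.node_type == "linker":
                combined = {"min": min, "max": max, "sum": sum}[node.operator](contribs)
            elif node.node_type == "complex":
                combined = min(contribs)
            else:
                combined = math.prod(contribs)
            result = _clip(own * combined)
        memo[node_id] = result
        return result

    return {node_id: signal(node_id) for node_id in pathway.nodes}


def make_chain(*signs: str, name: str = "chain") -> Pathway:
    """Gene chain g0 -> g1 -> ... -> gn -> sink; signs apply between genes."""
    n = len(signs)
    nodes = [PathwayNode(id=f"g{i}", node_type="gene") for i in range(n + 1)]
    nodes.append(PathwayNode(id="zz_sink", node_type="sink"))
    edges = [PathwayEdge(f"g{i}", f"g{i + 1}", signs[i]) for i in range(n)]
    edges.append(PathwayEdge(f"g{n}", "zz_sink", "activation"))
    return Pathway(name=name, nodes=nodes, edges=edges, sink="zz_sink")


def random_dag(rng: random.Random, max_nodes: int = 12) -> Pathway:
    """A random valid pathway DAG with mixed node types and edge signs.

    Node ids are ordered so edges always point forward; the last node is the
    sink and every source is connected toward it.
    """
    n = rng.randint(3, max_nodes)
    ids = [f"n{i:02d}" for i in range(n)]
    edges: list[PathwayEdge] = []
    for j in range(1, n):
        # at least one parent among earlier nodes keeps the graph connected
        parents = rng.sample(ids[:j], k=rng.randint(1, min(j, 3)))
        for src in parents:
            sign = "inhibition" if rng.random() < 0.3 else "activation"
            edges.append(PathwayEdge(src, ids[j], sign))

    nodes = []
    by_target: dict[str, list[str]] = {}
    for e in edges:
        by_target.setdefault(e.target, []).append(e.source)
    for i, node_id in enumerate(ids):
        if i == n - 1:
            nodes.append(PathwayNode(id=node_id, node_type="sink"))
        elif i == 0 or not by_target.get(node_id):
            nodes.append(PathwayNode(id=node_id, node_type="gene"))
        else:
            kind = rng.choice(["gene", "gene", "linker", "process"])
            if kind == "linker":
                nodes.append(
                    PathwayNode(
                        id=node_id,
                        node_type="linker",
                        operator=rng.choice(["min", "max", "sum"]),
                    )
                )
            else:
                nodes.append(PathwayNode(id=node_id, node_type=kind))
    return Pathway(name="random", nodes=nodes, edges=edges, sink=ids[-1])


def random_fc(rng: random.Random, pathway: Pathway) -> dict[str, float]:
    return {g: 2.0 ** rng.uniform(-3, 3) for g in pathway.gene_ids()}


@pytest.fixture(scope="session")
def alt_pathway():
    from tmmpsf import load_tmm

    return load_tmm("ALT")


@pytest.fixture(scope="session")
def tel_pathway():
    from tmmpsf import load_tmm

    return load_tmm("TEL")


@pytest.fixture
def toy_pathway() -> Pathway:
    """Small mixed-type pathway: two genes, a min linker, a process, a sink."""
    nodes = [
        PathwayNode(id="a", node_type="gene"),
        PathwayNode(id="b", node_type="gene"),
        PathwayNode(id="link", node_type="linker", operator="min"),
        PathwayNode(id="proc", node_type="process", branch="toy block"),
        PathwayNode(id="zz_sink", node_type="sink"),
    ]
    edges = [
        PathwayEdge("a", "link", "activation"),
        PathwayEdge("b", "link", "activation"),
        PathwayEdge("link", "proc", "activation"),
        PathwayEdge("proc", "zz_sink", "activation"),
    ]
    return Pathway(name="toy", nodes=nodes, edges=edges, sink="zz_sink")
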