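"""Graph model: validation, topological order and format round-trips."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmmpsf.pathway import (
    Pathway,
    PathwayEdge,
    PathwayNode,
    PathwayValidationError,
    topological_order,
    validate_pathway,
)
from tmmpsf.pathwayio import FORMATS, read_pathway, write_pathway

from conftest import random_dag


def _chain3() -> Pathway:
    nodes = [
        PathwayNode(id="a", node_type="gene"),
        PathwayNode(id="b", node_type="gene"),
        PathwayNode(id="c", node_type="sink"),
    ]
    edges = [PathwayEdge("a", "b"), PathwayEdge("b", "c")]
    return Pathway(name="chain", nodes=nodes, edges=edges, sink="c")


class TestValidation:
    def test_valid_chain_has_empty_report(self):
        assert validate_pathway(_chain3()) == []

    def test_cycle_is_flagged(self):
        p = Pathway(
            name="cyc",
            nodes=[
                PathwayNode(id="a", node_type="gene"),
                PathwayNode(id="b", node_type="gene"),
                PathwayNode(id="s", node_type="sink"),
            ],
            edges=[PathwayEdge("a", "b"), PathwayEdge("b", "a"), PathwayEdge("b", "s")],
            sink="s",
        )
        rules = {v["rule"] for v in validate_pathway(p)}
        assert "not_a_dag" in rules

    def test_linker_without_operator(self):
        p = Pathway(
            name="l",
            nodes=[
                PathwayNode(id="a", node_type="gene"),
                PathwayNode(id="l1", node_type="linker"),
                PathwayNode(id="s", node_type="sink"),
            ],
            edges=[PathwayEdge("a", "l1"), PathwayEdge("l1", "s")],
            sink="s",
        )
        violations = validate_pathway(p)
        assert any(
            v["rule"] == "linker_missing_operator" and v["element"] == "l1"
            for v in violations
        )

    def test_unknown_edge_sign_names_the_edge(self, tmp_path):
        p = _chain3()
        p.edges[0] = PathwayEdge("a", "b", "activates?")
        violations = validate_pathway(p)
        assert any(
            v["rule"] == "unknown_edge_sign" and "a->b" in v["element"]
            for v in violations
        )
        # writing a valid file then corrupting the sign is rejected on read
        path = tmp_path / "bad.json"
        write_pathway(_chain3(), path)
        text = path.read_text().replace('"activation"', '"activates?"', 1)
        path.write_text(text)
        with pytest.raises(PathwayValidationError, match="unknown_edge_sign"):
            read_pathway(path)

    def test_multiple_sinks_rejected(self):
        p = Pathway(
            name="two",
            nodes=[
                PathwayNode(id="a", node_type="gene"),
                PathwayNode(id="s1", node_type="sink"),
                PathwayNode(id="s2", node_type="sink"),
            ],
            edges=[PathwayEdge("a", "s1"), PathwayEdge("a", "s2")],
            sink="s1",
        )
        rules = {v["rule"] for v in validate_pathway(p)}
        assert "multiple_sinks" in rules or "sink_has_outgoing" in rules


class TestTopologicalOrder:
    def test_chain(self):
        assert topological_order(_chain3()) == ["a", "b", "c"]

    def test_diamond_ties_broken_by_id(self):
        p = Pathway(
            name="diamond",
            nodes=[
                PathwayNode(id="a", node_type="gene"),
                PathwayNode(id="b", node_type="gene"),
                PathwayNode(id="c", node_type="gene"),
                PathwayNode(id="d", node_type="sink"),
            ],
            edges=[
                PathwayEdge("a", "b"),
                PathwayEdge("a", "c"),
                PathwayEdge("b", "d"),
                PathwayEdge("c", "d"),
            ],
            sink="d",
        )
        assert topological_order(p) == ["a", "b", "c", "d"]

    def test_cycle_raises_naming_a_cycle(self):
        p = _chain3()
        p.edges.append(PathwayEdge("b", "a"))
        p.invalidate_cache()
        with pytest.raises(PathwayValidationError, match="cycle"):
            topological_order(p)

    def test_valid_pathway_always_orders(self):
        rng = random.Random(11)
        for _ in range(25):
            p = random_dag(rng)
            assert validate_pathway(p) == []
            order = topological_order(p)
            pos = {node_id: i for i, node_id in enumerate(order)}
            assert all(pos[e.source] < pos[e.target] for e in p.edges)


class TestRoundTrip:
    @pytest.mark.parametrize("fmt", FORMATS)
    def test_alt_fixture_round_trip(self, alt_pathway, tmp_path, fmt):
        path = tmp_path / f"alt.{fmt}"
        write_pathway(alt_pathway, path, format=fmt)
        back = read_pathway(path, format=fmt)
        assert len([n for n in back.nodes.values() if n.node_type == "gene"]) == 37
        assert back.nodes == alt_pathway.nodes
        assert sorted(map(repr, back.edges)) == sorted(map(repr, alt_pathway.edges))
        assert back.sink == alt_pathway.sink

    @pytest.mark.parametrize("fmt", FORMATS)
    def test_random_pathway_round_trip(self, tmp_path, fmt):
        rng = random.Random(5)
        for i in range(10):
            p = random_dag(rng)
            path = tmp_path / f"p{i}.{fmt}"
            write_pathway(p, path, format=fmt)
            back = read_pathway(path, format=fmt)
            assert back.nodes == p.nodes
            assert sorted(map(repr, back.edges)) == sorted(map(repr, p.edges))

    @pytest.mark.parametrize("fmt", FORMATS)
    def test_two_writes_are_byte_identical(self, tel_pathway, tmp_path, fmt):
        p1, p2 = tmp_path / f"one.{fmt}", tmp_path / f"two.{fmt}"
        write_pathway(tel_pathway, p1, format=fmt)
        write_pathway(tel_pathway, p2, format=fmt)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_name_round_trips(self, tmp_path):
        p = _chain3()
        p.name = ""
        path = tmp_path / "anon.json"
        write_pathway(p, path)
        assert read_pathway(path).name == ""

    def test_annotations_preserved(self, tmp_path):
        nodes = [
            PathwayNode(id="a", node_type="gene", annotations={"citations": "B1,B2"}),
            PathwayNode(id="s", node_type="sink"),
        ]
        p = Pathway(name="ann", nodes=nodes, edges=[PathwayEdge("a", "s")], sink="s")
        for fmt in FORMATS:
            path = tmp_path / f"ann.{fmt}"
            write_pathway(p, path, format=fmt)
            back = read_pathway(path, format=fmt)
            assert back.nodes["a"].annotations["citations"] == "B1,B2"

    def test_missing_file_raises(self):
        with pytest.raises(FileNotFoundError):
            read_pathway("does/not/exist.json")

    def test_missing_sink_raises(self, tmp_path):
        path = tmp_path / "nosink.json"
        path.write_text('{"name": "x", "nodes": [], "edges": []}')
        with pytest.raises(PathwayValidationError, match="sink"):
            read_pathway(path)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10**6), fmt=st.sampled_from(FORMATS))
def test_round_trip_property(seed, fmt, tmp_path_factory):
    """read(write(P)) is attribute-identical to P for random valid pathways."""
    p = random_dag(random.Random(seed))
    path = tmp_path_factory.mktemp("rt") / f"p.{fmt}"
    write_pathway(p, path, format=fmt)
    back = read_pathway(path, format=fmt)
    assert back.nodes == p.nodes
    assert sorted(map(repr, back.edges)) == sorted(map(repr, p.edges))
    assert (back.name, back.version, back.sink) == (p.name, p.version, p.sink)
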