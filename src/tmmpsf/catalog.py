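"""Packaged ALT and TEL telomere-maintenance pathway topologies (TMM v2.0).

The two pathways encode the literature-curated molecular events behind the
telomerase-dependent (TEL) and the alternative-lengthening-of-telomeres
(ALT) maintenance mechanisms.  Genes and complexes are grouped into event
blocks ("branches"); within a block the evidence is combined by a sum
operator, complexes by a min operator (the weakest subunit limits the
complex), and blocks combine multiplicatively along the event chain toward
a single sink node whose propagated signal summarises pathway activity.

ALT is a serial chain of seven event blocks: DNA damage response / G4
handling, non-sister telomere bridge formation (NTB), recruitment of
telomeres to APBs, strand invasion, template-directed synthesis, and the
two Holliday-junction processing fates (dissolution, resolution).  TEL has
three parallel component branches — nuclear TERT activation, hTR (TERC)
maturation and the dyskerin (DKC1) H/ACA complex — that converge on
telomerase assembly followed by recruitment to telomeres and synthesis by
telomerase together with DNA polymerase alpha.

Each gene carries its net activating (+) or inhibiting (-) effect and at
least one literature citation key.  The encodings ship as JSON files (in
``tmmpsf/data``) and can be exported to XGMML/GraphML with
:func:`tmmpsf.pathwayio.write_pathway`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

from .pathway import Pathway, PathwayEdge, PathwayNode, require_valid

TMM_VERSION = "2.0"


@dataclass(frozen=True)
class GeneRow:
    """One gene row of the curated tables."""

    symbol: str
    sign: str  # "+" or "-": net effect on the pathway
    citations: tuple[str, ...]
    alias: str | None = None


@dataclass(frozen=True)
class ComplexRow:
    """A protein complex with its member genes."""

    name: str
    sign: str
    members: tuple[GeneRow, ...]
    citations: tuple[str, ...] = ()


@dataclass(frozen=True)
class Block:
    """An event block: a named branch of the pathway."""

    key: str
    tag: str
    items: tuple[GeneRow | ComplexRow, ...]
    #: upstream block keys; None = serially chained to the preceding block,
    #: () = a root block with no upstream events
    parents: tuple[str, ...] | None = None


def _g(symbol: str, sign: str, *citations: str, alias: str | None = None) -> GeneRow:
    return GeneRow(symbol, sign, tuple(citations), alias)


# ---------------------------------------------------------------------------
# ALT: serial chain of seven event blocks

ALT_BLOCKS: tuple[Block, ...] = (
    Block(
        "DDR",
        "G4 formation; DDR provocation",
        (
            _g("H3F3A", "-", "B48", "B19", "B28"),
            ComplexRow(
                "ATRX/DAXX",
                "-",
                (
                    _g("DAXX", "-", "B48", "B19", "B28"),
                    _g("ATRX", "-", "B48", "B19", "B28"),
                ),
                ("B48", "B19", "B28"),
            ),
        ),
        parents=(),
    ),
    Block(
        "NTB",
        "Telomere bridge formation (NTB)",
        (
            _g("NR2C2", "+", "B21", alias="TRF4"),
            _g("NR2F2", "+", "B21", alias="COUP-TF2"),
            _g("ZNF827", "+", "B21"),
            ComplexRow("NuRD", "+", (), ("B21",)),
        ),
        parents=("DDR",),
    ),
    Block(
        "APB",
        "Recruitment of telomeres to APBs (APB)",
        (
            _g("PML", "+", "B18"),
            ComplexRow(
                "SMC5/6",
                "+",
                (
                    _g("SMC5", "+", "B62", "B3", alias="RAD18"),
                    _g("SMC6", "+", "B62", "B3", alias="Spr18"),
                    _g("NSMCE2", "+", "B62", "B3", alias="NSE2"),
                ),
                ("B62", "B3"),
            ),
        ),
        parents=("NTB",),
    ),
    Block(
        "SI",
        "Strand invasion (SI)",
        (
            _g("POT1", "-", "B31"),
            ComplexRow(
                "RPA",
                "+",
                (
                    _g("RPA1", "+", "B31"),
                    _g("RPA2", "+", "B31"),
                    _g("RPA3", "+", "B31"),
                ),
                ("B31",),
            ),
            _g("HNRNPA1", "-", "B31"),
            _g("ATR", "+", "B31", "B32", "B24", "B26"),
            _g("CHEK1", "+", "B26"),
            _g("RAD51", "+", "B16", "B41"),
            _g("PSMC3IP", "+", "B16", "B41", alias="HOP2"),
            _g("MND1", "+", "B16", "B41"),
            _g("RAD52", "+", "B41", "B51"),
        ),
        parents=("APB",),
    ),
    Block(
        "TDS",
        "Template directed synthesis",
        (
            _g("POLD3", "+", "B26"),
            _g("PCNA", "+", "B26"),
            _g("RFC1", "+", "B26"),
        ),
        parents=("SI",),
    ),
    Block(
        "HJd",
        "Holliday junction dissolution",
        (
            ComplexRow(
                "MRN",
                "+",
                (
                    _g("MRE11", "+", "B45"),
                    _g("RAD50", "+", "B45"),
                    _g("NBN", "+", "B45", alias="NBS1"),
                ),
                ("B27", "B19"),
            ),
            _g("SP100", "-", "B42"),
            ComplexRow(
                "BTR",
                "+",
                (
                    _g("BLM", "+", "B70"),
                    _g("TOP3A", "+", "B70"),
                    _g("RMI1", "+", "B70"),
                    _g("RMI2", "+", "B70"),
                ),
                ("B70", "B51"),
            ),
        ),
        parents=("TDS",),
    ),
    Block(
        "HJr",
        "Holliday junction resolution",
        (
            ComplexRow(
                "SLX4-SLX1-ERCC4",
                "-",
                (
                    _g("SLX1A", "-", "B70", alias="SLX1"),
                    _g("SLX1B", "-", "B70", alias="SLX1"),
                    _g("SLX4", "-", "B70"),
                    _g("ERCC1", "-", "B80"),
                    _g("ERCC4", "-", "B80"),
                ),
                ("B70", "B80"),
            ),
        ),
        parents=("HJd",),
    ),
)

# ---------------------------------------------------------------------------
# TEL: three component branches converging on assembly, then synthesis

TEL_BLOCKS: tuple[Block, ...] = (
    Block(
        "TERT",
        "Nuclear TERT (TERT activation and recruitment)",
        (
            _g("TERT", "+", "B20"),
            _g("KPNA1", "+", "B40"),
            _g("RAN", "+", "B40"),
            _g("IPO7", "+", "B33"),
            _g("RANBP2", "+", "B33"),
            ComplexRow(
                "HSP90",
                "+",
                (
                    _g("HSP90AA1", "+", "B40"),
                    _g("HSP90AB1", "+", "B40"),
                ),
                ("B40",),
            ),
            _g("PTGES3", "+", "B40", alias="p23"),
            _g("STUB1", "-", "B46"),
        ),
        parents=(),
    ),
    Block(
        "TERC",
        "hTR maturation",
        (
            _g("TERC", "+", "B11", "B20", alias="hTR"),
            _g("PARN", "+", "B52", "B7"),
            _g("WRAP53", "+", "B14", alias="TCAB1"),
            ComplexRow(
                "TRAMP",
                "-",
                (
                    _g("TENT4B", "-", "B52", "B74", alias="PAPD5"),
                    _g("MTREX", "-", "B74", alias="MTR4"),
                    _g("ZCCHC7", "-", "B74", alias="AIR2"),
                ),
                ("B7",),
            ),
        ),
        parents=(),
    ),
    Block(
        "DKC1",
        "Dyskerin complex (DKC1 branch)",
        (
            ComplexRow(
                "DKC1-NOP10-NHP2-NAF1",
                "+",
                (
                    _g("DKC1", "+", "B67"),
                    _g("NOP10", "+", "B67"),
                    _g("NHP2", "+", "B67"),
                    _g("NAF1", "+", "B67"),
                ),
                ("B67",),
            ),
            _g("GAR1", "+", "B67"),
        ),
        parents=(),
    ),
    Block(
        "assembly",
        "Telomerase assembly",
        (
            # TERT, TERC and DKC1 feed the assembly block in addition to
            # their own maturation branches.
            _g("TERT", "+", "B20"),
            _g("TERC", "+", "B11", "B20", alias="hTR"),
            _g("DKC1", "+", "B67"),
            ComplexRow(
                "Pontin/Reptin",
                "+",
                (
                    _g("RUVBL1", "+", "B75", alias="Pontin"),
                    _g("RUVBL2", "+", "B75", alias="Reptin"),
                ),
                ("B75",),
            ),
        ),
        parents=("TERT", "TERC", "DKC1"),
    ),
    Block(
        "synthesis",
        "Recruitment to telomeres and synthesis",
        (
            ComplexRow(
                "CST",
                "+",
                (
                    _g("CTC1", "+", "B13"),
                    _g("STN1", "+", "B13"),
                    _g("TEN1", "+", "B13"),
                ),
                ("B13",),
            ),
            _g("POLA1", "+", "B13"),
        ),
        parents=("assembly",),
    ),
)

_CATALOG_BLOCKS = {
    ("ALT", TMM_VERSION): ALT_BLOCKS,
    ("TEL", TMM_VERSION): TEL_BLOCKS,
}


def _sign_to_edge(sign: str) -> str:
    return "activation" if sign == "+" else "inhibition"


def build_pathway(name: str, blocks: tuple[Block, ...], version: str = TMM_VERSION) -> Pathway:
    """Wire a tuple of block definitions into a validated :class:`Pathway`.

    Per block: gene/complex evidence feeds a sum-operator linker
    (``evidence:<key>``), which activates the block's process node
    (``branch:<key>``); upstream blocks activate the process node as
    additional parents (combined multiplicatively by the engine).  The final
    block's process node activates the single sink.
    """
    nodes: dict[str, PathwayNode] = {}
    edges: list[PathwayEdge] = []

    def add_gene(row: GeneRow, tag: str) -> str:
        if row.symbol not in nodes:
            annotations = {"citations": ",".join(row.citations)}
            if row.alias:
                annotations["alias"] = row.alias
            nodes[row.symbol] = PathwayNode(
                id=row.symbol,
                node_type="gene",
                branch=tag,
                sign=row.sign,
                annotations=annotations,
            )
        return row.symbol

    for order, block in enumerate(blocks):
        tag = block.tag
        evidence_id = f"evidence:{block.key}"
        process_id = f"branch:{block.key}"
        nodes[evidence_id] = PathwayNode(
            id=evidence_id, node_type="linker", operator="sum", branch=tag
        )
        nodes[process_id] = PathwayNode(
            id=process_id,
            label=tag,
            node_type="process",
            branch=tag,
            annotations={"order": str(order)},
        )
        for item in block.items:
            if isinstance(item, GeneRow):
                gene_id = add_gene(item, tag)
                edges.append(PathwayEdge(gene_id, evidence_id, _sign_to_edge(item.sign)))
            else:
                complex_id = f"complex:{item.name}"
                if complex_id not in nodes:
                    nodes[complex_id] = PathwayNode(
                        id=complex_id,
                        label=item.name,
                        node_type="complex",
                        members=tuple(m.symbol for m in item.members),
                        branch=tag,
                        annotations={"citations": ",".join(item.citations)},
                    )
                    for member in item.members:
                        gene_id = add_gene(member, tag)
                        edges.append(PathwayEdge(gene_id, complex_id, "activation"))
                edges.append(PathwayEdge(complex_id, evidence_id, _sign_to_edge(item.sign)))
        edges.append(PathwayEdge(evidence_id, process_id, "activation"))
        for parent_key in block.parents or ():
            edges.append(PathwayEdge(f"branch:{parent_key}", process_id, "activation"))

    # implicit serial chaining for blocks without a declared parent list
    for prev, block in zip(blocks, blocks[1:]):
        if block.parents is None:
            edges.append(PathwayEdge(f"branch:{prev.key}", f"branch:{block.key}", "activation"))

    chained = {e.source for e in edges if e.source.startswith("branch:")}
    terminal = [b.key for b in blocks if f"branch:{b.key}" not in chained]
    sink_id = f"sink:{name}"
    nodes[sink_id] = PathwayNode(id=sink_id, label=f"{name} telomere maintenance", node_type="sink")
    for key in terminal:
        edges.append(PathwayEdge(f"branch:{key}", sink_id, "activation"))

    pathway = Pathway(name=name, version=version, nodes=nodes.values(), edges=edges, sink=sink_id)
    return require_valid(pathway)


def load_tmm(name: str, version: str = TMM_VERSION, source: str = "builtin") -> Pathway:
    """Load a packaged TMM pathway.

    Parameters
    ----------
    name
        ``"ALT"`` or ``"TEL"``.
    version
        Catalog version; only ``"2.0"`` is packaged.
    source
        ``"builtin"`` builds the pathway from the in-code tables; ``"json"``
        reads the shipped JSON export instead (identical content).
    """
    key = (name, version)
    if key not in _CATALOG_BLOCKS:
        known = sorted(f"{n} v{v}" for n, v in _CATALOG_BLOCKS)
        raise KeyError(f"unknown TMM pathway {name!r} version {version!r}; packaged: {known}")
    if source == "json":
        from .pathwayio import read_pathway

        ref = resources.files("tmmpsf").joinpath(
            f"data/{name.lower()}_tmm_v{version.replace('.', '_')}.json"
        )
        with resources.as_file(ref) as path:
            return read_pathway(path, format="json")
    return build_pathway(name, _CATALOG_BLOCKS[key], version)


def list_branches(pathway: Pathway) -> list[tuple[str, list[str]]]:
    """Branch tags with their member node ids, in event-chain order.

    Ordering follows the ``order`` annotation written on process nodes
    (left-to-right along the event chain); untagged pathways return an
    empty list with a warning.
    """
    tags: dict[str, list[str]] = {}
    order: dict[str, int] = {}
    for node_id in sorted(pathway.nodes):
        node = pathway.nodes[node_id]
        if node.branch is None:
            continue
        tags.setdefault(node.branch, []).append(node_id)
        if node.node_type == "process" and "order" in node.annotations:
            order[node.branch] = int(node.annotations["order"])
    if not tags:
        warnings.warn(f"pathway {pathway.name!r} carries no branch tags", stacklevel=2)
        return []
    return sorted(tags.items(), key=lambda kv: (order.get(kv[0], 10**6), kv[0]))


def gene_block_membership(pathway: Pathway) -> dict[str, set[str]]:
    """Map each gene to the branch tags of the evidence blocks it feeds.

    A gene belongs to a block if it feeds the block's evidence linker either
    directly or through a complex.
    """
    membership: dict[str, set[str]] = {g: set() for g in pathway.gene_ids()}
    complex_members: dict[str, tuple[str, ...]] = {
        n.id: n.members for n in pathway.nodes.values() if n.node_type == "complex"
    }
    for edge in pathway.edges:
        target = pathway.nodes.get(edge.target)
        if target is None or target.node_type != "linker" or target.branch is None:
            continue
        source = pathway.nodes[edge.source]
        if source.node_type == "gene":
            membership[source.id].add(target.branch)
        elif source.node_type == "complex":
            for member in complex_members.get(source.id, ()):
                membership[member].add(target.branch)
    return membership


def gene_signs(pathway: Pathway) -> dict[str, str]:
    """Net activating/inhibiting sign per gene, as annotated from the tables."""
    return {n.id: n.sign or "+" for n in pathway.gene_nodes()}


def provenance_table(pathway: Pathway) -> list[tuple[str, str, str, str]]:
    """Rows of ``(gene, sign, branch, citations)`` sorted by gene id."""
    return [
        (n.id, n.sign or "", n.branch or "", n.annotations.get("citations", ""))
        for n in pathway.gene_nodes()
    ]
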