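"""Pathway signal flow (PSF): propagate fold changes through a pathway DAG.

Each node carries a positive signal.  Source genes start at their fold
change; every other node combines the signals arriving on its incoming
edges — an activating edge contributes the parent's signal, an inhibiting
edge its reciprocal — and multiplies the combination by its own fold change
(1 for non-gene nodes and unmeasured genes).  How parents combine depends
on the node type:

* linker nodes apply their declared operator (``min``, ``max`` or ``sum``),
* complex nodes take the minimum (the weakest subunit limits the complex),
* all other multi-parent nodes multiply their inputs.

The sink node's signal summarises overall pathway activity.  Because sum
operators make the all-neutral signal differ from 1, activity is reported
as ``log2(sink_raw / sink_neutral)`` where ``sink_neutral`` is the sink
signal under the all-ones fold-change vector; 0 is then the neutral
activity threshold regardless of topology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .pathway import Pathway, PathwayValidationError, topological_order

SIGNAL_MIN = 1e-6
SIGNAL_MAX = 1e6


def _clip(x: float) -> float:
    return min(max(x, SIGNAL_MIN), SIGNAL_MAX)


@dataclass
class PSFResult:
    """Node signals and sink activity for one sample."""

    sample: str
    node_signal: dict[str, float]
    sink_raw: float
    sink_neutral: float
    missing_genes: list[str] = field(default_factory=list)

    @property
    def activity_log2(self) -> float:
        """Sink activity on the log2 scale; 0 is neutral."""
        return math.log2(self.sink_raw / self.sink_neutral)


def _propagate(pathway: Pathway, fc: Mapping[str, float]) -> dict[str, float]:
    """One pass of signal propagation; ``fc`` must cover the genes it covers."""
    signal: dict[str, float] = {}
    parents: dict[str, list[tuple[str, str]]] = {node_id: [] for node_id in pathway.nodes}
    for edge in pathway.edges:
        parents[edge.target].append((edge.source, edge.sign))
    for node_id in topological_order(pathway):
        node = pathway.nodes[node_id]
        own_fc = 1.0
        if node.node_type == "gene" and node_id in fc:
            own_fc = float(fc[node_id])
            if own_fc <= 0:
                raise ValueError(f"non-positive fold change {own_fc} for gene {node_id!r}")
        incoming = sorted(parents[node_id])
        if not incoming:
            signal[node_id] = _clip(own_fc)
            continue
        contributions = [
            _clip(signal[src]) if sign == "activation" else 1.0 / _clip(signal[src])
            for src, sign in incoming
        ]
        if node.node_type == "linker":
            if node.operator == "min":
                combined = min(contributions)
            elif node.operator == "max":
                combined = max(contributions)
            else:  # sum
                combined = sum(contributions)
        elif node.node_type == "complex":
            combined = min(contributions)
        else:
            combined = math.prod(contributions)
        signal[node_id] = _clip(own_fc * combined)
    return signal


def compute_psf(
    pathway: Pathway, fc: Mapping[str, float], sample: str = "sample"
) -> PSFResult:
    """Propagate a fold-change vector and report node signals + sink activity.

    Pathway genes absent from ``fc`` are treated as neutral (FC 1) and listed
    in ``missing_genes``.  Raises on non-positive fold changes and on cyclic
    pathways.
    """
    gene_ids = pathway.gene_ids()
    missing = [g for g in gene_ids if g not in fc]
    for gene in gene_ids:
        if gene in fc and not fc[gene] > 0:
            raise ValueError(f"non-positive fold change {fc[gene]} for gene {gene!r}")
    signal = _propagate(pathway, fc)
    neutral = _propagate(pathway, {})
    if pathway.sink not in signal:
        raise PathwayValidationError(f"pathway {pathway.name!r} has no sink signal")
    return PSFResult(
        sample=sample,
        node_signal=signal,
        sink_raw=signal[pathway.sink],
        sink_neutral=neutral[pathway.sink],
        missing_genes=missing,
    )


def pathway_activity(result: PSFResult) -> tuple[float, float]:
    """``(sink_raw, activity_log2)`` — the classification axis value."""
    if result.sink_raw is None or not result.sink_raw > 0:
        raise ValueError("PSF result is incomplete: sink signal missing")
    return result.sink_raw, result.activity_log2


def score_matrix(
    pathway: Pathway, fc_values: pd.DataFrame
) -> pd.DataFrame:
    """Score every sample (column) of a fold-change table against one pathway.

    Returns a DataFrame indexed by sample with ``sink_raw`` and
    ``activity_log2`` columns.
    """
    rows = []
    for sample in fc_values.columns:
        result = compute_psf(pathway, fc_values[sample].to_dict(), sample=str(sample))
        rows.append((str(sample), result.sink_raw, result.activity_log2))
    return pd.DataFrame(
        rows, columns=["sample", "sink_raw", "activity_log2"]
    ).set_index("sample")


def branch_summary(result: PSFResult, pathway: Pathway) -> pd.DataFrame:
    """Per-branch process-node signals versus the neutral baseline.

    One row per process/event node in event-chain order, with columns
    ``branch``, ``node``, ``signal`` and ``log2_vs_neutral``.  Pathways
    without branch tags yield an empty table with a warning.
    """
    from .catalog import list_branches

    neutral = _propagate(pathway, {})
    rows = []
    for tag, node_ids in list_branches(pathway):
        for node_id in node_ids:
            if node_id not in result.node_signal:
                raise KeyError(f"node {node_id!r} missing from PSF result")
            if pathway.nodes[node_id].node_type != "process":
                continue
            sig = result.node_signal[node_id]
            rows.append((tag, node_id, sig, math.log2(sig / neutral[node_id])))
    return pd.DataFrame(rows, columns=["branch", "node", "signal", "log2_vs_neutral"])


def write_node_signals(result: PSFResult, pathway: Pathway, path) -> None:
    """Long-format per-node signal TSV for one sample."""
    neutral = _propagate(pathway, {})
    rows = []
    for node_id in sorted(result.node_signal):
        node = pathway.nodes[node_id]
        sig = result.node_signal[node_id]
        rows.append(
            (
                node_id,
                node.node_type,
                node.branch or "",
                sig,
                math.log2(sig / neutral[node_id]),
            )
        )
    pd.DataFrame(
        rows, columns=["node", "type", "branch", "signal", "log2_vs_neutral"]
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")
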