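"""Partial influence (PI): gene-level what-if analysis on pathway signals.

The partial influence of a gene on a target node is the log2 ratio of the
target's propagated signal before versus after forcing the gene's fold
change to the neutral value 1.  Activating genes with FC above (below) 1
thus have positive (negative) PI on downstream targets; genes acting
through an odd number of inhibiting edges show the reverse association.
Multi-gene neutralization supports what-if scenarios such as "does the
pathway switch on when these suppressors are brought back to baseline?".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .pathway import Pathway
from .preprocess import FoldChangeMatrix
from .psf import PSFResult, compute_psf


@dataclass(frozen=True)
class PIRecord:
    """Influence of one gene on one target node."""

    gene: str
    target: str
    pi_log2: float
    observed_fc: float


def _target_signal(pathway: Pathway, fc: Mapping[str, float], target: str) -> float:
    result = compute_psf(pathway, fc)
    if target not in result.node_signal:
        raise KeyError(f"unknown target node {target!r} in pathway {pathway.name!r}")
    return result.node_signal[target]


def partial_influence(
    pathway: Pathway,
    fc: Mapping[str, float],
    gene: str,
    target: str | None = None,
) -> PIRecord:
    """PI of ``gene`` on ``target`` (default: the sink) for one FC vector.

    Computed from two full propagations: the observed vector and the vector
    with the gene's FC forced to 1.  A gene with no path to the target has
    PI exactly 0.
    """
    if target is None:
        target = pathway.sink
    if gene not in pathway.nodes or pathway.nodes[gene].node_type != "gene":
        raise KeyError(f"unknown pathway gene {gene!r}")
    observed = _target_signal(pathway, fc, target)
    neutralized_vec = dict(fc)
    neutralized_vec[gene] = 1.0
    neutralized = _target_signal(pathway, neutralized_vec, target)
    return PIRecord(
        gene=gene,
        target=target,
        pi_log2=math.log2(observed / neutralized),
        observed_fc=float(fc.get(gene, 1.0)),
    )


def pi_profile(
    pathway: Pathway,
    fc: Mapping[str, float],
    target: str | None = None,
) -> list[PIRecord]:
    """PI of every pathway gene, most negative (strongest suppressor) first.

    Deterministic: sorted ascending by ``pi_log2``, ties by gene id.
    """
    if target is None:
        target = pathway.sink
    records = [partial_influence(pathway, fc, gene, target) for gene in pathway.gene_ids()]
    return sorted(records, key=lambda r: (r.pi_log2, r.gene))


def neutralize_and_score(
    pathway: Pathway,
    fc: Mapping[str, float],
    genes: Iterable[str],
    sample: str = "what-if",
) -> PSFResult:
    """Score the vector with the listed genes forced to FC 1 (what-if)."""
    genes = list(genes)
    pathway_genes = set(pathway.gene_ids())
    unknown = [g for g in genes if g not in pathway_genes]
    if unknown:
        raise KeyError(f"not pathway genes: {unknown}")
    vec = dict(fc)
    for gene in genes:
        vec[gene] = 1.0
    return compute_psf(pathway, vec, sample=sample)


def mean_sample_pi(
    pathway: Pathway,
    fc_matrix: FoldChangeMatrix,
    target: str | None = None,
) -> list[PIRecord]:
    """PI profile of the "mean sample".

    The mean sample is formed by the per-gene arithmetic mean of fold
    changes across all samples; its PI profile summarises which genes limit
    or drive pathway activity in the cohort as a whole.
    """
    if fc_matrix.values.empty:
        raise ValueError("cannot build a mean sample from an empty matrix")
    mean_vector = fc_matrix.values.mean(axis=1).to_dict()
    return pi_profile(pathway, mean_vector, target)


def pi_table(records: list[PIRecord]) -> pd.DataFrame:
    """PI records as a ranked DataFrame (rank 1 = most negative PI)."""
    return pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "target": [r.target for r in records],
            "observed_fc": [r.observed_fc for r in records],
            "pi_log2": [r.pi_log2 for r in records],
            "rank": range(1, len(records) + 1),
        }
    )
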