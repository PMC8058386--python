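"""Synthetic expression matrices with planted TMM phenotypes.

The generator emulates a genes x samples expression study containing the
ALT and TEL pathway genes plus unrelated background genes.  Per-gene
baseline levels are drawn log-normally; in a TEL+ (resp. ALT+) sample the
activating genes of the TEL (resp. ALT) pathway are multiplied by the
effect size and the inhibiting genes divided by it, so the planted signal
is coherent with pathway semantics.  Independent log2-normal multiplicative
noise is applied to every gene x sample entry.  The defaults (4x effect,
0.2 log2 noise SD, 20 samples per quadrant, 100 background genes) represent
a clearly phenotyped cohort of the size of a typical cell-line panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import gene_signs, load_tmm
from .phenotype import QUADRANTS, classify_phenotype, fit_axis_threshold
from .preprocess import ExpressionMatrix, fold_changes
from .psf import compute_psf


@dataclass
class SimulationDesign:
    """Parameters of a planted-phenotype simulation."""

    n_per_quadrant: dict[str, int] = field(
        default_factory=lambda: {q: 20 for q in QUADRANTS}
    )
    effect_size: float = 4.0  # multiplicative FC shift on pathway genes
    noise_sd: float = 0.2  # SD of log2-normal noise
    background_genes: int = 100
    seed: int = 7
    mode: str = "microarray"
    baseline_log2_mean: float = 7.0  # centre of per-gene baseline levels
    baseline_log2_sd: float = 1.0

    def validate(self) -> None:
        if self.effect_size < 1:
            raise ValueError("effect_size must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.background_genes < 0:
            raise ValueError("background_genes must be >= 0")
        if any(n < 0 for n in self.n_per_quadrant.values()):
            raise ValueError("sample counts must be >= 0")
        unknown = set(self.n_per_quadrant) - set(QUADRANTS)
        if unknown:
            raise ValueError(f"unknown quadrants in design: {sorted(unknown)}")


def simulate_expression(design: SimulationDesign) -> tuple[ExpressionMatrix, pd.Series]:
    """Generate an expression matrix and the true quadrant label per sample.

    Deterministic given ``design.seed``.  Sample ids are
    ``<quadrant-tag>_<i>`` with tags like ``TELpALTn``.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)

    tel_signs = gene_signs(load_tmm("TEL"))
    alt_signs = gene_signs(load_tmm("ALT"))
    pathway_genes = sorted(set(tel_signs) | set(alt_signs))
    background = [f"BG{i:04d}" for i in range(design.background_genes)]
    genes = pathway_genes + background

    baseline = 2.0 ** rng.normal(
        design.baseline_log2_mean, design.baseline_log2_sd, size=len(genes)
    )

    samples: list[str] = []
    labels: list[str] = []
    columns: list[np.ndarray] = []
    for quadrant in QUADRANTS:
        n = design.n_per_quadrant.get(quadrant, 0)
        tel_on = "TEL+" in quadrant
        alt_on = "ALT+" in quadrant
        tag = quadrant.replace("TEL+", "TELp").replace("TEL-", "TELn")
        tag = tag.replace("/ALT+", "ALTp").replace("/ALT-", "ALTn")
        shift = np.ones(len(genes))
        for i, gene in enumerate(pathway_genes):
            factor = 1.0
            if tel_on and gene in tel_signs:
                factor *= (
                    design.effect_size if tel_signs[gene] == "+" else 1.0 / design.effect_size
                )
            if alt_on and gene in alt_signs:
                factor *= (
                    design.effect_size if alt_signs[gene] == "+" else 1.0 / design.effect_size
                )
            shift[i] = factor
        for i in range(n):
            noise = 2.0 ** rng.normal(0.0, design.noise_sd, size=len(genes))
            columns.append(baseline * shift * noise)
            samples.append(f"{tag}_{i:02d}")
            labels.append(quadrant)

    values = pd.DataFrame(
        np.column_stack(columns) if columns else np.empty((len(genes), 0)),
        index=pd.Index(genes, name="gene"),
        columns=samples,
    )
    matrix = ExpressionMatrix(values=values, mode=design.mode)
    return matrix, pd.Series(labels, index=samples, name="quadrant")


def score_and_classify(
    matrix: ExpressionMatrix, labels: pd.Series
) -> tuple[pd.DataFrame, tuple]:
    """Fold changes -> PSF on both pathways -> max-margin fit -> quadrants.

    Thresholds are fitted per axis on the true labels; returns the activity
    table with a ``called`` column plus the fitted (TEL, ALT) boundaries.
    """
    fc = fold_changes(matrix)
    tel = load_tmm("TEL")
    alt = load_tmm("ALT")
    rows = []
    for sample in matrix.samples:
        vec = fc.values[sample].to_dict()
        tel_act = compute_psf(tel, vec, sample=sample).activity_log2
        alt_act = compute_psf(alt, vec, sample=sample).activity_log2
        rows.append((sample, tel_act, alt_act))
    table = pd.DataFrame(rows, columns=["sample", "TEL_log2", "ALT_log2"]).set_index("sample")

    tel_labels = ["pos" if "TEL+" in labels[s] else "neg" for s in table.index]
    alt_labels = ["pos" if "ALT+" in labels[s] else "neg" for s in table.index]
    tel_boundary = fit_axis_threshold(table["TEL_log2"], tel_labels, axis="TEL")
    alt_boundary = fit_axis_threshold(table["ALT_log2"], alt_labels, axis="ALT")
    boundaries = (tel_boundary, alt_boundary)

    table["called"] = [
        classify_phenotype(row.TEL_log2, row.ALT_log2, boundaries, sample=str(idx)).quadrant
        for idx, row in table.iterrows()
    ]
    table["truth"] = [labels[s] for s in table.index]
    return table, boundaries


def phenotype_recovery(design: SimulationDesign) -> float:
    """Fraction of simulated samples assigned their true quadrant end-to-end."""
    if any(n < 2 for n in design.n_per_quadrant.values()):
        raise ValueError("need >= 2 samples per quadrant for recovery analysis")
    matrix, labels = simulate_expression(design)
    table, _ = score_and_classify(matrix, labels)
    return float((table["called"] == table["truth"]).mean())
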