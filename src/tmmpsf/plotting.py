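"""Activity scatter plots; every plotted number also lands in a TSV twin."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .phenotype import AxisBoundary

_COLORS = {
    "TEL-/ALT-": "#2ca02c",
    "TEL+/ALT-": "#1f77b4",
    "TEL-/ALT+": "#d62728",
    "TEL+/ALT+": "#9467bd",
}


def render_scatter(
    phenotypes: pd.DataFrame,
    boundaries: tuple[AxisBoundary, AxisBoundary],
    path: str | Path | None = None,
    ax=None,
):
    """TEL (x) versus ALT (y) activity scatter with dashed threshold lines.

    Points are coloured by experimental annotation when an ``annotation``
    column is present, otherwise single-coloured.  When ``path`` is given
    the figure is saved there and the plotted numbers are written next to
    it with a ``.tsv`` suffix.
    """
    if phenotypes.empty:
        raise ValueError("cannot plot an empty activity table")
    tel_b, alt_b = boundaries
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))

    color_col = "annotation" if "annotation" in phenotypes.columns else None
    if color_col:
        for group, sub in phenotypes.groupby(color_col):
            ax.scatter(
                sub["TEL_log2"],
                sub["ALT_log2"],
                s=25,
                label=str(group) or "unannotated",
                color=_COLORS.get(str(group), "#7f7f7f"),
            )
        ax.legend(fontsize=8)
    else:
        ax.scatter(phenotypes["TEL_log2"], phenotypes["ALT_log2"], s=25, color="#1f77b4")

    ax.axvline(tel_b.threshold, linestyle="--", color="grey", linewidth=1)
    ax.axhline(alt_b.threshold, linestyle="--", color="grey", linewidth=1)
    ax.set_xlabel("TEL pathway activity (log2 PSF)")
    ax.set_ylabel("ALT pathway activity (log2 PSF)")
    ax.set_title("TMM pathway activity")

    if path is not None:
        path = Path(path)
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        twin_cols = [c for c in ("TEL_log2", "ALT_log2", "quadrant", "annotation") if c in phenotypes]
        phenotypes[twin_cols].to_csv(
            path.with_suffix(".tsv"), sep="\t", index_label="sample", float_format="%.10g"
        )
        plt.close(ax.figure)
    return ax
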