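"""Model/Results interface tying preprocessing, scoring and phenotyping together.

:class:`TMMModel` is constructed from an expression matrix (plus optional
experimental TMM annotations); :meth:`TMMModel.fit` runs fold-change
computation and pathway-signal-flow scoring on both packaged pathways,
fits (or fixes) the per-axis phenotype thresholds and returns a
:class:`TMMResults` carrying activities, boundaries, quadrant calls and
diagnostics, with partial-influence and plotting methods hanging off it.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from . import influence as _influence
from .catalog import load_tmm
from .pathway import Pathway
from .phenotype import (
    AxisBoundary,
    PhenotypeCall,
    agreement_report,
    classify_phenotype,
    fit_axis_threshold,
    fixed_boundary,
)
from .preprocess import (
    ExpressionMatrix,
    FoldChangeMatrix,
    cap_at_quantile,
    fold_changes,
)
from .psf import branch_summary, compute_psf, score_matrix


class TMMModel:
    """Telomere-maintenance phenotyping model over one expression data set.

    Parameters
    ----------
    expression
        Genes x samples matrix (microarray intensities or TPM).
    annotations
        Optional experimental labels per sample id (quadrant strings such as
        ``"TEL+/ALT-"``); used to fit max-margin thresholds and to report
        agreement.
    cap_quantile
        When set (e.g. 0.9), intensities above this global quantile are
        capped before fold-change computation.
    reference_mode
        Fold-change reference: ``"mean"``, ``"nonzero_mean"`` or ``None`` to
        pick by platform mode.
    version
        Packaged pathway catalog version.
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        annotations: Mapping[str, str] | None = None,
        cap_quantile: float | None = None,
        reference_mode: str | None = None,
        version: str = "2.0",
    ) -> None:
        self.expression = expression
        self.annotations = dict(annotations) if annotations else None
        self.cap_quantile = cap_quantile
        self.reference_mode = reference_mode
        self.tel: Pathway = load_tmm("TEL", version)
        self.alt: Pathway = load_tmm("ALT", version)

    @classmethod
    def from_dataframe(
        cls, values: pd.DataFrame, mode: str = "microarray", **kwargs
    ) -> "TMMModel":
        return cls(ExpressionMatrix(values=values, mode=mode), **kwargs)

    def fit(self, thresholds: str = "auto") -> "TMMResults":
        """Score all samples and fit the phenotype boundaries.

        ``thresholds``: ``"fit"`` requires annotations (max-margin per
        axis), ``"fixed"`` uses 0/0, ``"auto"`` fits when annotations are
        available and falls back to fixed 0/0 otherwise.
        """
        if thresholds not in {"auto", "fit", "fixed"}:
            raise ValueError(f"unknown thresholds mode {thresholds!r}")
        matrix = self.expression
        if self.cap_quantile is not None:
            matrix = cap_at_quantile(matrix, self.cap_quantile)
        fc = fold_changes(matrix, self.reference_mode)
        activities = pd.DataFrame(
            {
                "TEL_log2": score_matrix(self.tel, fc.values)["activity_log2"],
                "ALT_log2": score_matrix(self.alt, fc.values)["activity_log2"],
            }
        )

        if thresholds == "fit" and not self.annotations:
            raise ValueError("thresholds='fit' requires experimental annotations")
        if thresholds in {"auto", "fit"} and self.annotations:
            known = [s for s in activities.index if s in self.annotations]
            tel_b = fit_axis_threshold(
                activities.loc[known, "TEL_log2"],
                ["pos" if "TEL+" in self.annotations[s] else "neg" for s in known],
                axis="TEL",
            )
            alt_b = fit_axis_threshold(
                activities.loc[known, "ALT_log2"],
                ["pos" if "ALT+" in self.annotations[s] else "neg" for s in known],
                axis="ALT",
            )
        else:
            tel_b, alt_b = fixed_boundary("TEL"), fixed_boundary("ALT")
        return TMMResults(self, fc, activities, (tel_b, alt_b))


class TMMResults:
    """Fitted activities, boundaries and phenotype calls."""

    def __init__(
        self,
        model: TMMModel,
        fold_change: FoldChangeMatrix,
        activities: pd.DataFrame,
        boundaries: tuple[AxisBoundary, AxisBoundary],
    ) -> None:
        self.model = model
        self.fold_change = fold_change
        self.activities = activities
        self.boundaries = boundaries
        self.calls: list[PhenotypeCall] = [
            classify_phenotype(row.TEL_log2, row.ALT_log2, boundaries, sample=str(idx))
            for idx, row in activities.iterrows()
        ]

    # -- tables -----------------------------------------------------------------

    @property
    def phenotypes(self) -> pd.DataFrame:
        """Activity + quadrant (+ annotation/match when available) per sample."""
        df = self.activities.copy()
        df["quadrant"] = [c.quadrant for c in self.calls]
        if self.model.annotations:
            df["annotation"] = [
                self.model.annotations.get(str(s), "") for s in df.index
            ]
            df["match"] = (df["annotation"] == df["quadrant"]) & (df["annotation"] != "")
        return df

    def agreement(self) -> dict:
        """Agreement report against the experimental annotations."""
        if not self.model.annotations:
            raise ValueError("no experimental annotations were provided")
        return agreement_report(self.calls, self.model.annotations)

    def summary(self) -> str:
        """Plain-text summary of thresholds, quadrant counts and agreement."""
        tel_b, alt_b = self.boundaries
        counts = pd.Series([c.quadrant for c in self.calls]).value_counts()
        lines = [
            "TMM pathway activity phenotyping",
            "=" * 40,
            f"samples:            {len(self.calls)}",
            f"pathway version:    TMM v{self.model.tel.version}",
            f"fold-change ref:    {self.fold_change.reference_mode}",
            f"TEL threshold:      {tel_b.threshold:+.4f} (margin {tel_b.margin:.4f}, {tel_b.method})",
            f"ALT threshold:      {alt_b.threshold:+.4f} (margin {alt_b.margin:.4f}, {alt_b.method})",
            "quadrant counts:",
        ]
        for quadrant, count in counts.items():
            lines.append(f"  {quadrant:<12} {count}")
        if self.model.annotations:
            report = self.agreement()
            lines.append(f"overall agreement:  {report['overall_agreement']:.1%}")
        return "\n".join(lines)

    # -- gene-level diagnostics -------------------------------------------------

    def _pathway(self, name: str) -> Pathway:
        if name.upper() == "TEL":
            return self.model.tel
        if name.upper() == "ALT":
            return self.model.alt
        raise KeyError(f"unknown pathway {name!r}; expected 'TEL' or 'ALT'")

    def pi_profile(self, sample: str, pathway: str = "TEL"):
        """Ranked partial-influence records for one sample."""
        vec = self.fold_change.sample_vector(sample)
        return _influence.pi_profile(self._pathway(pathway), vec)

    def mean_sample_pi(self, pathway: str = "TEL"):
        """PI profile of the cohort mean sample."""
        return _influence.mean_sample_pi(self._pathway(pathway), self.fold_change)

    def branch_summary(self, sample: str, pathway: str = "TEL") -> pd.DataFrame:
        """Per-branch activation table for one sample."""
        p = self._pathway(pathway)
        result = compute_psf(p, self.fold_change.sample_vector(sample), sample=sample)
        return branch_summary(result, p)

    # -- output -----------------------------------------------------------------

    def plot_scatter(self, path: str | Path | None = None, ax=None):
        """TEL-vs-ALT activity scatter with dashed threshold lines."""
        from .plotting import render_scatter

        return render_scatter(self.phenotypes, self.boundaries, path=path, ax=ax)

    def save(self, outdir: str | Path) -> None:
        """Write the phenotype table, thresholds and scatter TSV twin."""
        import json

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.phenotypes.to_csv(
            outdir / "phenotypes.tsv", sep="\t", index_label="sample", float_format="%.10g"
        )
        tel_b, alt_b = self.boundaries
        (outdir / "thresholds.json").write_text(
            json.dumps(
                {
                    "TEL": {"threshold": tel_b.threshold, "margin": tel_b.margin, "method": tel_b.method},
                    "ALT": {"threshold": alt_b.threshold, "margin": alt_b.margin, "method": alt_b.method},
                },
                indent=1,
            )
            + "\n"
        )
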