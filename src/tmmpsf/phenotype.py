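"""Max-margin quadrant phenotyping on (TEL, ALT) activity axes.

Samples are placed in a 2-D coordinate system of TEL and ALT pathway
activities (log2 scale, 0 = neutral).  Each axis gets an independent 1-D
decision threshold: with experimental labels the threshold is the
max-margin separator (midpoint of the innermost opposite-label pair; for
non-separable data the error-minimising cut), without labels it defaults
to 0.  The two axis calls combine into one of four phenotype quadrants:
TEL-/ALT-, TEL+/ALT-, TEL-/ALT+, TEL+/ALT+.  A value exactly on a
threshold counts as negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

QUADRANTS = ("TEL-/ALT-", "TEL+/ALT-", "TEL-/ALT+", "TEL+/ALT+")


@dataclass(frozen=True)
class AxisBoundary:
    """Decision threshold for one activity axis."""

    axis: str  # "TEL" or "ALT"
    threshold: float
    margin: float
    method: str = "max_margin"  # or "fixed"

    def is_positive(self, value: float) -> bool:
        return value > self.threshold


def fixed_boundary(axis: str, threshold: float = 0.0) -> AxisBoundary:
    return AxisBoundary(axis=axis, threshold=threshold, margin=0.0, method="fixed")


@dataclass(frozen=True)
class PhenotypeCall:
    """Joint (TEL, ALT) phenotype assignment for one sample."""

    sample: str
    tel_log2: float
    alt_log2: float
    quadrant: str


def fit_axis_threshold(
    values: Sequence[float], labels: Sequence[str], axis: str = "TEL"
) -> AxisBoundary:
    """Fit the 1-D max-margin threshold separating pos (above) from neg.

    For separable data the threshold is the midpoint of the innermost
    opposite-label pair and the margin is half their gap.  For
    non-separable data the threshold minimises misclassifications, with
    ties broken by larger margin, then by smaller threshold.  The
    orientation is fixed: positive means strictly greater than the
    threshold.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must align")
    is_pos = labels == "pos"
    is_neg = labels == "neg"
    if not (is_pos | is_neg).all():
        bad = labels[~(is_pos | is_neg)]
        raise ValueError(f"labels must be 'pos'/'neg'; got {bad[:3].tolist()}")
    if not is_pos.any() or not is_neg.any():
        raise ValueError("both labels must be present to fit a threshold")

    distinct = np.unique(values)
    candidates = [float(distinct[0]) - 1.0]
    candidates += [float(a + b) / 2.0 for a, b in zip(distinct[:-1], distinct[1:])]
    candidates += [float(distinct[-1]) + 1.0]

    best: tuple[int, float, float] | None = None
    for t in candidates:
        errors = int(np.sum(is_pos & (values <= t)) + np.sum(is_neg & (values > t)))
        margin = float(np.min(np.abs(values - t)))
        key = (errors, -margin, t)
        if best is None or key < best:
            best = key
    errors, neg_margin, threshold = best
    return AxisBoundary(axis=axis, threshold=threshold, margin=-neg_margin, method="max_margin")


def classify_phenotype(
    tel_log2: float,
    alt_log2: float,
    boundaries: tuple[AxisBoundary, AxisBoundary] | None = None,
    sample: str = "sample",
) -> PhenotypeCall:
    """Assign the quadrant for one (TEL, ALT) activity pair.

    ``boundaries`` is a (TEL, ALT) pair; without it both thresholds default
    to 0 on the log2 activity scale.
    """
    if boundaries is None:
        boundaries = (fixed_boundary("TEL"), fixed_boundary("ALT"))
    tel_b, alt_b = boundaries
    tel = "+" if tel_b.is_positive(tel_log2) else "-"
    alt = "+" if alt_b.is_positive(alt_log2) else "-"
    return PhenotypeCall(
        sample=sample,
        tel_log2=float(tel_log2),
        alt_log2=float(alt_log2),
        quadrant=f"TEL{tel}/ALT{alt}",
    )


def classify_table(
    activities: pd.DataFrame,
    boundaries: tuple[AxisBoundary, AxisBoundary] | None = None,
) -> pd.DataFrame:
    """Classify a table with ``TEL_log2``/``ALT_log2`` columns per sample."""
    calls = [
        classify_phenotype(row.TEL_log2, row.ALT_log2, boundaries, sample=str(idx))
        for idx, row in activities.iterrows()
    ]
    out = activities.copy()
    out["quadrant"] = [c.quadrant for c in calls]
    return out


def replicate_pairs(sample_ids: Sequence[str]) -> list[tuple[str, str]]:
    """Pair technical replicates whose ids share a stem with _1/_2 suffixes."""
    stems: dict[str, dict[str, str]] = {}
    for sid in sample_ids:
        if sid.endswith(("_1", "_2")):
            stems.setdefault(sid[:-2], {})[sid[-1]] = sid
    return [
        (pair["1"], pair["2"])
        for stem, pair in sorted(stems.items())
        if "1" in pair and "2" in pair
    ]


def agreement_report(
    calls: Sequence[PhenotypeCall], annotations: dict[str, str]
) -> dict:
    """Compare phenotype calls against experimental annotations.

    Returns overall and per-phenotype agreement fractions, the confusion
    table (annotation x call), and concordance of technical replicate pairs
    (ids suffixed ``_1``/``_2``).
    """
    call_by_id = {c.sample: c for c in calls}
    missing = sorted(set(annotations) - set(call_by_id))
    if missing:
        raise KeyError(f"annotated samples without calls: {missing[:5]}")

    rows = [
        (sid, annotations[sid], call_by_id[sid].quadrant)
        for sid in sorted(annotations)
    ]
    df = pd.DataFrame(rows, columns=["sample", "annotation", "call"])
    df["match"] = df["annotation"] == df["call"]
    confusion = pd.crosstab(df["annotation"], df["call"])
    per_class = df.groupby("annotation")["match"].mean().to_dict()

    replicate_status = {}
    for first, second in replicate_pairs(list(call_by_id)):
        concordant = call_by_id[first].quadrant == call_by_id[second].quadrant
        replicate_status[first[:-2]] = "concordant" if concordant else "discordant"

    return {
        "overall_agreement": float(df["match"].mean()),
        "per_class_agreement": per_class,
        "confusion": confusion,
        "table": df,
        "replicates": replicate_status,
    }
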