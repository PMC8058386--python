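"""Expression preprocessing: probe collapsing, capping and fold changes.

The scoring engine consumes per-sample fold changes (FC) of each pathway
gene relative to its reference expression across the data set.  For
microarray intensities the reference is the per-gene mean over all samples;
for RNA-seq TPM it is the per-gene mean over samples with non-zero TPM.
Multi-probe platforms are first collapsed to one probe per gene (the probe
with the largest standard deviation across samples), and extreme
intensities may be capped at a global quantile of the data set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: clipping bound for fold changes: zeros become EPS so downstream
#: reciprocals (inhibition) stay finite
EPS = 1e-6

MODES = ("microarray", "tpm")
REFERENCE_MODES = ("mean", "nonzero_mean")


@dataclass
class ExpressionMatrix:
    """A genes x samples non-negative expression table.

    ``values`` is a :class:`pandas.DataFrame` indexed by gene id with sample
    ids as columns; ``mode`` records the platform (``microarray`` or
    ``tpm``), which selects the default fold-change reference.
    """

    values: pd.DataFrame
    mode: str = "microarray"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown platform mode {self.mode!r}; expected one of {MODES}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids after collapsing: {dupes[:5]}")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if (arr < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class FoldChangeMatrix:
    """Per-gene, per-sample fold changes; neutral value is 1."""

    values: pd.DataFrame
    reference_mode: str = "mean"

    def __post_init__(self) -> None:
        if self.reference_mode not in REFERENCE_MODES:
            raise ValueError(
                f"unknown reference mode {self.reference_mode!r}; "
                f"expected one of {REFERENCE_MODES}"
            )

    def sample_vector(self, sample: str) -> dict[str, float]:
        """FC vector for one sample as a gene -> value mapping."""
        return self.values[sample].to_dict()

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def collapse_probes(
    probe_matrix: pd.DataFrame, probe_to_gene: dict[str, str] | pd.Series
) -> pd.DataFrame:
    """Collapse a probes x samples table to one row per gene.

    For each gene, the mapped probe with the largest population standard
    deviation across samples is kept (ties broken by ascending probe id);
    unmapped probes are dropped with a logged count.
    """
    if isinstance(probe_to_gene, pd.Series):
        probe_to_gene = probe_to_gene.to_dict()
    if not probe_to_gene:
        raise ValueError("empty probe-to-gene mapping")
    mapped = [p for p in probe_matrix.index if p in probe_to_gene]
    dropped = len(probe_matrix.index) - len(mapped)
    if dropped:
        log.info("collapse_probes: dropped %d unmapped probes", dropped)
    if not mapped:
        raise ValueError("no probe in the matrix maps to a gene symbol")

    sub = probe_matrix.loc[mapped]
    sd = sub.std(axis=1, ddof=0)
    # highest SD wins; ties broken by ascending probe id
    best: dict[str, str] = {}
    for probe in sorted(sub.index):
        gene = probe_to_gene[probe]
        if gene not in best or sd[probe] > sd[best[gene]]:
            best[gene] = probe
    collapsed = sub.loc[sorted(best.values())]
    collapsed.index = pd.Index([probe_to_gene[p] for p in collapsed.index], name="gene")
    return collapsed.sort_index()


def cap_at_quantile(matrix: ExpressionMatrix, q: float = 0.9) -> ExpressionMatrix:
    """Cap all values above the global ``q``-quantile at that quantile.

    The quantile is computed over all entries of the matrix with the
    linear-interpolation definition; the operation is idempotent and
    preserves the rank order of values at or below the cap.
    """
    if not 0 < q <= 1:
        raise ValueError(f"quantile must be in (0, 1], got {q}")
    arr = matrix.values.to_numpy(dtype=float)
    if arr.size == 0:
        raise ValueError("cannot cap an empty matrix")
    cap = float(np.quantile(arr, q))
    capped = matrix.values.clip(upper=cap)
    return ExpressionMatrix(values=capped, mode=matrix.mode)


def fold_changes(
    matrix: ExpressionMatrix, reference_mode: str | None = None
) -> FoldChangeMatrix:
    """Per-gene fold changes relative to the data-set reference expression.

    ``reference_mode="mean"`` divides by the per-gene mean over all samples
    (microarray default); ``"nonzero_mean"`` divides by the mean over
    samples with value > 0 (TPM default).  Results are clipped to
    ``[1e-6, 1e6]``; genes with an undefined reference (all-zero rows) get
    FC 1 in every sample with a logged warning.
    """
    if reference_mode is None:
        reference_mode = "nonzero_mean" if matrix.mode == "tpm" else "mean"
    if reference_mode not in REFERENCE_MODES:
        raise ValueError(f"unknown reference mode {reference_mode!r}")
    values = matrix.values
    if values.empty:
        raise ValueError("cannot compute fold changes of an empty matrix")
    arr = values.to_numpy(dtype=float)
    if reference_mode == "mean":
        ref = arr.mean(axis=1)
    else:
        with np.errstate(invalid="ignore"):
            masked = np.where(arr > 0, arr, np.nan)
            ref = np.nanmean(masked, axis=1)
        ref = np.nan_to_num(ref, nan=0.0)
    undefined = ref <= 0
    if undefined.any():
        log.warning(
            "fold_changes: %d gene(s) with undefined reference set to FC 1: %s",
            int(undefined.sum()),
            values.index[undefined][:5].tolist(),
        )
    safe_ref = np.where(undefined, 1.0, ref)
    fc = arr / safe_ref[:, None]
    fc[undefined, :] = 1.0
    fc = np.clip(fc, EPS, 1.0 / EPS)
    return FoldChangeMatrix(
        values=pd.DataFrame(fc, index=values.index, columns=values.columns),
        reference_mode=reference_mode,
    )


# ---------------------------------------------------------------------------
# file formats


def read_expression_tsv(path: str | Path, mode: str = "microarray") -> ExpressionMatrix:
    """Read a TSV with gene/probe ids in the first column, samples in the header."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(values=df.astype(float), mode=mode)


def read_expression_gct(path: str | Path, mode: str = "tpm") -> ExpressionMatrix:
    """Read a GCT 1.2 file (GTEx-style): gene Name/Description + sample columns.

    Rows are collapsed on the ``Description`` (gene symbol) column by keeping
    the row with the largest standard deviation, mirroring probe collapsing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression file not found: {path}")
    with open(path) as handle:
        magic = handle.readline().strip()
        if not magic.startswith("#1.2"):
            raise ValueError(f"{path}: not a GCT 1.2 file (first line {magic!r})")
        handle.readline()  # dimensions line
        df = pd.read_csv(handle, sep="\t")
    if df.shape[1] < 3 or df.columns[0] != "Name":
        raise ValueError(f"{path}: malformed GCT header")
    symbols = df[df.columns[1]].astype(str)
    data = df.set_index(df.columns[0]).drop(columns=[df.columns[1]]).astype(float)
    if symbols.duplicated().any():
        collapsed = collapse_probes(data, dict(zip(df[df.columns[0]], symbols)))
    else:
        collapsed = data.set_axis(pd.Index(symbols, name="gene"), axis=0)
    return ExpressionMatrix(values=collapsed, mode=mode)


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (probe id, gene symbol); header optional."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: probe map needs two columns")
    first = df.iloc[0]
    if first.iloc[0].lower() in {"probe", "probe_id", "id"}:
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_fold_changes(fc: FoldChangeMatrix, path: str | Path) -> None:
    fc.values.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")
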