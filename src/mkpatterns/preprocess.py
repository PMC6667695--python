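"""Probe-level preprocessing: flooring, quantile normalization, annotation
filtering, probe-to-gene collapsing, and normalization to untreated wild-type.

Pipeline order is fixed::

    floor -> quantile_normalize -> [baseline_to_median, export only]
          -> filter_annotated -> collapse_probes -> normalize_to_untreated_wt

Classification downstream works on ratios of means, which per-probe log2
median-centering does not change, so ``baseline_to_median`` exists for
exported log-scale tables but is not part of the quantitative path.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import GeneMatrix, select_samples

log = logging.getLogger(__name__)


def floor_intensities(matrix: pd.DataFrame, floor: float = 5.0) -> pd.DataFrame:
    """Replace every intensity below ``floor`` with ``floor``.

    Single-channel background subtraction can leave small or negative
    intensities; flooring at 5 avoids negative or exploding ratios.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    return matrix.clip(lower=floor)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize sample columns against the per-rank mean distribution.

    After the transform the sorted value vector of every column equals the
    mean of the sorted input columns.  Within-column order is preserved;
    tied values all receive the mean of the reference values over their
    rank span.
    """
    if matrix.empty:
        raise ValueError("cannot quantile-normalize an empty matrix")
    vals = matrix.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("matrix contains non-finite values")
    n, _ = vals.shape
    reference = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="mergesort")
        ranked = col[order]
        i = 0
        while i < n:
            k = i
            while k + 1 < n and ranked[k + 1] == ranked[i]:
                k += 1
            out[order[i : k + 1], j] = reference[i : k + 1].mean()
            i = k + 1
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def baseline_to_median(matrix: pd.DataFrame, scale: str = "linear") -> pd.DataFrame:
    """Per-probe log2 median-centering ("baseline transformation").

    ``scale`` tags the input: ``"linear"`` intensities are log2-transformed
    first (all values must be positive — floor first), ``"log2"`` input is
    centered as-is, which makes the operation idempotent.  Output is always
    on the log2 scale.
    """
    if scale not in ("linear", "log2"):
        raise ValueError(f"scale must be 'linear' or 'log2', got {scale!r}")
    if scale == "linear":
        if (matrix.to_numpy() <= 0).any():
            raise ValueError("non-positive intensity; apply floor_intensities first")
        logm = np.log2(matrix)
    else:
        logm = matrix
    return logm.sub(logm.median(axis=1), axis=0)


def filter_annotated(matrix: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Keep probes annotated to a gene of known function, preserving order.

    Probes absent from the annotation table count as unannotated and are
    dropped, as are probes with ``known_function`` false.
    """
    known = annotation.loc[annotation["known_function"].astype(bool), "probe_id"]
    keep = matrix.index.isin(set(known))
    out = matrix.loc[keep]
    log.info("annotation filter: %d of %d probes retained", len(out), len(matrix))
    return out


def wt_induction(matrix: pd.DataFrame, samples: pd.DataFrame, timepoint: int) -> pd.Series:
    """Per-probe wild-type LPS induction: mean(wt LPS at timepoint) / mean(wt untreated)."""
    lps = select_samples(samples, "wt", "LPS", timepoint)
    untr = select_samples(samples, "wt", "untreated")
    if not lps or not untr:
        raise ValueError(f"wt LPS (t={timepoint}) and wt untreated samples are both required")
    return matrix[lps].mean(axis=1) / matrix[untr].mean(axis=1)


def collapse_probes(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    samples: pd.DataFrame,
    timepoint: int = 120,
) -> GeneMatrix:
    """Collapse multi-probe genes to the single probe with the highest
    wild-type LPS induction at ``timepoint``.

    Exact induction ties are broken toward the lexicographically smallest
    probe id, which keeps the choice deterministic and auditable.  Genes
    whose probes were all filtered out are simply absent from the output.
    """
    induction = wt_induction(matrix, samples, timepoint)
    annot = annotation.set_index("probe_id")["gene_symbol"]
    table = pd.DataFrame(
        {
            "probe_id": matrix.index,
            "gene": annot.reindex(matrix.index).to_numpy(),
            "induction": induction.to_numpy(),
        }
    )
    table = table[table["gene"].notna() & (table["gene"] != "")]
    chosen = (
        table.sort_values(["induction", "probe_id"], ascending=[False, True])
        .groupby("gene", sort=True)
        .head(1)
        .sort_values("gene")
    )
    values = matrix.loc[chosen["probe_id"]].copy()
    values.index = pd.Index(chosen["gene"].to_numpy(), name="gene")
    provenance = pd.Series(chosen["probe_id"].to_numpy(), index=values.index, name="probe_id")
    log.info("collapse: %d probes -> %d genes (wt induction at t=%d)", len(table), len(values), timepoint)
    return GeneMatrix(values=values, samples=samples, probe_of_gene=provenance)


def normalize_to_untreated_wt(gm: GeneMatrix) -> GeneMatrix:
    """Express every gene relative to its mean in untreated wild-type
    samples, so that mean == 1 there.  Ratios between conditions are
    unchanged (the operation is a per-gene rescaling)."""
    untr_wt = select_samples(gm.samples, "wt", "untreated")
    if not untr_wt:
        raise ValueError("no untreated wt samples present")
    ref = gm.values[untr_wt].mean(axis=1)
    if (ref <= 0).any():
        raise ValueError("non-positive untreated-wt mean; floor intensities first")
    values = gm.values.div(ref, axis=0)
    return GeneMatrix(values=values, samples=gm.samples, probe_of_gene=gm.probe_of_gene)


def preprocess_pipeline(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    annotation: pd.DataFrame,
    floor: float = 5.0,
    collapse_timepoint: int = 120,
) -> GeneMatrix:
    """Full probe-to-gene preprocessing in the fixed stage order."""
    log.info("preprocess: input %d probes x %d samples", *matrix.shape)
    floored = floor_intensities(matrix, floor)
    normalized = quantile_normalize(floored)
    annotated = filter_annotated(normalized, annotation)
    collapsed = collapse_probes(annotated, annotation, samples, collapse_timepoint)
    return normalize_to_untreated_wt(collapsed)
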