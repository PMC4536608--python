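"""Copy-number masking: remove CN-affected expression measurements per cell.

Apparent coordinate expression across a chromosomal segment can be a pure
dosage artifact: a deletion or amplification shifts every spanned gene in
the affected samples, which neighboring genes then "share".  Masking sets
each (gene, sample) cell with a non-neutral copy-number call to missing, so
downstream correlations are computed on copy-number-neutral measurements
only.  Masking is per cell: a gene masked in one sample still contributes
its other samples to every correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import CopyNumberCallSet, ExpressionMatrix

__all__ = ["MaskReport", "call_copy_number", "mask_expression"]


@dataclass(frozen=True)
class MaskReport:
    """Accounting of newly masked cells."""

    n_cells_masked: int
    per_sample_counts: dict[str, int]
    per_gene_counts: dict[str, int]


def call_copy_number(
    log_ratios: pd.DataFrame | ExpressionMatrix,
    loss_threshold: float = -0.3,
    gain_threshold: float = 0.3,
) -> CopyNumberCallSet:
    """Threshold aCGH log2 ratios into loss/neutral/gain calls.

    A deliberately simple caller: ratio <= ``loss_threshold`` is a loss,
    ratio >= ``gain_threshold`` a gain, anything else (including missing)
    neutral.  Defaults of +/-0.3 log2 are conventional single-copy-change
    bounds.  Externally produced call sets (e.g. from a segmentation-based
    caller) can be supplied to :func:`mask_expression` instead.
    """
    if not loss_threshold < 0 < gain_threshold:
        raise ValueError(
            f"need loss_threshold < 0 < gain_threshold, got "
            f"({loss_threshold}, {gain_threshold})"
        )
    df = log_ratios.data if isinstance(log_ratios, ExpressionMatrix) else log_ratios
    values = df.to_numpy(dtype=float)
    rows = []
    loss_i, loss_j = np.where(values <= loss_threshold)
    gain_i, gain_j = np.where(values >= gain_threshold)
    for i, j in zip(loss_i, loss_j):
        rows.append((df.index[i], df.columns[j], "loss"))
    for i, j in zip(gain_i, gain_j):
        rows.append((df.index[i], df.columns[j], "gain"))
    if not rows:
        return CopyNumberCallSet.empty()
    return CopyNumberCallSet(
        pd.DataFrame(rows, columns=["gene_id", "sample_id", "call"])
    )


def mask_expression(
    expr: ExpressionMatrix, calls: CopyNumberCallSet
) -> tuple[ExpressionMatrix, MaskReport]:
    """Set every (gene, sample) cell with a non-neutral call to missing.

    All other values are unchanged; the report counts exactly the cells that
    were newly masked (cells already missing are not re-counted).  Unknown
    genes or samples in the call set are rejected by name.  The operation is
    idempotent and never un-masks.
    """
    non_neutral = calls.non_neutral()
    unknown_genes = set(non_neutral["gene_id"]) - set(expr.gene_ids)
    if unknown_genes:
        raise KeyError(f"call set names unknown gene {sorted(unknown_genes)[0]!r}")
    unknown_samples = set(non_neutral["sample_id"]) - set(expr.sample_ids)
    if unknown_samples:
        raise KeyError(f"call set names unknown sample {sorted(unknown_samples)[0]!r}")

    data = expr.data.copy()
    gene_pos = {g: i for i, g in enumerate(data.index)}
    sample_pos = {s: j for j, s in enumerate(data.columns)}
    values = data.to_numpy()
    per_gene: dict[str, int] = {}
    per_sample: dict[str, int] = {}
    n_masked = 0
    for gene, sample in zip(non_neutral["gene_id"], non_neutral["sample_id"]):
        i, j = gene_pos[gene], sample_pos[sample]
        if not np.isnan(values[i, j]):
            values[i, j] = np.nan
            n_masked += 1
            per_gene[gene] = per_gene.get(gene, 0) + 1
            per_sample[sample] = per_sample.get(sample, 0) + 1
    masked = ExpressionMatrix(pd.DataFrame(values, index=data.index, columns=data.columns))
    return masked, MaskReport(n_masked, per_sample, per_gene)
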