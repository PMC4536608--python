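"""Delineation, trimming and multiscale resolution of RER regions.

Each significant-TCS gene seeds a candidate window of itself plus ``n``
genes either side (the genes of its sliding window, clipped at chromosome
ends).  Overlapping or book-ended candidate windows on a chromosome are
merged, and merged regions with fewer than two significant genes are
discarded.

Trimming then refines each region against the data: a representative
per-sample profile is formed as the median over member genes (excluding
the gene under test, so self-correlation cannot inflate retention), every
member gene is Spearman-correlated against it, and genes whose correlation
does not reach ``p < alpha`` are trimmed from the flanks.  Two trimming
modes are provided:

* ``"contiguous"`` (default) keeps the maximal run of consecutively
  correlated genes around the significant-TCS core.  An isolated flank gene
  that correlates by chance cannot drag the region boundary out to it,
  which keeps trimmed boundaries tight against embedded-domain edges.
* ``"extent"`` keeps everything between the first and the last correlated
  member gene, a literal min/max reading of the same refinement.  With
  ~2n flanking genes per region and alpha = 0.05, chance correlations
  extend roughly half of all region boundaries under this mode, which is
  why it is not the default.

A multiscale scan re-runs scoring at several window sizes (n = 1..10 in the
classic use) and records the gene-by-window significance matrix; a broad
region that is a union of independent sub-domains separates into distinct
significant blocks as the window shrinks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix, GeneTable
from .tcs_core import TCSParams, compute_tcs, tcs_significance

__all__ = [
    "RERRegion",
    "delineate_regions",
    "trim_region",
    "multiscale_scan",
    "call_rer_regions",
]


@dataclass(frozen=True)
class RERRegion:
    """A delineated region of coordinate expression.

    ``start``/``end`` span the first to last member gene; ``span_sig``
    measures first to last *significant* gene, the size convention used for
    reporting.  ``member_genes`` are contiguous in genome order.
    """

    region_id: str
    chrom: str
    start: int
    end: int
    member_genes: tuple[str, ...]
    significant_genes: tuple[str, ...]
    span_sig: int
    window_n: int
    trimmed: bool = False
    discarded: bool = False
    warning: str | None = None

    @property
    def span(self) -> int:
        return self.end - self.start

    def __len__(self) -> int:
        return len(self.member_genes)


def _region_from_member_rows(
    rows: pd.DataFrame,
    sig_ids: set[str],
    region_id: str,
    window_n: int,
    **flags,
) -> RERRegion:
    members = tuple(rows["gene_id"])
    sig = tuple(g for g in members if g in sig_ids)
    sig_rows = rows[rows["gene_id"].isin(sig)]
    span_sig = (
        int(sig_rows["end"].max() - sig_rows["start"].min()) if len(sig_rows) else 0
    )
    return RERRegion(
        region_id=region_id,
        chrom=str(rows["chrom"].iloc[0]),
        start=int(rows["start"].min()),
        end=int(rows["end"].max()),
        member_genes=members,
        significant_genes=sig,
        span_sig=span_sig,
        window_n=window_n,
        **flags,
    )


def delineate_regions(
    tcs_table: pd.DataFrame, genes: GeneTable, n: int = 10
) -> list[RERRegion]:
    """Merge the sliding windows of significant genes into candidate regions.

    ``tcs_table`` must carry a boolean ``significant`` column (from
    :func:`~rer_scan.tcs_core.tcs_significance` or a fixed cutoff).  Merging
    is order-independent: candidate windows are gene-index intervals and any
    pair that overlaps or shares a boundary gene is merged.  Regions with
    fewer than two significant genes are discarded.  Output is sorted by
    (chrom, start) and numbered ``RER-001`` onwards.
    """
    if "significant" not in tcs_table.columns:
        raise ValueError("tcs_table has no 'significant' column; run tcs_significance")
    regions: list[RERRegion] = []
    table = tcs_table.reset_index()
    for chrom in dict.fromkeys(table["chrom"]):
        sub = table[table["chrom"] == chrom].sort_values("order_index")
        order = sub["order_index"].to_numpy()
        sig_mask = sub["significant"].to_numpy(dtype=bool)
        if not sig_mask.any():
            continue
        lo, hi = int(order.min()), int(order.max())
        seeds = order[sig_mask]
        windows = [(max(s - n, lo), min(s + n, hi)) for s in seeds]
        merged: list[list[int]] = []
        for a, b in windows:  # seeds are sorted, so a single sweep merges all
            if merged and a <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        sig_ids = set(sub.loc[sig_mask, "gene_id"] if "gene_id" in sub else [])
        for a, b in merged:
            rows = sub[(order >= a) & (order <= b)]
            region = _region_from_member_rows(rows, sig_ids, "tmp", n)
            if len(region.significant_genes) >= 2:
                regions.append(region)
    regions.sort(key=lambda r: (r.chrom, r.start))
    return [
        dataclasses.replace(r, region_id=f"RER-{i + 1:03d}")
        for i, r in enumerate(regions)
    ]


def _member_rows(region: RERRegion, genes: GeneTable) -> pd.DataFrame:
    gmap = genes.data.set_index("gene_id")
    rows = gmap.loc[list(region.member_genes)].reset_index()
    return rows


def trim_region(
    region: RERRegion,
    expr: ExpressionMatrix,
    genes: GeneTable,
    alpha: float = 0.05,
    mode: str = "contiguous",
) -> RERRegion:
    """Trim a region to the member genes correlated with its own profile.

    For each member gene, a representative per-sample profile is computed
    as the median over the *other* member genes; the gene is kept when its
    Spearman correlation against that profile reaches ``p < alpha``
    (two-sided).  ``mode`` selects how the retained set defines the new
    boundaries (see module docstring).  Significant genes are re-clipped to
    the new boundaries; a region left with fewer than two significant genes
    is flagged ``discarded``.  Regions of fewer than three members are
    returned unchanged with a warning flag.
    """
    if mode not in ("contiguous", "extent"):
        raise ValueError(f"mode must be 'contiguous' or 'extent', got {mode!r}")
    if len(region.member_genes) < 3:
        return dataclasses.replace(region, warning="too few member genes to trim")
    missing = [g for g in region.member_genes if g not in expr.gene_ids]
    if missing:
        raise KeyError(f"member gene {missing[0]!r} absent from expression matrix")

    X = expr.data.loc[list(region.member_genes)].to_numpy(dtype=float)
    m = X.shape[0]
    keep = np.zeros(m, dtype=bool)
    for i in range(m):
        others = np.delete(X, i, axis=0)
        rep = np.nanmedian(others, axis=0)
        ok = ~(np.isnan(X[i]) | np.isnan(rep))
        if ok.sum() < 3:
            continue
        xi, ri = X[i][ok], rep[ok]
        if np.all(xi == xi[0]) or np.all(ri == ri[0]):
            continue
        res = stats.spearmanr(xi, ri)
        keep[i] = res.pvalue < alpha

    if not keep.any():
        return dataclasses.replace(region, trimmed=True, discarded=True)

    if mode == "extent":
        first, last = int(np.argmax(keep)), int(m - 1 - np.argmax(keep[::-1]))
    else:
        runs = []  # (first, last) of each maximal run of kept genes
        i = 0
        while i < m:
            if keep[i]:
                j = i
                while j + 1 < m and keep[j + 1]:
                    j += 1
                runs.append((i, j))
                i = j + 1
            else:
                i += 1
        sig_set = set(region.significant_genes)
        members = list(region.member_genes)

        def run_score(run: tuple[int, int]) -> tuple[int, int, int]:
            a, b = run
            n_sig = sum(1 for g in members[a : b + 1] if g in sig_set)
            return (n_sig, b - a, -a)  # most core genes, then longest, then leftmost

        first, last = max(runs, key=run_score)

    rows = _member_rows(region, genes).iloc[first : last + 1]
    trimmed = _region_from_member_rows(
        rows,
        set(region.significant_genes),
        region.region_id,
        region.window_n,
        trimmed=True,
    )
    if len(trimmed.significant_genes) < 2:
        trimmed = dataclasses.replace(trimmed, discarded=True)
    return trimmed


def multiscale_scan(
    expr: ExpressionMatrix,
    genes: GeneTable,
    n_values: Sequence[int],
    alpha: float = 0.05,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Gene-by-window-size significance matrix.

    Runs the TCS scan once per window half-size in ``n_values`` and returns
    a boolean frame (genes in genome order x window sizes).  No region
    logic is applied; sub-domain structure shows up as significant blocks
    that separate as n shrinks.
    """
    if not n_values:
        raise ValueError("n_values must be non-empty")
    columns = {}
    for n in n_values:
        params = TCSParams(n=n, alpha=alpha, min_pairs=min_pairs)
        table = tcs_significance(compute_tcs(expr, genes, params), alpha)
        columns[n] = table["significant"]
    return pd.DataFrame(columns)


def call_rer_regions(
    expr: ExpressionMatrix,
    genes: GeneTable,
    params: TCSParams = TCSParams(),
    trim: bool = True,
    trim_mode: str = "contiguous",
) -> tuple[pd.DataFrame, list[RERRegion]]:
    """Full detection chain: score, flag, delineate and (optionally) trim.

    Returns the significance-annotated TCS table and the list of surviving
    regions (trim-discarded regions are dropped; every returned region has
    at least two significant genes).
    """
    table = tcs_significance(compute_tcs(expr, genes, params), params.alpha)
    regions = delineate_regions(table, genes, params.n)
    if trim:
        regions = [
            trim_region(r, expr, genes, params.alpha, mode=trim_mode) for r in regions
        ]
        regions = [r for r in regions if not r.discarded]
    return table, regions
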