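"""Region-level expression summaries, clustering and association tests.

The regional expression of an RER region in a sample is the mean z score of
its significant-TCS genes: each gene is z-scored across samples first, so a
region row summarizes coordinate deviation from each gene's own typical
level, not absolute expression.  Region rows are clustered (Ward linkage,
Euclidean distance) to find groups of co-expressed regions, compared
between sample groups with Wilcoxon rank-sum tests, and checked for
gene-density enrichment against random placement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .core_io import ExpressionMatrix, GeneTable, SampleMetadata
from .region_calling import RERRegion

__all__ = [
    "RegionExpressionMatrix",
    "ClusterResult",
    "region_mean_expression",
    "cluster_regions",
    "subtype_association",
    "neighbor_correlation_count",
    "gene_density_test",
]


@dataclass(frozen=True)
class RegionExpressionMatrix:
    """Regions-by-samples matrix of mean gene z scores.

    ``gene_set`` records which member set was averaged (the significant-TCS
    genes, by default).
    """

    data: pd.DataFrame
    gene_set: str = "significant_genes"


@dataclass(frozen=True)
class ClusterResult:
    """Ward/Euclidean clustering of regions and samples."""

    region_labels: dict[str, int]
    region_order: tuple[str, ...]
    sample_order: tuple[str, ...]
    k: int
    linkage_method: str = "ward"
    metric: str = "euclidean"


def _zscore_rows(data: pd.DataFrame) -> pd.DataFrame:
    values = data.to_numpy(dtype=float)
    mean = np.nanmean(values, axis=1, keepdims=True)
    sd = np.nanstd(values, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = np.nan
    return pd.DataFrame(z, index=data.index, columns=data.columns)


def region_mean_expression(
    regions: Sequence[RERRegion], expr: ExpressionMatrix
) -> RegionExpressionMatrix:
    """Mean z score of each region's significant genes, per sample.

    Genes are z-scored across samples (population sd, missing ignored);
    the region value in a sample is the mean over its significant genes'
    z scores there, skipping missing cells.  A region whose significant
    genes are all absent from the matrix is rejected by name.
    """
    z = _zscore_rows(expr.data)
    rows = {}
    for region in regions:
        present = [g for g in region.significant_genes if g in z.index]
        if not present:
            raise KeyError(
                f"region {region.region_id}: no significant gene present in matrix"
            )
        rows[region.region_id] = z.loc[present].mean(axis=0, skipna=True)
    data = pd.DataFrame(rows).T
    data.index.name = "region_id"
    return RegionExpressionMatrix(data)


def cluster_regions(rem: RegionExpressionMatrix, k: int) -> ClusterResult:
    """Ward hierarchical clustering of region rows (and sample columns).

    Missing cells are imputed to 0 -- the gene-wise z-score mean -- for the
    distance computation only.  Region labels come from cutting the region
    dendrogram at ``k`` clusters; both dendrogram leaf orders are returned.
    """
    n_regions = len(rem.data)
    if k < 2 or k > n_regions:
        raise ValueError(f"k must be in [2, {n_regions}], got {k}")
    values = rem.data.to_numpy(dtype=float)
    values = np.where(np.isnan(values), 0.0, values)
    row_linkage = hierarchy.linkage(values, method="ward", metric="euclidean")
    col_linkage = hierarchy.linkage(values.T, method="ward", metric="euclidean")
    labels = hierarchy.fcluster(row_linkage, t=k, criterion="maxclust")
    region_order = tuple(rem.data.index[hierarchy.leaves_list(row_linkage)])
    sample_order = tuple(rem.data.columns[hierarchy.leaves_list(col_linkage)])
    return ClusterResult(
        region_labels={r: int(l) for r, l in zip(rem.data.index, labels)},
        region_order=region_order,
        sample_order=sample_order,
        k=k,
    )


def _rank_sum_p(a: np.ndarray, b: np.ndarray, exact_max: int = 20) -> float:
    """Two-sided Wilcoxon rank-sum p.

    Exact distribution when both groups are small and tie-free; otherwise
    the normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if max(len(a), len(b)) <= exact_max and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def subtype_association(
    rem: RegionExpressionMatrix,
    meta: SampleMetadata,
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """Per-region two-sided rank-sum test of mean z between two groups."""
    samples_a = [s for s in meta.samples_in(group_a) if s in rem.data.columns]
    samples_b = [s for s in meta.samples_in(group_b) if s in rem.data.columns]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError(
            f"both groups need >= 2 samples (got {len(samples_a)} {group_a!r}, "
            f"{len(samples_b)} {group_b!r})"
        )
    records = []
    for region_id, row in rem.data.iterrows():
        a = row[samples_a].dropna().to_numpy()
        b = row[samples_b].dropna().to_numpy()
        records.append((region_id, len(a), len(b), _rank_sum_p(a, b)))
    return pd.DataFrame(
        records, columns=["region_id", "n_a", "n_b", "p"]
    ).set_index("region_id")


def neighbor_correlation_count(
    gene: str,
    expr: ExpressionMatrix,
    genes: GeneTable,
    k: int = 20,
    alpha: float = 0.05,
    min_pairs: int = 10,
) -> int:
    """How many of a gene's k nearest neighbors correlate with it (p < alpha).

    Neighbors are the k/2 genes either side in genome order on the same
    chromosome (fewer at chromosome ends); the p value is the two-sided
    t-approximation for the Spearman correlation.
    """
    info = genes.loc(gene)
    chrom_genes = genes.genes_on(info["chrom"]).reset_index(drop=True)
    pos = int(chrom_genes.index[chrom_genes["gene_id"] == gene][0])
    half = k // 2
    neighbor_ids = [
        chrom_genes["gene_id"].iloc[j]
        for j in range(max(0, pos - half), min(len(chrom_genes), pos + half + 1))
        if j != pos
    ]
    if gene not in expr.gene_ids:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    x = expr.data.loc[gene].to_numpy(dtype=float)
    count = 0
    for nb in neighbor_ids:
        if nb not in expr.gene_ids:
            continue
        y = expr.data.loc[nb].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < min_pairs:
            continue
        xs, ys = x[ok], y[ok]
        if np.all(xs == xs[0]) or np.all(ys == ys[0]):
            continue
        if stats.spearmanr(xs, ys).pvalue < alpha:
            count += 1
    return count


def gene_density_test(
    regions: Sequence[RERRegion],
    genes: GeneTable,
    chrom_sizes: Mapping[str, int],
    n_permutations: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Are the regions more gene dense than random same-size placements?

    Observed density is genes-with-start-inside-regions per Mb of summed
    region span.  The null repositions each region uniformly within its own
    chromosome (overlap between placed regions is not prevented) and the p
    value uses the add-one permutation estimator, so it is never 0.
    """
    if not regions:
        raise ValueError("no regions supplied")
    rng = np.random.default_rng(seed)
    starts_by_chrom = {
        chrom: np.sort(genes.genes_on(chrom)["start"].to_numpy())
        for chrom in genes.chromosomes()
    }
    total_span = 0
    observed_genes = 0
    null_genes = np.zeros(n_permutations)
    for region in regions:
        if region.chrom not in chrom_sizes:
            raise ValueError(f"no chromosome size for {region.chrom!r}")
        size = chrom_sizes[region.chrom]
        length = region.span
        if length > size:
            raise ValueError(
                f"region {region.region_id} ({length} bp) exceeds {region.chrom} ({size} bp)"
            )
        starts = starts_by_chrom.get(region.chrom, np.array([], dtype=int))
        total_span += length
        observed_genes += int(
            np.searchsorted(starts, region.end, side="left")
            - np.searchsorted(starts, region.start, side="left")
        )
        placements = rng.integers(0, size - length + 1, size=n_permutations)
        null_genes += np.searchsorted(starts, placements + length, side="left") - np.searchsorted(
            starts, placements, side="left"
        )
    span_mb = total_span / 1e6
    observed_density = observed_genes / span_mb
    null_density = null_genes / span_mb
    p = (1 + int(np.sum(null_density >= observed_density))) / (n_permutations + 1)
    return observed_density, float(p)
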