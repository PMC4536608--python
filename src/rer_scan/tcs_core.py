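"""Transcription correlation scores (TCS) and their significance.

The TCS of a gene is the sum of the Spearman rank correlations between its
expression profile and the profiles of its up-to-``n`` neighbors on each
side in genomic order (a sliding window of 2n + 1 genes; n = 10 by
default).  Windows never cross chromosome boundaries, and at chromosome
ends the available <= 2n neighbors are used without rescaling --
``n_neighbors_used`` is reported so edge genes can be filtered if desired.

Correlations are computed on pairwise-complete samples with average ranks
for ties.  A correlation is undefined -- and dropped from the sum rather
than counted as zero -- when fewer than ``min_pairs`` complete pairs remain
or either profile is constant on them; treating undefined correlations as
zero would bias scores toward the null in heavily masked regions.

Significance follows the empirical-null recipe: the observed TCS
distribution is approximately normal with a tail of outliers at the high
end, so each score is converted to a z score against the mean and standard
deviation of all defined TCS values and assigned a one-sided upper-tail
normal p value.

The false discovery rate is estimated by randomizing gene order: expression
profiles keep their values but are assigned to random genome positions, the
scan is re-run, and null scores are compared against the *observed* TCS
cutoff (the score at which the real data reached significance).  The FDR is
the region-level ratio of null to observed significant regions, averaged
over permutations; the gene-level ratio is emitted alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix, GeneTable

__all__ = [
    "TCSParams",
    "FDREstimate",
    "spearman_rho",
    "compute_tcs",
    "tcs_significance",
    "tcs_threshold",
    "estimate_fdr",
]


@dataclass(frozen=True)
class TCSParams:
    """Sliding-window parameters.

    ``n``: neighbors per side (window 2n + 1); ``alpha``: one-sided
    significance level on the empirical-null z score; ``min_pairs``:
    minimum pairwise-complete samples for a correlation to be defined.
    """

    n: int = 10
    alpha: float = 0.05
    min_pairs: int = 10

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.min_pairs < 3:
            raise ValueError(f"min_pairs must be >= 3, got {self.min_pairs}")


@dataclass(frozen=True)
class FDREstimate:
    """Permutation FDR for the detection chain.

    ``null_regions``/``null_sig_genes`` are means per permutation at the
    observed TCS cutoff.  ``fdr`` is the mean over permutations of
    (null regions / observed regions); NaN when no region was observed.
    """

    observed_regions: int
    observed_sig_genes: int
    null_regions: float
    null_sig_genes: float
    fdr: float
    gene_fdr: float
    tcs_cutoff: float
    n_permutations: int
    seed: int


def spearman_rho(
    x: np.ndarray, y: np.ndarray, min_pairs: int = 10
) -> float:
    """Spearman correlation on pairwise-complete entries, or NaN.

    Uses average ranks for ties.  Returns NaN when fewer than ``min_pairs``
    complete pairs remain or either vector is constant on them.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < min_pairs:
        return float("nan")
    xs, ys = x[ok], y[ok]
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        return float("nan")
    rx = stats.rankdata(xs)
    ry = stats.rankdata(ys)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def _aligned_values(expr: ExpressionMatrix, genes: GeneTable) -> pd.DataFrame:
    missing = set(expr.gene_ids) - set(genes.gene_ids)
    if missing:
        raise KeyError(
            f"gene {sorted(missing)[0]!r} in expression matrix but not in gene table"
        )
    keep = genes.data[genes.data["gene_id"].isin(set(expr.gene_ids))]
    return keep  # genome order


def compute_tcs(
    expr: ExpressionMatrix, genes: GeneTable, params: TCSParams = TCSParams()
) -> pd.DataFrame:
    """Compute the TCS for every gene of the expression matrix.

    Returns a frame indexed by gene_id with columns chrom, start, end,
    order_index, tcs and n_neighbors_used, in genome order.  ``tcs`` is NaN
    when no neighbor correlation is defined.

    Rows without missing values take a vectorized path (Pearson on
    standardized average ranks, which is exactly Spearman); rows with
    missing values fall back to per-pair pairwise-complete correlation.
    """
    _aligned_values(expr, genes)  # validates every expr gene is annotated
    gmap = genes.data  # neighbor distance is order_index distance on the full map
    n_samples = expr.shape[1]

    out_tcs = np.zeros(len(gmap))
    out_cnt = np.zeros(len(gmap), dtype=int)

    row_offset = 0
    for chrom in dict.fromkeys(gmap["chrom"]):
        sub = gmap[gmap["chrom"] == chrom]
        # genes annotated but not measured become all-NaN rows: they occupy
        # their genomic position yet contribute no defined correlation
        X = expr.data.reindex(sub["gene_id"]).to_numpy(dtype=float)
        g = X.shape[0]
        complete = ~np.isnan(X).any(axis=1)
        ranks = np.empty_like(X)
        ranks[complete] = stats.rankdata(X[complete], axis=1)
        sd = np.zeros(g)
        mu = np.zeros(g)
        if complete.any():
            mu[complete] = ranks[complete].mean(axis=1)
            sd[complete] = ranks[complete].std(axis=1)
        fast = complete & (sd > 0) & (n_samples >= params.min_pairs)
        Z = np.zeros_like(X)
        if fast.any():
            Z[fast] = (ranks[fast] - mu[fast, None]) / sd[fast, None]

        tcs = out_tcs[row_offset : row_offset + g]
        cnt = out_cnt[row_offset : row_offset + g]
        for d in range(1, min(params.n, g - 1) + 1):
            both_fast = fast[:-d] & fast[d:]
            rho = np.full(g - d, np.nan)
            if both_fast.any():
                rho[both_fast] = (Z[:-d][both_fast] * Z[d:][both_fast]).mean(axis=1)
            slow = np.where(~both_fast)[0]
            for i in slow:
                rho[i] = spearman_rho(X[i], X[i + d], params.min_pairs)
            defined = ~np.isnan(rho)
            np.add.at(tcs, np.where(defined)[0], rho[defined])
            np.add.at(tcs, np.where(defined)[0] + d, rho[defined])
            cnt[:-d] += defined
            cnt[d:] += defined
        row_offset += g

    out_tcs[out_cnt == 0] = np.nan
    result = gmap.loc[:, ["gene_id", "chrom", "start", "end", "order_index"]].copy()
    result["tcs"] = out_tcs
    result["n_neighbors_used"] = out_cnt
    result = result[result["gene_id"].isin(set(expr.gene_ids))]
    return result.set_index("gene_id")


def tcs_significance(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Attach empirical-null z, one-sided p and a significance flag.

    z scores are computed against the mean and (sample) standard deviation
    of all defined TCS values; p is the upper-tail normal probability.
    Genes with undefined TCS are never significant.
    """
    defined = table["tcs"].notna()
    if defined.sum() < 2:
        raise ValueError("need at least 2 genes with a defined TCS")
    values = table.loc[defined, "tcs"].to_numpy()
    mean = values.mean()
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("TCS standard deviation is zero; z scores undefined")
    out = table.copy()
    out["z"] = (out["tcs"] - mean) / sd
    out["p"] = stats.norm.sf(out["z"])
    out["significant"] = defined & (out["p"] < alpha)
    return out


def tcs_threshold(table: pd.DataFrame, alpha: float = 0.05) -> float:
    """The TCS value at which the one-sided empirical-null p reaches alpha."""
    values = table.loc[table["tcs"].notna(), "tcs"].to_numpy()
    if len(values) < 2:
        raise ValueError("need at least 2 genes with a defined TCS")
    return float(values.mean() + stats.norm.isf(alpha) * values.std(ddof=1))


def estimate_fdr(
    expr: ExpressionMatrix,
    genes: GeneTable,
    params: TCSParams = TCSParams(),
    n_permutations: int = 10,
    seed: int = 0,
) -> FDREstimate:
    """Estimate the FDR of the detection chain by gene-order randomization.

    The observed data fix the TCS significance cutoff; each permutation
    shuffles the gene-to-position assignment (profiles keep their values),
    recomputes scores, applies the observed cutoff and re-delineates
    regions.  See the module docstring for the rationale of the fixed
    cutoff.
    """
    from .region_calling import delineate_regions  # local: avoids import cycle

    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)

    observed = tcs_significance(compute_tcs(expr, genes, params), params.alpha)
    cutoff = tcs_threshold(observed, params.alpha)
    obs_regions = delineate_regions(observed, genes, params.n)
    obs_sig = int(observed["significant"].sum())

    null_region_counts = []
    null_gene_counts = []
    for _ in range(n_permutations):
        perm = rng.permutation(expr.shape[0])
        shuffled = ExpressionMatrix(
            pd.DataFrame(
                expr.data.to_numpy()[perm],
                index=expr.data.index,
                columns=expr.data.columns,
            )
        )
        null = compute_tcs(shuffled, genes, params)
        null["significant"] = null["tcs"].notna() & (null["tcs"] >= cutoff)
        null_regions = delineate_regions(null, genes, params.n)
        null_region_counts.append(len(null_regions))
        null_gene_counts.append(int(null["significant"].sum()))

    mean_null_regions = float(np.mean(null_region_counts))
    mean_null_genes = float(np.mean(null_gene_counts))
    fdr = mean_null_regions / len(obs_regions) if obs_regions else float("nan")
    gene_fdr = mean_null_genes / obs_sig if obs_sig else float("nan")
    return FDREstimate(
        observed_regions=len(obs_regions),
        observed_sig_genes=obs_sig,
        null_regions=mean_null_regions,
        null_sig_genes=mean_null_genes,
        fdr=fdr,
        gene_fdr=gene_fdr,
        tcs_cutoff=cutoff,
        n_permutations=n_permutations,
        seed=seed,
    )
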