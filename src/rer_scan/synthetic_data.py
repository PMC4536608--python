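"""Synthetic cohorts with the statistical structure the RER analysis assumes.

The generator emulates the three ingredients the detection method has to
disentangle:

* coordinately regulated domains -- blocks of consecutive genes sharing a
  per-sample latent factor (loading ``sqrt(c)``) plus a mean shift in the
  affected sample groups, the signature of regional epigenetic regulation;
* segmental copy-number aberrations -- additive log-scale dosage shifts for
  the spanned genes in an affected subset of samples, the confounder that
  copy-number masking must remove;
* independent per-gene Gaussian noise.

For a domain gene the expression value is

    baseline(g) + shift * 1[group(s) affected] + sqrt(c) * F(d, s)
               + cna_shift(g, s) + Normal(0, noise_sd)

with ``F(d, s)`` a standard-normal factor drawn once per domain and sample.
Two genes of the same domain (same group structure aside) then correlate at
``c / (c + noise_sd**2)``; choosing ``noise_sd = sqrt(1 - c)`` makes the
realized within-domain correlation equal the configured ``c``.

Every generator is a pure function of (config, seed): the same seed yields
bit-identical output.  Ground truth for all embedded signal is returned
alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    COPY_NUMBER_CALLS,
    CopyNumberCallSet,
    ExpressionMatrix,
    GeneTable,
    IntervalSet,
    SampleMetadata,
)

__all__ = [
    "DomainSpec",
    "CNASegmentSpec",
    "CohortConfig",
    "GroundTruth",
    "simulate_cohort",
    "simulate_fish_measurements",
    "simulate_tads",
]


@dataclass(frozen=True)
class DomainSpec:
    """A coordinately regulated domain on the synthetic gene map.

    Gene indices are half-open ``[gene_start, gene_end)`` into the order of
    genes on ``chrom``.  ``affected_groups`` empty means the mean shift
    applies to no group (pure correlation); the latent-factor component is
    shared by all samples regardless.
    """

    chrom: str
    gene_start: int
    gene_end: int
    affected_groups: tuple[str, ...] = ()
    shift: float = 0.0
    correlation: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.correlation <= 1.0:
            raise ValueError(f"correlation must be in [0, 1], got {self.correlation}")
        if self.gene_end <= self.gene_start:
            raise ValueError("gene_end must exceed gene_start")


@dataclass(frozen=True)
class CNASegmentSpec:
    """A segmental copy-number aberration affecting a fraction of samples."""

    chrom: str
    gene_start: int
    gene_end: int
    sample_fraction: float = 0.3
    call: str = "loss"
    shift: float = -1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.sample_fraction <= 1.0:
            raise ValueError(
                f"sample_fraction must be in (0, 1], got {self.sample_fraction}"
            )
        if self.call not in COPY_NUMBER_CALLS or self.call == "neutral":
            raise ValueError(f"call must be a non-neutral copy-number call, got {self.call!r}")
        if self.gene_end <= self.gene_start:
            raise ValueError("gene_end must exceed gene_start")


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition knobs for :func:`simulate_cohort`.

    Defaults mirror a mid-sized expression cohort: a few hundred ordered
    genes, ~200 samples split into two receptor-status groups, unit log-scale
    noise, and no embedded signal (a null cohort) until domains or CNA
    segments are listed.
    """

    n_chromosomes: int = 1
    genes_per_chromosome: int = 500
    gene_spacing: int = 100_000
    n_samples: int = 200
    group_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"ER+": 0.5, "ER-": 0.5}
    )
    rer_domains: tuple[DomainSpec, ...] = ()
    cna_segments: tuple[CNASegmentSpec, ...] = ()
    noise_sd: float = 1.0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")
        if self.genes_per_chromosome < 1:
            raise ValueError("genes_per_chromosome must be >= 1")
        if self.gene_spacing < 2:
            raise ValueError("gene_spacing must be >= 2")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        total = float(sum(self.group_proportions.values()))
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"group_proportions must sum to 1, got {total}")
        chroms = {f"chr{i + 1}" for i in range(self.n_chromosomes)}
        for dom in self.rer_domains:
            if dom.chrom not in chroms:
                raise ValueError(f"rer_domains: unknown chromosome {dom.chrom!r}")
            if dom.gene_end > self.genes_per_chromosome:
                raise ValueError(f"rer_domains: domain {dom} exceeds gene map")
            unknown = set(dom.affected_groups) - set(self.group_proportions)
            if unknown:
                raise ValueError(f"rer_domains: unknown group(s) {sorted(unknown)}")
        for seg in self.cna_segments:
            if seg.chrom not in chroms:
                raise ValueError(f"cna_segments: unknown chromosome {seg.chrom!r}")
            if seg.gene_end > self.genes_per_chromosome:
                raise ValueError(f"cna_segments: segment {seg} exceeds gene map")


@dataclass(frozen=True)
class GroundTruth:
    """Embedded signal of a simulated cohort.

    ``domain_intervals`` gives each true domain as a genomic interval (first
    gene start to last gene end) named after its affected groups;
    ``cna_cells`` is the exact set of (gene_id, sample_id) cells carrying a
    copy-number shift.
    """

    domains: tuple[DomainSpec, ...]
    domain_intervals: IntervalSet
    domain_gene_ids: tuple[tuple[str, ...], ...]
    cna_cells: frozenset[tuple[str, str]]


def _make_gene_table(config: CohortConfig) -> GeneTable:
    rows = []
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        for i in range(config.genes_per_chromosome):
            start = i * config.gene_spacing
            rows.append(
                (
                    f"G{c + 1:02d}{i + 1:05d}",
                    chrom,
                    start,
                    start + config.gene_spacing // 2,
                )
            )
    return GeneTable.from_frame(
        pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
    )


def _assign_groups(config: CohortConfig, rng: np.random.Generator) -> list[str]:
    labels = list(config.group_proportions)
    counts = {g: int(np.floor(config.group_proportions[g] * config.n_samples)) for g in labels}
    # distribute the remainder by declaration order
    i = 0
    while sum(counts.values()) < config.n_samples:
        counts[labels[i % len(labels)]] += 1
        i += 1
    assignment = [g for g in labels for _ in range(counts[g])]
    rng.shuffle(assignment)
    return assignment


def simulate_cohort(
    config: CohortConfig,
) -> tuple[GeneTable, ExpressionMatrix, CopyNumberCallSet, SampleMetadata, GroundTruth]:
    """Simulate an expression cohort with known regional signal.

    Returns the gene map, expression matrix, the (sparse) copy-number call
    set marking exactly the true CNA cells, the sample group labels and the
    ground truth of every embedded domain and CNA cell.
    """
    rng = np.random.default_rng(config.seed)
    genes = _make_gene_table(config)
    n_genes = len(genes)
    sample_ids = [f"S{i + 1:04d}" for i in range(config.n_samples)]
    group_of = _assign_groups(config, rng)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_genes)
    values = baseline[:, None] + rng.normal(
        0.0, config.noise_sd, size=(n_genes, config.n_samples)
    )

    # genome-order row lookup: rows of `values` follow genes.data order
    row_of: dict[tuple[str, int], int] = {
        (row.chrom, row.order_index): i
        for i, row in enumerate(genes.data.itertuples(index=False))
    }
    gene_id_at = genes.data["gene_id"].to_numpy()

    group_arr = np.asarray(group_of)
    domain_gene_ids: list[tuple[str, ...]] = []
    domain_records: list[tuple] = []
    for d, dom in enumerate(config.rer_domains):
        rows = [row_of[(dom.chrom, i)] for i in range(dom.gene_start, dom.gene_end)]
        factor = rng.standard_normal(config.n_samples)
        values[rows, :] += np.sqrt(dom.correlation) * factor[None, :]
        if dom.affected_groups and dom.shift != 0.0:
            affected = np.isin(group_arr, dom.affected_groups)
            values[np.ix_(rows, np.where(affected)[0])] += dom.shift
        ids = tuple(gene_id_at[rows])
        domain_gene_ids.append(ids)
        sub = genes.data.iloc[rows]
        domain_records.append(
            (
                dom.chrom,
                int(sub["start"].min()),
                int(sub["end"].max()),
                ",".join(dom.affected_groups) or "all",
            )
        )

    cna_cells: set[tuple[str, str]] = set()
    call_rows = []
    for seg in config.cna_segments:
        rows = [row_of[(seg.chrom, i)] for i in range(seg.gene_start, seg.gene_end)]
        n_affected = max(1, int(round(seg.sample_fraction * config.n_samples)))
        affected = rng.choice(config.n_samples, size=n_affected, replace=False)
        values[np.ix_(rows, affected)] += seg.shift
        for r in rows:
            for s in affected:
                cna_cells.add((gene_id_at[r], sample_ids[s]))
                call_rows.append((gene_id_at[r], sample_ids[s], seg.call))

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(gene_id_at, name="gene_id"), columns=sample_ids)
    )
    calls = (
        CopyNumberCallSet(pd.DataFrame(call_rows, columns=["gene_id", "sample_id", "call"]))
        if call_rows
        else CopyNumberCallSet.empty()
    )
    meta = SampleMetadata(pd.DataFrame({"sample_id": sample_ids, "group_label": group_of}))
    truth = GroundTruth(
        domains=tuple(config.rer_domains),
        domain_intervals=(
            IntervalSet.from_records(domain_records)
            if domain_records
            else IntervalSet.empty()
        ),
        domain_gene_ids=tuple(domain_gene_ids),
        cna_cells=frozenset(cna_cells),
    )
    return genes, expr, calls, meta, truth


# ---------------------------------------------------------------------------
# FISH measurements
# ---------------------------------------------------------------------------

#: parameters of the stated measurement distributions (recorded in output)
FISH_DISTRIBUTIONS = {
    "nuclear_area": "lognormal(mean=log(150) um^2, sigma=0.2)",
    "d2_over_r2": "gamma(shape=2, scale=compaction/2); mean == compaction",
    "radial_position[peripheral]": "beta(4, 1.5) on [0=center, 1=periphery]",
    "radial_position[central]": "beta(1.5, 4) on [0=center, 1=periphery]",
}


def simulate_fish_measurements(
    n_nuclei: int,
    compaction: float,
    radial_mode: str = "central",
    seed: int = 0,
    condition: str | None = None,
) -> pd.DataFrame:
    """Simulate a per-nucleus FISH measurement table.

    ``compaction`` sets the mean of the normalized squared interprobe
    distance d^2/r^2 (a de-compact locus has a larger mean).  d^2/r^2 is
    drawn from a gamma distribution -- chosen for positivity and right skew,
    not from any claim about real measurements -- nuclear area from a
    lognormal, and the radial signal position from a beta distribution
    skewed toward the periphery (``peripheral``) or the center
    (``central``).  Distribution parameters are recorded in ``df.attrs``.
    """
    if n_nuclei < 1:
        raise ValueError("n_nuclei must be >= 1")
    if compaction <= 0:
        raise ValueError(f"compaction must be > 0, got {compaction}")
    if radial_mode not in ("peripheral", "central"):
        raise ValueError(f"radial_mode must be 'peripheral' or 'central', got {radial_mode!r}")
    rng = np.random.default_rng(seed)
    area = rng.lognormal(mean=np.log(150.0), sigma=0.2, size=n_nuclei)
    d2_over_r2 = rng.gamma(shape=2.0, scale=compaction / 2.0, size=n_nuclei)
    a, b = (4.0, 1.5) if radial_mode == "peripheral" else (1.5, 4.0)
    radial = rng.beta(a, b, size=n_nuclei)
    r2 = area / np.pi
    d = np.sqrt(d2_over_r2 * r2)
    df = pd.DataFrame(
        {
            "nucleus_id": [f"N{i + 1:05d}" for i in range(n_nuclei)],
            "condition": condition or f"{radial_mode}:compaction={compaction:g}",
            "interprobe_distance_um": d,
            "nuclear_area_um2": area,
            "radial_position": radial,
        }
    )
    df.attrs["distributions"] = dict(FISH_DISTRIBUTIONS)
    df.attrs["compaction"] = float(compaction)
    df.attrs["radial_mode"] = radial_mode
    df.attrs["seed"] = int(seed)
    return df


# ---------------------------------------------------------------------------
# TAD tiling
# ---------------------------------------------------------------------------


def simulate_tads(
    gene_table: GeneTable,
    mean_tad_size: int = 1_000_000,
    seed: int = 0,
    gap_probability: float = 0.1,
    gap_fraction: float = 0.05,
) -> tuple[IntervalSet, IntervalSet]:
    """Tile each chromosome with non-overlapping TAD-like intervals.

    Sizes are lognormal around ``mean_tad_size`` (sigma 0.25 in log space);
    between consecutive domains a gap of ``gap_fraction * mean_tad_size``
    is inserted with probability ``gap_probability``, emulating assembly
    gaps.  Returns ``(tads, gaps)``, both sorted and half-open.
    """
    if mean_tad_size <= 0:
        raise ValueError("mean_tad_size must be positive")
    rng = np.random.default_rng(seed)
    sigma = 0.25
    mu = np.log(mean_tad_size) - sigma**2 / 2.0
    tad_records: list[tuple] = []
    gap_records: list[tuple] = []
    for chrom in gene_table.chromosomes():
        extent = int(gene_table.genes_on(chrom)["end"].max())
        pos = 0
        k = 0
        while pos < extent:
            size = int(rng.lognormal(mu, sigma))
            size = max(size, mean_tad_size // 10)
            end = min(pos + size, extent)
            k += 1
            tad_records.append((chrom, pos, end, f"{chrom}_tad{k}"))
            pos = end
            if pos < extent and rng.random() < gap_probability:
                gap_end = min(pos + int(gap_fraction * mean_tad_size), extent)
                if gap_end > pos:
                    gap_records.append((chrom, pos, gap_end, f"{chrom}_gap{k}"))
                    pos = gap_end
    tads = IntervalSet.from_records(tad_records)
    gaps = IntervalSet.from_records(gap_records) if gap_records else IntervalSet.empty()
    return tads, gaps
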