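"""Permutation statistics on genomic intervals: TAD containment and
binding-site window enrichment.

Both tests compare an observed configuration against random repositioning
of intervals, excluding assembly gaps.  The TAD test repositions each
region within its own chromosome (preserving chromosome composition); the
window-enrichment test places windows genome-wide with the chromosome
chosen proportional to its placeable length, matching the question "where
does this window rank among all same-size windows of the genome".  Both
report tie-inclusive, add-one estimates, so no p value or percentile is
ever exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .core_io import IntervalSet

__all__ = [
    "TADOverlapResult",
    "EnrichmentResult",
    "containment_fraction",
    "tad_overlap_test",
    "window_site_enrichment",
]

_MAX_PLACEMENT_ROUNDS = 200


@dataclass(frozen=True)
class TADOverlapResult:
    """Outcome of the TAD-containment permutation test."""

    n_regions: int
    n_contained: int
    containment_threshold: float
    n_permutations: int
    p: float
    seed: int
    null_mean_contained: float


@dataclass(frozen=True)
class EnrichmentResult:
    """Rank of a window's site count among random equal-size windows."""

    observed_count: int
    window_size: int
    n_windows: int
    percentile_rank: float
    seed: int
    null_mean_count: float


def _as_tuple(interval) -> tuple[str, int, int]:
    if isinstance(interval, tuple):
        chrom, start, end = interval[:3]
        return str(chrom), int(start), int(end)
    return str(interval.chrom), int(interval.start), int(interval.end)


def containment_fraction(region, tad) -> float:
    """Fraction of the region's span covered by one TAD (0 on other chroms)."""
    rc, rs, re = _as_tuple(region)
    tc, ts, te = _as_tuple(tad)
    if rc != tc:
        return 0.0
    overlap = min(re, te) - max(rs, ts)
    return max(overlap, 0) / (re - rs)


class _GapIndex:
    """Per-chromosome overlap queries against a fixed interval set."""

    def __init__(self, intervals: IntervalSet):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in intervals.data["chrom"].unique():
            sub = intervals.on(chrom).sort_values("start")
            starts = sub["start"].to_numpy()
            ends = np.maximum.accumulate(sub["end"].to_numpy())  # prefix max
            self._by_chrom[chrom] = (starts, ends)

    def overlaps(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Vectorized: does [start, end) intersect any interval on chrom."""
        if chrom not in self._by_chrom:
            return np.zeros(len(starts), dtype=bool)
        gs, ge_cummax = self._by_chrom[chrom]
        j = np.searchsorted(gs, ends, side="left")  # gaps starting before end
        hit = j > 0
        hit[hit] = ge_cummax[j[hit] - 1] > starts[hit]
        return hit


def _containment_batch(
    starts: np.ndarray, length: int, tad_starts: np.ndarray, tad_ends: np.ndarray
) -> np.ndarray:
    """Max single-TAD containment fraction for each candidate start."""
    if len(tad_starts) == 0:
        return np.zeros(len(starts))
    ends = starts + length
    overlap = np.minimum(ends[:, None], tad_ends[None, :]) - np.maximum(
        starts[:, None], tad_starts[None, :]
    )
    return np.clip(overlap.max(axis=1), 0, None) / length


def _place_in_chrom(
    rng: np.random.Generator,
    size: int,
    length: int,
    gaps: _GapIndex,
    chrom: str,
    n: int,
    what: str,
) -> np.ndarray:
    """n uniform gap-avoiding placements of a length-`length` interval."""
    if length > size:
        raise ValueError(f"{what} ({length} bp) does not fit on {chrom} ({size} bp)")
    out = np.empty(n, dtype=np.int64)
    todo = np.arange(n)
    for _ in range(_MAX_PLACEMENT_ROUNDS):
        starts = rng.integers(0, size - length + 1, size=len(todo))
        bad = gaps.overlaps(chrom, starts, starts + length)
        out[todo[~bad]] = starts[~bad]
        todo = todo[bad]
        if len(todo) == 0:
            return out
    raise RuntimeError(
        f"could not place {what} outside gaps on {chrom} "
        f"after {_MAX_PLACEMENT_ROUNDS} rounds"
    )


def tad_overlap_test(
    regions: IntervalSet,
    tads: IntervalSet,
    gaps: IntervalSet,
    chrom_sizes: Mapping[str, int],
    threshold: float = 0.8,
    n_permutations: int = 1000,
    seed: int = 0,
) -> TADOverlapResult:
    """Permutation test of region containment within single TADs.

    A region counts as contained when at least ``threshold`` of its span
    lies within one TAD.  Each permutation repositions every region
    uniformly within its own chromosome, rejecting placements that
    intersect assembly gaps; the p value is the add-one fraction of
    permutations whose contained count reaches the observed one.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    rng = np.random.default_rng(seed)
    gap_index = _GapIndex(gaps)
    tads_by_chrom = {
        chrom: (
            tads.on(chrom).sort_values("start")["start"].to_numpy(),
            tads.on(chrom).sort_values("start")["end"].to_numpy(),
        )
        for chrom in tads.data["chrom"].unique()
    }
    empty = (np.array([], dtype=int), np.array([], dtype=int))

    observed = 0
    null_counts = np.zeros(n_permutations, dtype=int)
    for row in regions.data.itertuples(index=False):
        chrom, start, end = row.chrom, int(row.start), int(row.end)
        if chrom not in chrom_sizes:
            raise ValueError(f"no chromosome size for {chrom!r}")
        length = end - start
        ts, te = tads_by_chrom.get(chrom, empty)
        if _containment_batch(np.array([start]), length, ts, te)[0] >= threshold:
            observed += 1
        name = getattr(row, "name", "") or f"{chrom}:{start}-{end}"
        placements = _place_in_chrom(
            rng, chrom_sizes[chrom], length, gap_index, chrom, n_permutations,
            f"region {name}",
        )
        null_counts += _containment_batch(placements, length, ts, te) >= threshold

    p = (1 + int(np.sum(null_counts >= observed))) / (n_permutations + 1)
    return TADOverlapResult(
        n_regions=len(regions),
        n_contained=observed,
        containment_threshold=threshold,
        n_permutations=n_permutations,
        p=float(p),
        seed=seed,
        null_mean_contained=float(null_counts.mean()) if n_permutations else 0.0,
    )


def window_site_enrichment(
    window: tuple[str, int, int],
    sites: IntervalSet,
    gaps: IntervalSet,
    chrom_sizes: Mapping[str, int],
    n_windows: int = 10_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Rank a window's site count among random equal-size genomic windows.

    A site belongs to a window when its midpoint falls inside (half-open),
    so a site straddling a window edge is never double-counted.  Random
    windows of the same length are placed across all chromosomes that can
    hold them (chromosome probability proportional to placeable length),
    rejecting gap-intersecting placements.  ``percentile_rank`` is the
    add-one, tie-inclusive percentage of random windows with a count at
    least the observed one: small means enriched.
    """
    chrom, start, end = _as_tuple(window)
    length = end - start
    if length <= 0:
        raise ValueError("window must have positive length")
    rng = np.random.default_rng(seed)
    gap_index = _GapIndex(gaps)

    midpoints = {
        c: np.sort(
            ((sites.on(c)["start"] + sites.on(c)["end"]) // 2).to_numpy()
        )
        for c in sites.data["chrom"].unique()
    }

    def count_in(c: str, starts: np.ndarray) -> np.ndarray:
        mids = midpoints.get(c)
        if mids is None or len(mids) == 0:
            return np.zeros(len(starts), dtype=int)
        return np.searchsorted(mids, starts + length, side="left") - np.searchsorted(
            mids, starts, side="left"
        )

    observed = int(count_in(chrom, np.array([start]))[0])

    placeable = {
        c: size - length + 1 for c, size in chrom_sizes.items() if size >= length
    }
    if not placeable:
        raise ValueError(f"no chromosome can hold a {length}-bp window")
    chroms = list(placeable)
    probs = np.array([placeable[c] for c in chroms], dtype=float)
    probs /= probs.sum()
    chosen = rng.choice(len(chroms), size=n_windows, p=probs)

    null_counts = np.empty(n_windows, dtype=int)
    for ci, c in enumerate(chroms):
        idx = np.where(chosen == ci)[0]
        if len(idx) == 0:
            continue
        starts = _place_in_chrom(
            rng, chrom_sizes[c], length, gap_index, c, len(idx), "window"
        )
        null_counts[idx] = count_in(c, starts)

    n_ge = int(np.sum(null_counts >= observed))
    percentile = 100.0 * (1 + n_ge) / (n_windows + 1)
    return EnrichmentResult(
        observed_count=observed,
        window_size=length,
        n_windows=n_windows,
        percentile_rank=float(percentile),
        seed=seed,
        null_mean_count=float(null_counts.mean()),
    )
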