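"""Domain containers and flat-file I/O shared across the RER pipeline.

The pipeline works on five kinds of data: an ordered genomic gene map
(:class:`GeneTable`), a genes-by-samples expression matrix with missing
values (:class:`ExpressionMatrix`), per-cell copy-number calls
(:class:`CopyNumberCallSet`), generic genomic interval sets
(:class:`IntervalSet`, used for TADs, binding sites, assembly gaps and the
pipeline's own output regions) and per-sample group labels
(:class:`SampleMetadata`).

All genomic coordinates are 0-based half-open (BED convention) throughout;
any 1-based source must be converted at the boundary.  Missing expression is
represented as NaN and is a first-class state: copy-number masking produces
missing cells, and every downstream correlation works on pairwise-complete
entries.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

COPY_NUMBER_CALLS = ("loss", "neutral", "gain", "amplification")

__all__ = [
    "GeneTable",
    "ExpressionMatrix",
    "CopyNumberCallSet",
    "IntervalSet",
    "SampleMetadata",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_table",
    "write_gene_table",
    "read_intervals_bed",
    "write_intervals_bed",
    "write_regions_bed",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_copy_number_calls",
    "write_copy_number_calls",
    "read_chrom_sizes",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneTable:
    """Ordered genomic gene map.

    Wraps a frame with columns ``gene_id, chrom, start, end, order_index``
    where ``order_index`` is the dense 0-based rank of the gene along its
    chromosome by start coordinate.  Gene order -- not physical distance --
    defines "neighbors" for all sliding-window logic.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "start", "end", "order_index"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"GeneTable frame missing columns: {sorted(missing)}")
        if self.data["gene_id"].duplicated().any():
            dup = self.data["gene_id"][self.data["gene_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate gene_id: {dup!r}")
        if (self.data["end"] <= self.data["start"]).any():
            bad = self.data[self.data["end"] <= self.data["start"]].iloc[0]
            raise ValueError(f"gene {bad['gene_id']!r} has end <= start")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GeneTable":
        """Build from a frame with gene_id/chrom/start/end, assigning order."""
        df = frame.loc[:, ["gene_id", "chrom", "start", "end"]].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df = df.sort_values(["chrom", "start", "gene_id"], kind="mergesort")
        df["order_index"] = df.groupby("chrom", sort=False).cumcount()
        df = df.reset_index(drop=True)
        return cls(df)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.data["gene_id"])

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.data["chrom"]))

    def genes_on(self, chrom: str) -> pd.DataFrame:
        """Genes of one chromosome sorted by order_index."""
        sub = self.data[self.data["chrom"] == chrom]
        return sub.sort_values("order_index")

    def loc(self, gene_id: str) -> pd.Series:
        hit = self.data[self.data["gene_id"] == gene_id]
        if hit.empty:
            raise KeyError(f"gene {gene_id!r} not in GeneTable")
        return hit.iloc[0]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes-by-samples matrix of log-scale expression (or z scores).

    ``data`` is indexed by gene id with sample ids as columns; missing
    measurements are NaN.  Row order is meaningful and preserved by I/O.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[1] < 2:
            raise ValueError("ExpressionMatrix needs at least 2 samples")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def n_missing(self) -> int:
        return int(self.data.isna().sum().sum())


@dataclass(frozen=True)
class CopyNumberCallSet:
    """Sparse per-(gene, sample) copy-number calls.

    Only non-neutral calls are stored; any (gene, sample) pair absent from
    ``data`` is implicitly neutral.
    """

    data: pd.DataFrame  # columns: gene_id, sample_id, call

    def __post_init__(self) -> None:
        required = {"gene_id", "sample_id", "call"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"CopyNumberCallSet missing columns: {sorted(missing)}")
        bad = set(self.data["call"]) - set(COPY_NUMBER_CALLS)
        if bad:
            raise ValueError(f"unknown copy-number call(s): {sorted(bad)}")

    @classmethod
    def empty(cls) -> "CopyNumberCallSet":
        return cls(pd.DataFrame(columns=["gene_id", "sample_id", "call"]))

    def non_neutral(self) -> pd.DataFrame:
        return self.data[self.data["call"] != "neutral"]

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class IntervalSet:
    """A set of genomic intervals (0-based half-open), sortable by position."""

    data: pd.DataFrame  # columns: chrom, start, end, name

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"IntervalSet missing columns: {sorted(missing)}")
        if len(self.data) and (self.data["end"] <= self.data["start"]).any():
            bad = self.data[self.data["end"] <= self.data["start"]].iloc[0]
            raise ValueError(
                f"interval {bad['chrom']}:{bad['start']}-{bad['end']} has end <= start"
            )

    @classmethod
    def from_records(
        cls, records: Iterable[tuple], names: Sequence[str] | None = None
    ) -> "IntervalSet":
        rows = []
        for i, rec in enumerate(records):
            chrom, start, end = rec[0], int(rec[1]), int(rec[2])
            name = rec[3] if len(rec) > 3 else (names[i] if names else "")
            rows.append((chrom, start, end, name))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
            drop=True
        )
        return cls(df)

    @classmethod
    def empty(cls) -> "IntervalSet":
        return cls(
            pd.DataFrame(
                {
                    "chrom": pd.Series(dtype=str),
                    "start": pd.Series(dtype=np.int64),
                    "end": pd.Series(dtype=np.int64),
                    "name": pd.Series(dtype=str),
                }
            )
        )

    def __len__(self) -> int:
        return len(self.data)

    def on(self, chrom: str) -> pd.DataFrame:
        return self.data[self.data["chrom"] == chrom]

    def lengths(self) -> np.ndarray:
        return (self.data["end"] - self.data["start"]).to_numpy()


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample group labels (tumor subtype, ER status, condition ...)."""

    data: pd.DataFrame  # columns: sample_id, group_label

    def __post_init__(self) -> None:
        required = {"sample_id", "group_label"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"SampleMetadata missing columns: {sorted(missing)}")
        if self.data["sample_id"].duplicated().any():
            dup = self.data["sample_id"][self.data["sample_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate sample_id: {dup!r}")

    def samples_in(self, group: str) -> list[str]:
        return list(self.data.loc[self.data["group_label"] == group, "sample_id"])

    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.data["group_label"]))

    def validate_against(self, expr: ExpressionMatrix) -> None:
        unknown = set(self.data["sample_id"]) - set(expr.sample_ids)
        if unknown:
            raise ValueError(
                f"samples in metadata but not in expression matrix: {sorted(unknown)[:5]}"
            )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_NA_STRINGS = {"", "NA", "NaN", "nan"}


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a tab-separated expression matrix (genes in rows).

    First column holds gene ids, the header row sample ids.  Empty cells or
    ``NA`` denote missing values.  Duplicate gene ids and non-numeric cells
    are rejected with the offending location named.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r} in {path}")
    values = raw.replace(list(_NA_STRINGS), np.nan)
    numeric = values.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & values.notna()
    if bad.to_numpy().any():
        gi, sj = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell {values.iat[gi, sj]!r} at gene {raw.index[gi]!r}, "
            f"sample {raw.columns[sj]!r} in {path}"
        )
    numeric.index.name = "gene_id"
    return ExpressionMatrix(numeric.astype(float))


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    df = expr.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_gene_table(path: str | Path) -> GeneTable:
    """Read a gene map TSV with columns gene_id, chrom, start, end."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    return GeneTable.from_frame(df)


def write_gene_table(genes: GeneTable, path: str | Path) -> None:
    genes.data.loc[:, ["gene_id", "chrom", "start", "end"]].to_csv(
        path, sep="\t", index=False
    )


def read_intervals_bed(path: str | Path) -> IntervalSet:
    """Read BED3/BED4 (whitespace-separated, 0-based half-open).

    Columns beyond the name are ignored; ``track``/``browser``/comment lines
    are skipped.  A line with end <= start is rejected citing the line number.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected at least 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end ({end}) <= start ({start})")
            name = fields[3] if len(fields) > 3 else ""
            records.append((chrom, start, end, name))
    if not records:
        return IntervalSet.empty()
    return IntervalSet.from_records(records)


def write_intervals_bed(intervals: IntervalSet, path: str | Path) -> None:
    """Write BED4, sorted by (chrom, start)."""
    df = intervals.data.sort_values(["chrom", "start", "end"], kind="mergesort")
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            name = row.name if row.name else "."
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{name}\n")


def write_regions_bed(regions: Sequence, path: str | Path) -> None:
    """Write RER regions as BED4 (name = region id).

    Round-trips through :func:`read_intervals_bed` with identical coordinates.
    """
    records = [(r.chrom, r.start, r.end, r.region_id) for r in regions]
    write_intervals_bed(
        IntervalSet.from_records(records) if records else IntervalSet.empty(), path
    )


def read_sample_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleMetadata(df.loc[:, ["sample_id", "group_label"]])


def write_sample_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.data.to_csv(path, sep="\t", index=False)


def read_copy_number_calls(path: str | Path) -> CopyNumberCallSet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return CopyNumberCallSet(df.loc[:, ["gene_id", "sample_id", "call"]])


def write_copy_number_calls(calls: CopyNumberCallSet, path: str | Path) -> None:
    calls.data.to_csv(path, sep="\t", index=False)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read UCSC-style two-column chrom sizes."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes
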