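"""Readers and writers for contact matrices, TAD intervals and bin annotations.

Contact matrices travel in two plain-text dialects:

* ``triple`` — tab-separated ``start1 <TAB> start2 <TAB> count`` lines, one per
  non-zero upper-triangle entry, with coordinates giving the left edge of each
  bin in bp (the convention of standard per-chromosome Hi-C dumps).  A variant
  accepts bare bin indices instead of bp coordinates.
* ``dense`` — a whitespace-delimited square matrix.

Genomic coordinates are 0-based, half-open everywhere externally; bin indices
are inclusive internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class MatrixFormatError(ValueError):
    """Raised for malformed or inconsistent contact-matrix input."""


@dataclass
class ContactMatrix:
    """A symmetric, non-negative binned contact count matrix for one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome identifier, e.g. ``"chr1"``.
    bin_size : int
        Bin width in bp.
    counts : ndarray of shape (n_bins, n_bins)
        Symmetric non-negative contact counts.
    start_offset : int
        Genomic coordinate (bp) of the left edge of bin 0.
    """

    chrom: str
    bin_size: int
    counts: np.ndarray
    start_offset: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        validate_counts(self.counts)
        if self.bin_size <= 0:
            raise ValueError(f"bin_size must be positive, got {self.bin_size}")
        if self.start_offset < 0:
            raise ValueError("start_offset must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def with_counts(self, counts: np.ndarray) -> "ContactMatrix":
        """Return a copy of this matrix carrying new counts (same metadata)."""
        return ContactMatrix(self.chrom, self.bin_size, counts, self.start_offset)


@dataclass
class BinAnnotation:
    """Per-bin 0/1 indicator of overlap with at least one annotation interval."""

    chrom: str
    bin_size: int
    indicator: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    def __post_init__(self) -> None:
        self.indicator = np.asarray(self.indicator, dtype=int)
        if not np.isin(self.indicator, (0, 1)).all():
            raise ValueError("annotation indicator must be 0/1")

    @property
    def n_bins(self) -> int:
        return self.indicator.shape[0]


@dataclass(frozen=True)
class TADInterval:
    """A contiguous domain: inclusive bin indices [start_bin, end_bin]."""

    chrom: str
    start_bin: int
    end_bin: int
    cluster_id: int

    def __post_init__(self) -> None:
        if not (0 <= self.start_bin <= self.end_bin):
            raise ValueError(
                f"invalid interval bins [{self.start_bin}, {self.end_bin}]"
            )

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin + 1


def validate_counts(counts: np.ndarray) -> None:
    """Check the ContactMatrix invariants on a raw count array."""
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise MatrixFormatError(f"counts must be square, got shape {counts.shape}")
    if counts.shape[0] < 2:
        raise MatrixFormatError("contact matrix needs at least 2 bins")
    if not np.isfinite(counts).all():
        raise MatrixFormatError("counts contain NaN or Inf")
    if (counts < 0).any():
        raise MatrixFormatError("counts contain negative entries")
    if not np.array_equal(counts, counts.T):
        raise MatrixFormatError("counts are not symmetric")


def _coords_to_bins(
    coords: np.ndarray, bin_size: int, start_offset: int, path: str
) -> np.ndarray:
    shifted = coords - start_offset
    if (shifted < 0).any():
        bad = int(np.argmax(shifted < 0))
        raise MatrixFormatError(
            f"{path}: coordinate {coords[bad]} lies before start_offset {start_offset}"
        )
    bins, rem = np.divmod(shifted, bin_size)
    if (rem != 0).any():
        bad = int(np.argmax(rem != 0))
        raise MatrixFormatError(
            f"{path}: coordinate {coords[bad]} is not a multiple of "
            f"bin_size {bin_size} from offset {start_offset}"
        )
    return bins.astype(np.int64)


def read_contact_matrix(
    path,
    format: str = "triple",
    *,
    bin_size: int = 1,
    chrom: str = "chr1",
    start_offset: int = 0,
    n_bins: int | None = None,
    coords: str = "bp",
) -> ContactMatrix:
    """Read a contact matrix from a triple or dense text file.

    Parameters
    ----------
    format : {"triple", "dense"}
    bin_size, chrom, start_offset
        Genomic metadata attached to the result; for triple files in bp
        coordinates, ``bin_size`` and ``start_offset`` define the bin grid.
    n_bins : int, optional
        Matrix dimension; inferred from the maximal coordinate when omitted.
    coords : {"bp", "bin"}
        Whether triple-file coordinates are bin left edges in bp or bin indices.
    """
    if format == "dense":
        try:
            counts = np.loadtxt(path, ndmin=2)
        except ValueError as exc:
            raise MatrixFormatError(f"{path}: cannot parse dense matrix: {exc}") from exc
        if counts.shape[0] != counts.shape[1]:
            raise MatrixFormatError(
                f"{path}: dense matrix is {counts.shape[0]}x{counts.shape[1]}, not square"
            )
        asym = np.abs(counts - counts.T).max()
        scale = max(np.abs(counts).max(), 1.0)
        if asym > 0:
            if asym > 1e-6 * scale:
                warnings.warn(
                    f"{path}: dense matrix asymmetric (max rel. deviation "
                    f"{asym / scale:.3g}); symmetrizing as (X + X.T)/2"
                )
            counts = (counts + counts.T) / 2.0
        return ContactMatrix(chrom, bin_size, counts, start_offset)

    if format != "triple":
        raise ValueError(f"unknown format {format!r}; expected 'triple' or 'dense'")
    if coords not in ("bp", "bin"):
        raise ValueError(f"coords must be 'bp' or 'bin', got {coords!r}")

    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["a", "b", "count"],
            dtype={"a": np.int64, "b": np.int64, "count": float},
            comment="#",
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise MatrixFormatError(f"{path}: malformed triple file: {exc}") from exc
    if df.isna().any().any():
        line = int(df.isna().any(axis=1).idxmax()) + 1
        raise MatrixFormatError(f"{path}: malformed triple at line {line}")
    if (df["count"] < 0).any():
        line = int((df["count"] < 0).idxmax()) + 1
        raise MatrixFormatError(f"{path}: negative count at line {line}")

    if coords == "bp":
        i = _coords_to_bins(df["a"].to_numpy(), bin_size, start_offset, str(path))
        j = _coords_to_bins(df["b"].to_numpy(), bin_size, start_offset, str(path))
    else:
        i = df["a"].to_numpy(dtype=np.int64)
        j = df["b"].to_numpy(dtype=np.int64)
        if (i < 0).any() or (j < 0).any():
            raise MatrixFormatError(f"{path}: negative bin index")

    dim = int(max(i.max(), j.max())) + 1 if len(i) else 0
    if n_bins is not None:
        if dim > n_bins:
            raise MatrixFormatError(
                f"{path}: coordinates imply {dim} bins but n_bins={n_bins}"
            )
        dim = n_bins
    if dim < 2:
        raise MatrixFormatError(f"{path}: matrix has fewer than 2 bins")

    lo, hi = np.minimum(i, j), np.maximum(i, j)
    vals = df["count"].to_numpy()
    keys = lo * dim + hi
    if len(np.unique(keys)) != len(keys):
        # A pair may legitimately appear twice only as mirrored (i,j)/(j,i)
        # entries with equal counts; same-orientation duplicates and
        # disagreeing mirrors are errors.
        groups = pd.DataFrame({"key": keys, "i": i, "j": j, "val": vals})
        for key, g in groups.groupby("key", sort=False):
            if len(g) == 1:
                continue
            pi, pj = int(g["i"].iloc[0]), int(g["j"].iloc[0])
            if len(g) > 2 or g["i"].nunique() != len(g):
                raise MatrixFormatError(
                    f"{path}: duplicate entry for bins ({pi}, {pj})"
                )
            if g["val"].nunique() != 1:
                raise MatrixFormatError(
                    f"{path}: mirrored entries for bins ({pi}, {pj}) disagree"
                )
        keep = ~pd.Series(keys).duplicated().to_numpy()
        lo, hi, vals = lo[keep], hi[keep], vals[keep]

    counts = np.zeros((dim, dim))
    counts[lo, hi] = vals
    counts[hi, lo] = vals
    return ContactMatrix(chrom, bin_size, counts, start_offset)


def write_contact_matrix(m: ContactMatrix, path, format: str = "triple") -> None:
    """Write a contact matrix; triple format emits the non-zero upper triangle."""
    if format == "dense":
        np.savetxt(path, m.counts, fmt="%.17g", delimiter="\t")
        return
    if format != "triple":
        raise ValueError(f"unknown format {format!r}")
    iu, ju = np.nonzero(np.triu(m.counts))
    with open(path, "w") as fh:
        for i, j in zip(iu, ju):
            a = m.start_offset + int(i) * m.bin_size
            b = m.start_offset + int(j) * m.bin_size
            fh.write(f"{a}\t{b}\t{m.counts[i, j]:.17g}\n")


def write_tads_bed(
    tads: list[TADInterval],
    m_meta: tuple[str, int, int],
    path,
) -> None:
    """Write TADs as BED4 (chrom, start, end, cluster_id), 0-based half-open."""
    chrom, bin_size, start_offset = m_meta
    occupied: set[int] = set()
    for t in tads:
        span = set(range(t.start_bin, t.end_bin + 1))
        if occupied & span:
            raise ValueError(f"overlapping TAD intervals at bins {sorted(occupied & span)[:3]}")
        occupied |= span
    with open(path, "w") as fh:
        for t in sorted(tads, key=lambda t: t.start_bin):
            start = start_offset + t.start_bin * bin_size
            end = start_offset + (t.end_bin + 1) * bin_size
            fh.write(f"{chrom}\t{start}\t{end}\t{t.cluster_id}\n")


def read_tads_bed(path, m_meta: tuple[str, int, int]) -> list[TADInterval]:
    """Read a BED4 TAD file back into bin-indexed intervals."""
    chrom, bin_size, start_offset = m_meta
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    tads = []
    for _, row in df.iterrows():
        if str(row[0]) != chrom:
            warnings.warn(f"{path}: skipping interval on {row[0]} (expected {chrom})")
            continue
        start_bin = (int(row[1]) - start_offset) // bin_size
        end_bin = (int(row[2]) - start_offset) // bin_size - 1
        cid = int(row[3]) if len(row) > 3 else len(tads)
        tads.append(TADInterval(chrom, start_bin, end_bin, cid))
    return tads


def read_bed_to_annotation(path, m_meta: tuple[str, int, int, int]) -> BinAnnotation:
    """Mark bins overlapped (by >= 1 bp) by any interval of a BED file.

    ``m_meta`` is ``(chrom, bin_size, start_offset, n_bins)``.  Intervals on
    other chromosomes are skipped with a warning; half-open convention means an
    interval ending exactly at a bin edge does not mark the next bin.
    """
    chrom, bin_size, start_offset, n_bins = m_meta
    indicator = np.zeros(n_bins, dtype=int)
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    for idx, row in df.iterrows():
        start, end = int(row[1]), int(row[2])
        if start >= end:
            raise ValueError(f"{path}: line {idx + 1}: start {start} >= end {end}")
        if str(row[0]) != chrom:
            warnings.warn(f"{path}: skipping interval on {row[0]} (expected {chrom})")
            continue
        first = max(0, (start - start_offset) // bin_size)
        last = min(n_bins - 1, (end - 1 - start_offset) // bin_size)
        if last >= 0 and first < n_bins:
            indicator[first : last + 1] = 1
    return BinAnnotation(chrom, bin_size, indicator)
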