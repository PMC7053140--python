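"""Binned read-coverage extraction from BAM/BigWig and coverage-matrix assembly.

The per-bin statistic is the mean per-base depth, so values from 1-bp bins
equal the raw pileup and BAM- and BigWig-backed tracks are directly
comparable. Per-cell normalization is multiplicative: a CPM-style factor
(1e6 / total mapped reads) can be supplied as-is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam
import pyBigWig

from .genome import GenomicRegion

__all__ = [
    "CoverageVector",
    "CoverageMatrix",
    "bin_edges",
    "bin_coverage_from_bam",
    "bin_coverage_from_bigwig",
    "bin_coverage",
    "build_coverage_matrix",
    "mean_coverage_by_group",
    "read_manifest",
]

DEFAULT_N_BINS = 1000

# CIGAR operation codes that consume the reference (BAM spec numbering).
# M=0, I=1, D=2, N=3, S=4, H=5, P=6, ==7, X=8. Depth is contributed by
# M/=/X/D (the read's alignment covers the base); N (skipped intron) and
# soft clips consume no depth.
_DEPTH_OPS = frozenset((0, 2, 7, 8))
_REF_CONSUMING = frozenset((0, 2, 3, 7, 8))


@dataclass(frozen=True)
class CoverageVector:
    """Mean per-base depth in each bin of a region.

    ``bin_edges`` has ``n_bins + 1`` genomic positions with
    ``bin_edges[0] == region.start`` and ``bin_edges[-1] == region.end``.
    """

    values: np.ndarray
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        edges = np.asarray(self.bin_edges, dtype=np.int64)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "bin_edges", edges)
        if values.ndim != 1 or edges.ndim != 1 or len(edges) != len(values) + 1:
            raise ValueError("bin_edges must have len(values) + 1 entries")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if np.any(values < 0):
            raise ValueError("coverage values must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.values)


@dataclass
class CoverageMatrix:
    """Cells x bins matrix of normalized mean per-base depth.

    Rows follow the input cell order; reordering for display is kept
    separate (see :mod:`cellpile.ordering`).
    """

    matrix: np.ndarray
    cell_ids: list[str]
    region: GenomicRegion
    bin_edges: np.ndarray
    norm_factors: np.ndarray = field(default=None)  # type: ignore[assignment]
    groups: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (cells x bins)")
        n = self.matrix.shape[0]
        if len(self.cell_ids) != n:
            raise ValueError("cell_ids length must equal row count")
        if self.norm_factors is None:
            self.norm_factors = np.ones(n)
        self.norm_factors = np.asarray(self.norm_factors, dtype=float)
        if len(self.norm_factors) != n:
            raise ValueError("norm_factors length must equal row count")
        if np.any(self.norm_factors <= 0):
            raise ValueError("norm_factors must be positive")
        if self.groups is not None and len(self.groups) != n:
            raise ValueError("groups length must equal row count")
        if np.any(self.matrix < 0):
            raise ValueError("coverage matrix entries must be non-negative")
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.int64)

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]


def bin_edges(region: GenomicRegion, n_bins: int) -> np.ndarray:
    """Partition *region* into ``n_bins`` contiguous bins.

    Bin widths differ by at most 1 bp; when the width is not divisible by
    ``n_bins`` the remainder goes to the leftmost bins.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    width = region.width
    if width < n_bins:
        raise ValueError(
            f"region width {width} is smaller than n_bins {n_bins}"
        )
    base, rem = divmod(width, n_bins)
    widths = np.full(n_bins, base, dtype=np.int64)
    widths[:rem] += 1
    edges = np.empty(n_bins + 1, dtype=np.int64)
    edges[0] = region.start
    np.cumsum(widths, out=edges[1:])
    edges[1:] += region.start
    return edges


def _bin_means(per_base: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Mean of a per-base array over each bin defined by absolute edges."""
    offsets = (edges - edges[0]).astype(np.intp)
    sums = np.add.reduceat(per_base, offsets[:-1])
    return sums / np.diff(offsets)


def per_base_depth_from_bam(
    path: str,
    region: GenomicRegion,
    min_mapq: int = 0,
    include_secondary: bool = False,
    include_duplicates: bool = False,
) -> np.ndarray:
    """CIGAR-aware per-base read depth over *region* from an indexed BAM.

    A read contributes depth at reference base ``p`` when its alignment
    covers ``p`` through an M/=/X/D operation; N gaps contribute nothing.
    Secondary, supplementary and duplicate-flagged reads are excluded by
    default, as are reads below *min_mapq*. A chromosome missing from the
    BAM header yields all zeros with a warning rather than an error, so a
    heat map stays complete when one cell's file uses different naming.
    """
    depth_diff = np.zeros(region.width + 1, dtype=np.float64)
    with pysam.AlignmentFile(path, "rb") as bam:
        if region.chrom not in bam.references:
            warnings.warn(
                f"chromosome {region.chrom!r} absent from {path}; coverage set to 0",
                stacklevel=2,
            )
            return np.zeros(region.width)
        for read in bam.fetch(region.chrom, region.start, region.end):
            if read.is_unmapped or read.mapping_quality < min_mapq:
                continue
            if not include_secondary and (read.is_secondary or read.is_supplementary):
                continue
            if not include_duplicates and read.is_duplicate:
                continue
            pos = read.reference_start
            for op, length in read.cigartuples or ():
                if op in _REF_CONSUMING:
                    if op in _DEPTH_OPS:
                        lo = max(pos, region.start) - region.start
                        hi = min(pos + length, region.end) - region.start
                        if hi > lo:
                            depth_diff[lo] += 1
                            depth_diff[hi] -= 1
                    pos += length
    return np.cumsum(depth_diff[:-1])


def bin_coverage_from_bam(
    path: str,
    region: GenomicRegion,
    n_bins: int = DEFAULT_N_BINS,
    min_mapq: int = 0,
    **read_filters,
) -> CoverageVector:
    """Binned mean per-base depth from an indexed BAM file."""
    edges = bin_edges(region, n_bins)
    depth = per_base_depth_from_bam(path, region, min_mapq=min_mapq, **read_filters)
    return CoverageVector(_bin_means(depth, edges), edges)


def per_base_signal_from_bigwig(path: str, region: GenomicRegion) -> np.ndarray:
    """Per-base BigWig signal over *region*, with absent bases as 0."""
    with pyBigWig.open(path) as bw:
        if region.chrom not in bw.chroms():
            warnings.warn(
                f"chromosome {region.chrom!r} absent from {path}; coverage set to 0",
                stacklevel=2,
            )
            return np.zeros(region.width)
        end = min(region.end, bw.chroms()[region.chrom])
        vals = np.zeros(region.width)
        if end > region.start:
            raw = np.asarray(
                bw.values(region.chrom, region.start, end), dtype=float
            )
            # a chromosome with a header but no data yields an empty array
            if raw.size == end - region.start:
                vals[: end - region.start] = np.nan_to_num(raw, nan=0.0)
    return vals


def bin_coverage_from_bigwig(
    path: str, region: GenomicRegion, n_bins: int = DEFAULT_N_BINS
) -> CoverageVector:
    """Binned mean signal from a BigWig file (absent bases count as 0)."""
    edges = bin_edges(region, n_bins)
    signal = per_base_signal_from_bigwig(path, region)
    return CoverageVector(_bin_means(signal, edges), edges)


def bin_coverage(
    path: str,
    fmt: str,
    region: GenomicRegion,
    n_bins: int = DEFAULT_N_BINS,
    min_mapq: int = 0,
) -> CoverageVector:
    """Dispatch on source format (``"bam"`` or ``"bigwig"``)."""
    fmt = fmt.lower()
    if fmt == "bam":
        return bin_coverage_from_bam(path, region, n_bins, min_mapq=min_mapq)
    if fmt in ("bigwig", "bw"):
        return bin_coverage_from_bigwig(path, region, n_bins)
    raise ValueError(f"unknown coverage format {fmt!r} (expected bam or bigwig)")


def build_coverage_matrix(
    sources: Sequence[tuple[str, str, str]],
    region: GenomicRegion,
    n_bins: int = DEFAULT_N_BINS,
    norm_factors: Optional[Sequence[float]] = None,
    groups: Optional[Sequence[str]] = None,
    min_mapq: int = 0,
) -> CoverageMatrix:
    """Assemble the cells x bins coverage matrix.

    Parameters
    ----------
    sources
        ``(cell_id, path, format)`` triples, one per cell, in display order.
    norm_factors
        Per-cell multiplicative scale factors correcting for differences in
        the number of mapped reads (default: all 1.0). Row ``i`` of the
        result is the binned coverage of source ``i`` times its factor.
    """
    if len(sources) == 0:
        raise ValueError("at least one coverage source is required")
    if norm_factors is None:
        norm_factors = [1.0] * len(sources)
    if len(norm_factors) != len(sources):
        raise ValueError("norm_factors length must match sources")
    factors = np.asarray(norm_factors, dtype=float)
    if np.any(factors <= 0):
        raise ValueError("norm_factors must be positive")
    if groups is not None and len(groups) != len(sources):
        raise ValueError("groups length must match sources")

    edges = bin_edges(region, n_bins)
    rows = []
    for (cell_id, path, fmt), factor in zip(sources, factors):
        vec = bin_coverage(path, fmt, region, n_bins, min_mapq=min_mapq)
        rows.append(vec.values * factor)
    return CoverageMatrix(
        matrix=np.vstack(rows),
        cell_ids=[cid for cid, _, _ in sources],
        region=region,
        bin_edges=edges,
        norm_factors=factors,
        groups=list(groups) if groups is not None else None,
    )


def group_order(groups: Sequence[str]) -> list[str]:
    """Distinct group labels in first-appearance order."""
    seen: dict[str, None] = {}
    for g in groups:
        seen.setdefault(g, None)
    return list(seen)


def mean_coverage_by_group(m: CoverageMatrix) -> list[tuple[str, CoverageVector]]:
    """Per-group arithmetic column means, groups in first-appearance order.

    A matrix without group labels is treated as one group ``"all"``.
    """
    groups = m.groups if m.groups is not None else ["all"] * m.n_cells
    out = []
    for label in group_order(groups):
        idx = [i for i, g in enumerate(groups) if g == label]
        mean = m.matrix[idx].mean(axis=0)
        out.append((label, CoverageVector(mean, m.bin_edges)))
    return out


MANIFEST_COLUMNS = ["cell_id", "path", "format", "group", "norm_factor"]


def read_manifest(path: str) -> pd.DataFrame:
    """Read the tab-separated sample manifest.

    Columns: ``cell_id``, ``path``, ``format`` (bam/bigwig), and optional
    ``group`` and ``norm_factor`` (defaulting to a single group and 1.0).
    """
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    missing = [c for c in ("cell_id", "path", "format") if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks required columns: {missing}")
    if "group" not in df.columns:
        df["group"] = "all"
    if "norm_factor" not in df.columns:
        df["norm_factor"] = 1.0
    df["norm_factor"] = df["norm_factor"].astype(float)
    if (df["norm_factor"] <= 0).any():
        raise ValueError(f"manifest {path}: norm_factor must be positive")
    return df[MANIFEST_COLUMNS]
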