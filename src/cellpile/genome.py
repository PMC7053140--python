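"""Genomic coordinate types, GTF/BED parsing, and enhancer interval filtering.

All in-memory coordinates are 0-based half-open (the BAM/BED convention).
Display coordinates — region strings such as ``chr8:127,735,434-127,742,951``
— are 1-based inclusive, the genome-browser convention; :func:`parse_region`
converts between the two.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

__all__ = [
    "GenomicRegion",
    "FeatureInterval",
    "GeneModel",
    "parse_region",
    "format_region",
    "read_bed",
    "write_bed",
    "read_gtf_gene_models",
    "define_enhancers",
]


@dataclass(frozen=True)
class GenomicRegion:
    """A half-open genomic interval ``[start, end)`` on one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome / reference sequence name.
    start : int
        0-based inclusive start position (bp), ``>= 0``.
    end : int
        0-based exclusive end position (bp), ``> start``.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicRegion") -> bool:
        """Shared length >= 1 bp on half-open intervals; strand-blind."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicRegion") -> bool:
        """True if *other* lies fully within this interval."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class FeatureInterval:
    """A named genomic interval, e.g. one BED record or a ChIP-seq peak."""

    region: GenomicRegion
    name: Optional[str] = None
    strand: Literal["+", "-", "."] = "."
    score: Optional[float] = None


@dataclass(frozen=True)
class GeneModel:
    """Exon structure of one transcript.

    ``tss`` is the 0-based transcription start site: the transcript span's
    start for ``+`` strand transcripts and ``end - 1`` for ``-`` strand.
    Exons are kept sorted by start and non-overlapping (overlapping exon
    records within one transcript are merged at parse time).
    """

    gene_id: str
    transcript_id: str
    strand: Literal["+", "-"]
    exons: tuple[GenomicRegion, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError("GeneModel requires at least one exon")
        starts = [e.start for e in self.exons]
        if starts != sorted(starts):
            raise ValueError("exons must be sorted by start")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError("exons within one transcript must not overlap")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> GenomicRegion:
        """Transcript span from first exon start to last exon end."""
        return GenomicRegion(self.chrom, self.exons[0].start, self.exons[-1].end)

    @property
    def tss(self) -> int:
        return self.span.start if self.strand == "+" else self.span.end - 1


_REGION_RE = re.compile(r"^(?P<chrom>[^:\s]+):(?P<start>[\d,]+)-(?P<end>[\d,]+)$")


def parse_region(text: str) -> GenomicRegion:
    """Parse a browser-style region string into internal coordinates.

    The input uses 1-based inclusive display coordinates with optional
    thousands commas (``chr8:127,735,434-127,742,951``); the result is
    0-based half-open.
    """
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise ValueError(f"malformed region string: {text!r}")
    start_display = int(m["start"].replace(",", ""))
    end_display = int(m["end"].replace(",", ""))
    if start_display < 1:
        raise ValueError(f"display coordinates are 1-based: {text!r}")
    if end_display < start_display:
        raise ValueError(f"region end precedes start: {text!r}")
    start = start_display - 1
    end = end_display
    if end <= start:
        raise ValueError(f"empty region: {text!r}")
    return GenomicRegion(m["chrom"], start, end)


def format_region(region: GenomicRegion) -> str:
    """Inverse of :func:`parse_region` (without thousands commas)."""
    return f"{region.chrom}:{region.start + 1}-{region.end}"


def read_bed(path: str, region: Optional[GenomicRegion] = None) -> list[FeatureInterval]:
    """Read BED3+ records, optionally keeping only those overlapping *region*.

    BED is already 0-based half-open, so coordinates pass through unchanged.
    Intervals are returned unclipped, in file order; columns beyond the
    sixth are ignored. ``track``/``browser``/``#`` lines are skipped.
    """
    out: list[FeatureInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED record has <3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric BED coordinates"
                ) from exc
            iv_region = GenomicRegion(fields[0], start, end)
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: Optional[float] = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            iv = FeatureInterval(iv_region, name=name, strand=strand, score=score)
            if region is None or iv_region.overlaps(region):
                out.append(iv)
    return out


def write_bed(path: str, intervals: Iterable[FeatureInterval]) -> None:
    """Write intervals as BED6 (name/score/strand filled with defaults)."""
    with open(path, "w") as fh:
        for iv in intervals:
            score = "0" if iv.score is None else format(iv.score, "g")
            fh.write(
                "\t".join(
                    (
                        iv.region.chrom,
                        str(iv.region.start),
                        str(iv.region.end),
                        iv.name if iv.name is not None else ".",
                        score,
                        iv.strand,
                    )
                )
                + "\n"
            )


_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf_gene_models(
    path: str, region: Optional[GenomicRegion] = None
) -> list[GeneModel]:
    """Parse GTF exon records into one :class:`GeneModel` per transcript.

    GTF coordinates are 1-based inclusive and are converted to 0-based
    half-open (``start - 1``, ``end``). A transcript is kept when at least
    one of its exons overlaps *region* (all transcripts if *region* is
    None). Exons are sorted by start; overlapping exon records within one
    transcript are merged.
    """
    # transcript_id -> (gene_id, strand, [exon regions])
    transcripts: dict[str, tuple[str, str, list[GenomicRegion]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: GTF record has <9 columns")
            if fields[2] != "exon":
                continue
            chrom, start1, end1, strand = fields[0], fields[3], fields[4], fields[6]
            try:
                start1i, end1i = int(start1), int(end1)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinates") from exc
            if end1i < start1i:
                raise ValueError(f"{path}:{lineno}: exon end < start")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: exon strand must be + or -")
            attrs = dict(_GTF_ATTR_RE.findall(fields[8]))
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise ValueError(
                    f"{path}:{lineno}: exon lacks gene_id/transcript_id attributes"
                )
            exon = GenomicRegion(chrom, start1i - 1, end1i)
            tid = attrs["transcript_id"]
            entry = transcripts.setdefault(tid, (attrs["gene_id"], strand, []))
            entry[2].append(exon)

    models: list[GeneModel] = []
    for tid, (gene_id, strand, exons) in transcripts.items():
        exons.sort(key=lambda e: (e.start, e.end))
        merged: list[GenomicRegion] = []
        for e in exons:
            if merged and e.start < merged[-1].end and e.chrom == merged[-1].chrom:
                merged[-1] = GenomicRegion(
                    e.chrom, merged[-1].start, max(merged[-1].end, e.end)
                )
            else:
                merged.append(e)
        model = GeneModel(
            gene_id=gene_id, transcript_id=tid, strand=strand, exons=tuple(merged)
        )
        if region is None or any(e.overlaps(region) for e in model.exons):
            models.append(model)
    return models


def _tss_distance(tss: int, peak: GenomicRegion) -> int:
    """Unsigned distance (bp) from a TSS point to the nearest base of *peak*.

    A peak overlapping the TSS has distance 0.
    """
    if tss < peak.start:
        return peak.start - tss
    if tss >= peak.end:
        return tss - (peak.end - 1)
    return 0


def define_enhancers(
    h3k4me1: Iterable[FeatureInterval],
    h3k4me3: Iterable[FeatureInterval],
    genes: Iterable[GeneModel],
    min_tss_distance: int = 2000,
    gene_body_rule: Literal["containment", "overlap"] = "containment",
) -> list[FeatureInterval]:
    """Select candidate enhancers from H3K4me1 ChIP-seq peaks.

    An H3K4me1 peak is kept when it

    1. does not overlap any H3K4me3 peak (promoter mark),
    2. lies at least *min_tss_distance* bp (default 2 kbp) from every
       transcription start site, and
    3. is not included in any gene body (transcript span).

    With ``gene_body_rule="containment"`` (default) "included in" means
    fully contained in a transcript span; ``"overlap"`` excludes a peak on
    any overlap instead. Chromosomes are matched by name; strand is ignored.
    """
    if min_tss_distance < 0:
        raise ValueError("min_tss_distance must be >= 0")
    me3 = list(h3k4me3)
    gene_list = list(genes)
    out: list[FeatureInterval] = []
    for peak in h3k4me1:
        pr = peak.region
        if any(pr.overlaps(p.region) for p in me3):
            continue
        too_close = any(
            g.chrom == pr.chrom and _tss_distance(g.tss, pr) < min_tss_distance
            for g in gene_list
        )
        if too_close:
            continue
        if gene_body_rule == "containment":
            in_body = any(g.span.contains(pr) for g in gene_list)
        else:
            in_body = any(g.span.overlaps(pr) for g in gene_list)
        if in_body:
            continue
        out.append(peak)
    return out
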