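"""Deterministic synthetic scRNA-seq coverage scenarios for testing and demos.

Generates sorted indexed BAMs (one per cell, single-end 100-bp reads),
BigWig signal, GTF gene models, BED features, a tab-separated sample
manifest, and a ground-truth table recording each cell's planted state.
Planted structures emulate phenomena that full-length scRNA-seq coverage
exposes: on/off expression heterogeneity, a monotone pseudo-time gradient,
isoform switching, and 3' UTR shortening. Everything is reproducible: a
scenario's seed fixes all randomness, byte-for-byte.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam
import pyBigWig

from .genome import FeatureInterval, GeneModel, GenomicRegion, write_bed

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "make_bam",
    "make_bigwig",
    "write_gtf",
    "make_scenario",
    "SCENARIO_KINDS",
]

READ_LENGTH = 100
SCENARIO_KINDS = (
    "uniform",
    "bimodal_expression",
    "monotone_gradient",
    "isoform_switch",
    "utr_shortening",
)

_QUERY_CONSUMING = frozenset("MIS=X")


def _query_length(cigar: str) -> int:
    n, total = "", 0
    for ch in cigar:
        if ch.isdigit():
            n += ch
        else:
            if ch in _QUERY_CONSUMING:
                total += int(n)
            n = ""
    return total


def make_bam(
    path: str,
    placements: Sequence[tuple[int, int, Optional[str]]],
    chrom: str = "chr1",
    chrom_len: int = 1_000_000,
) -> str:
    """Write a sorted, indexed BAM from explicit read placements.

    Each placement is ``(start, length, cigar)`` with 0-based *start*; a
    ``None`` cigar means a fully matching read (``{length}M``). The
    brute-force pileup of the output equals the analytic depth profile of
    the placements.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": chrom_len}],
    }
    records = sorted(placements, key=lambda p: p[0])
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for i, (start, length, cigar) in enumerate(records):
            if cigar is None:
                cigar = f"{length}M"
            a = pysam.AlignedSegment(bam.header)
            a.query_name = f"read{i:06d}"
            a.reference_id = 0
            a.reference_start = start
            a.cigarstring = cigar
            if start < 0 or a.reference_end > chrom_len:
                raise ValueError(
                    f"placement [{start}, {a.reference_end}) beyond reference "
                    f"length {chrom_len}"
                )
            qlen = _query_length(cigar)
            a.query_sequence = "A" * qlen
            a.query_qualities = pysam.qualitystring_to_array("I" * qlen)
            a.mapping_quality = 60
            a.flag = 0
            bam.write(a)
    pysam.index(path)
    return path


def make_bigwig(
    path: str,
    intervals: Sequence[tuple[int, int, float]],
    chrom_sizes: dict[str, int],
    chrom: str = "chr1",
) -> str:
    """Write a BigWig whose per-base expansion equals *intervals*.

    Intervals are ``(start, end, value)`` on one chromosome and must not
    overlap.
    """
    ivs = sorted(intervals)
    for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping BigWig intervals at {s2} < {e1}")
    bw = pyBigWig.open(path, "w")
    try:
        bw.addHeader(sorted(chrom_sizes.items()))
        if ivs:
            bw.addEntries(
                [chrom] * len(ivs),
                [s for s, _, _ in ivs],
                ends=[e for _, e, _ in ivs],
                values=[float(v) for _, _, v in ivs],
            )
    finally:
        bw.close()
    return path


def write_gtf(path: str, models: Sequence[GeneModel], source: str = "cellpile") -> None:
    """Write gene models as GTF exon records (1-based inclusive)."""
    with open(path, "w") as fh:
        for m in models:
            for exon in m.exons:
                attrs = (
                    f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
                )
                fh.write(
                    "\t".join(
                        (
                            exon.chrom,
                            source,
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            m.strand,
                            ".",
                            attrs,
                        )
                    )
                    + "\n"
                )


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic scenario.

    ``depth`` is the number of reads an expressing cell receives over the
    planted locus; group sizes must sum to ``n_cells``. The seed fixes all
    randomness, including read placement jitter.
    """

    kind: str
    n_cells: int = 10
    region: GenomicRegion = field(
        default_factory=lambda: GenomicRegion("chr1", 10_000, 20_000)
    )
    groups: Optional[Sequence[tuple[str, int]]] = None
    depth: int = 200
    n_expressing: Optional[int] = None  # bimodal only; default n_cells // 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.groups is not None and sum(s for _, s in self.groups) != self.n_cells:
            raise ValueError("group sizes must sum to n_cells")


@dataclass
class ScenarioResult:
    """Paths and ground truth of a generated scenario directory."""

    spec: ScenarioSpec
    outdir: str
    manifest_path: str
    gtf_path: str
    bed_path: str
    truth_path: str
    bam_paths: list[str]
    ground_truth: pd.DataFrame


def _tile_reads(
    rng: np.random.Generator, start: int, end: int, n_reads: int
) -> list[tuple[int, int, Optional[str]]]:
    """n_reads 100-bp reads over [start, end): evenly tiled with jitter."""
    span = max(end - start - READ_LENGTH, 1)
    base = np.linspace(0, span, num=n_reads, endpoint=True)
    jitter = rng.integers(-READ_LENGTH // 4, READ_LENGTH // 4 + 1, size=n_reads)
    starts = np.clip(base.astype(np.int64) + jitter, 0, span) + start
    return [(int(s), READ_LENGTH, None) for s in starts]


def _group_labels(spec: ScenarioSpec) -> list[str]:
    if spec.groups is None:
        return ["all"] * spec.n_cells
    labels: list[str] = []
    for name, size in spec.groups:
        labels.extend([name] * size)
    return labels


def make_scenario(spec: ScenarioSpec, outdir: str) -> ScenarioResult:
    """Generate per-cell BAMs, manifest, GTF, BED and ground truth.

    Planted structures (all within the central 60% of the region, the
    "locus"):

    - ``uniform``: every cell expresses the locus at the same depth.
    - ``bimodal_expression``: ``n_expressing`` cells (default half) carry
      reads over the locus; the rest are silent (zero reads).
    - ``monotone_gradient``: cell of ground-truth rank r covers the locus
      from its start up to a breakpoint strictly increasing with r (a step
      function sweeping rightward); cells are shuffled on disk.
    - ``isoform_switch``: "long" cells cover all three exons, "short" cells
      only the first.
    - ``utr_shortening``: all cells cover the gene body and proximal 3' UTR;
      only "long" cells cover the distal 3' UTR window.

    The ground-truth table records each cell's planted state
    (``expressing``, ``rank``, ``state``) for use as an ordering oracle.
    """
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    region = spec.region
    chrom = region.chrom
    chrom_len = region.end + 100_000
    w = region.width
    locus = GenomicRegion(chrom, region.start + w // 5, region.start + 4 * w // 5)

    n = spec.n_cells
    labels = _group_labels(spec)
    cell_ids = [f"cell{i:03d}" for i in range(n)]
    truth = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "group": labels,
            "expressing": True,
            "rank": np.arange(n),
            "state": "expressing",
        }
    )

    per_cell: list[list[tuple[int, int, Optional[str]]]] = [[] for _ in range(n)]
    models: list[GeneModel] = []
    bed_features: list[FeatureInterval] = [
        FeatureInterval(locus, name="planted_locus")
    ]

    if spec.kind == "uniform":
        models.append(_single_exon_model(locus, "geneU"))
        for i in range(n):
            per_cell[i] = _tile_reads(rng, locus.start, locus.end, spec.depth)

    elif spec.kind == "bimodal_expression":
        models.append(_single_exon_model(locus, "geneB"))
        n_expr = spec.n_expressing if spec.n_expressing is not None else n // 2
        if not 0 <= n_expr <= n:
            raise ValueError("n_expressing must lie in [0, n_cells]")
        expressing = np.zeros(n, dtype=bool)
        expressing[rng.permutation(n)[:n_expr]] = True
        truth["expressing"] = expressing
        truth["state"] = np.where(expressing, "expressing", "silent")
        for i in range(n):
            if expressing[i]:
                per_cell[i] = _tile_reads(rng, locus.start, locus.end, spec.depth)

    elif spec.kind == "monotone_gradient":
        models.append(_single_exon_model(locus, "geneG"))
        ranks = rng.permutation(n)
        truth["rank"] = ranks
        truth["state"] = [f"rank{r}" for r in ranks]
        step = locus.width // (n + 1)
        for i in range(n):
            # breakpoint strictly monotone in rank; coverage from locus start
            breakpoint = locus.start + (int(ranks[i]) + 1) * step
            frac = (breakpoint - locus.start) / locus.width
            n_reads = max(int(round(spec.depth * frac)), 8)
            per_cell[i] = _tile_reads(rng, locus.start, breakpoint, n_reads)

    elif spec.kind == "isoform_switch":
        exon_w = locus.width // 7
        e1 = GenomicRegion(chrom, locus.start, locus.start + exon_w)
        e2 = GenomicRegion(chrom, locus.start + 3 * exon_w, locus.start + 4 * exon_w)
        e3 = GenomicRegion(chrom, locus.start + 6 * exon_w, locus.end)
        models.append(
            GeneModel("geneI", "geneI.long", "+", exons=(e1, e2, e3))
        )
        models.append(GeneModel("geneI", "geneI.short", "+", exons=(e1,)))
        long_state = np.zeros(n, dtype=bool)
        long_state[rng.permutation(n)[: n // 2]] = True
        truth["state"] = np.where(long_state, "long", "short")
        d = max(spec.depth // 3, 4)
        for i in range(n):
            exons = (e1, e2, e3) if long_state[i] else (e1,)
            for e in exons:
                per_cell[i].extend(_tile_reads(rng, e.start, e.end, d))

    elif spec.kind == "utr_shortening":
        # gene body + proximal UTR in the left 2/3 of the locus; distal UTR
        # window in the right 1/3, covered only by "long" cells.
        split = locus.start + 2 * locus.width // 3
        body = GenomicRegion(chrom, locus.start, split)
        distal = GenomicRegion(chrom, split, locus.end)
        models.append(_single_exon_model(locus, "geneUTR"))
        bed_features.append(FeatureInterval(distal, name="distal_utr"))
        long_state = np.zeros(n, dtype=bool)
        long_state[rng.permutation(n)[: n // 2]] = True
        truth["state"] = np.where(long_state, "long", "short")
        d_body = max(2 * spec.depth // 3, 4)
        d_utr = max(spec.depth // 3, 4)
        for i in range(n):
            per_cell[i] = _tile_reads(rng, body.start, body.end, d_body)
            if long_state[i]:
                per_cell[i].extend(_tile_reads(rng, distal.start, distal.end, d_utr))

    bam_paths = []
    for cid, placements in zip(cell_ids, per_cell):
        path = os.path.join(outdir, f"{cid}.bam")
        make_bam(path, placements, chrom=chrom, chrom_len=chrom_len)
        bam_paths.append(path)

    gtf_path = os.path.join(outdir, "annotation.gtf")
    write_gtf(gtf_path, models)
    bed_path = os.path.join(outdir, "features.bed")
    write_bed(bed_path, bed_features)

    manifest = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "path": bam_paths,
            "format": "bam",
            "group": labels,
            "norm_factor": 1.0,
        }
    )
    manifest_path = os.path.join(outdir, "manifest.tsv")
    manifest.to_csv(manifest_path, sep="\t", index=False)
    truth_path = os.path.join(outdir, "ground_truth.tsv")
    truth.to_csv(truth_path, sep="\t", index=False)

    return ScenarioResult(
        spec=spec,
        outdir=outdir,
        manifest_path=manifest_path,
        gtf_path=gtf_path,
        bed_path=bed_path,
        truth_path=truth_path,
        bam_paths=bam_paths,
        ground_truth=truth,
    )


def _single_exon_model(locus: GenomicRegion, gene_id: str) -> GeneModel:
    return GeneModel(gene_id, f"{gene_id}.1", "+", exons=(locus,))
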