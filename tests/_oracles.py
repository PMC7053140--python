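"""Independent brute-force oracles used to validate the implementation.

Each oracle deliberately takes a different computational route from the
package code: per-base Python loops instead of vectorized difference
arrays, base-position sets instead of interval arithmetic, and a
nonsymmetric eigendecomposition of the diffusion transition matrix instead
of the symmetric-conjugate solve.
"""

from __future__ import annotations

import re

import numpy as np
import pysam

CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def naive_bam_pileup(path: str, start: int, end: int, chrom: str,
                     min_mapq: int = 0) -> np.ndarray:
    """O(reads x bases) per-base depth: walk each CIGAR string base by base."""
    depth = np.zeros(end - start)
    with pysam.AlignmentFile(path, "rb") as bam:
        if chrom not in bam.references:
            return depth
        for read in bam.fetch(chrom, start, end):
            if (read.is_unmapped or read.is_secondary or read.is_supplementary
                    or read.is_duplicate or read.mapping_quality < min_mapq):
                continue
            pos = read.reference_start
            for n, op in CIGAR_RE.findall(read.cigarstring):
                n = int(n)
                if op in "M=XD":  # covers reference bases
                    for p in range(pos, pos + n):
                        if start <= p < end:
                            depth[p - start] += 1
                    pos += n
                elif op == "N":  # skipped region: consumes reference, no depth
                    pos += n
                # I/S/H/P consume no reference
    return depth


def naive_bin_means(per_base: np.ndarray, n_bins: int) -> np.ndarray:
    """Bin means with remainder distributed to the leftmost bins."""
    width = len(per_base)
    base, rem = divmod(width, n_bins)
    out = np.empty(n_bins)
    pos = 0
    for i in range(n_bins):
        w = base + (1 if i < rem else 0)
        out[i] = per_base[pos:pos + w].mean()
        pos += w
    return out


def expand_intervals(intervals, start: int, end: int) -> np.ndarray:
    """Per-base expansion of (start, end, value) intervals; absent bases = 0."""
    arr = np.zeros(end - start)
    for s, e, v in intervals:
        for p in range(max(s, start), min(e, end)):
            arr[p - start] = v
    return arr


def _fix_sign(vec: np.ndarray) -> np.ndarray:
    scale = np.max(np.abs(vec)) if vec.size else 0.0
    nz = np.nonzero(np.abs(vec) > 1e-12 * max(scale, 1.0))[0]
    if nz.size and vec[nz[0]] < 0:
        return -vec
    return vec


def dc1_oracle(m: np.ndarray, sigma: float) -> np.ndarray:
    """DC1 via the nonsymmetric transition matrix and numpy.linalg.eig.

    Explicit Gaussian kernel with zeroed diagonal, alpha=1 density
    normalization, row-stochastic P, eigenvector of the second-largest
    eigenvalue, unit-normalized, scaled by its eigenvalue, sign fixed by the
    lowest-index nonzero entry.
    """
    n = m.shape[0]
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                d2 = float(np.sum((m[i] - m[j]) ** 2))
                W[i, j] = np.exp(-d2 / (2.0 * sigma ** 2))
    q = W.sum(axis=1)
    Wt = W / np.outer(q, q)
    P = Wt / Wt.sum(axis=1)[:, None]
    evals, evecs = np.linalg.eig(P)
    order = np.argsort(evals.real)[::-1]
    lam = evals.real[order[1]]
    psi = evecs[:, order[1]].real
    psi = psi / np.linalg.norm(psi)
    return _fix_sign(lam * psi)


def pc1_oracle(m: np.ndarray) -> np.ndarray:
    """PC1 scores via eigendecomposition of the Gram matrix of centered rows."""
    x = m - m.mean(axis=0)
    gram = x @ x.T
    evals, evecs = np.linalg.eigh(gram)
    scores = evecs[:, -1] * np.sqrt(max(evals[-1], 0.0))
    return _fix_sign(scores)


def enhancer_oracle(me1, me3, genes, min_tss_distance: int):
    """Three-rule enhancer filter on explicit base-position sets.

    Independent route: overlap = set intersection, gene-body containment =
    subset test, TSS distance = min |tss - p| over peak bases.
    """
    me3_bases = {}
    for p in me3:
        me3_bases.setdefault(p.region.chrom, set()).update(
            range(p.region.start, p.region.end))
    out = []
    for peak in me1:
        bases = set(range(peak.region.start, peak.region.end))
        if bases & me3_bases.get(peak.region.chrom, set()):
            continue
        ok = True
        for g in genes:
            if g.chrom != peak.region.chrom:
                continue
            if min(abs(g.tss - p) for p in bases) < min_tss_distance:
                ok = False
                break
            body = set(range(g.span.start, g.span.end))
            if bases <= body:
                ok = False
                break
        if ok:
            out.append(peak)
    return out


def first_fit_lanes_oracle(spans: list[tuple[int, int]]) -> list[int]:
    """Greedy first-fit lane packing simulated with explicit occupancy lists."""
    lanes: list[list[tuple[int, int]]] = []
    out = []
    for s, e in spans:
        for i, lane in enumerate(lanes):
            if all(e <= ls or le <= s for ls, le in lane):
                lane.append((s, e))
                out.append(i)
                break
        else:
            lanes.append([(s, e)])
            out.append(len(lanes) - 1)
    return out


def random_cigar_reads(rng: np.random.Generator, n_reads: int,
                       region_start: int, region_end: int):
    """Random read placements with mixed CIGAR shapes, kept inside bounds."""
    placements = []
    for _ in range(n_reads):
        kind = rng.integers(0, 5)
        start = int(rng.integers(max(region_start - 150, 0), region_end + 50))
        if kind == 0:
            cigar = "100M"
        elif kind == 1:  # spliced
            gap = int(rng.integers(50, 400))
            cigar = f"40M{gap}N60M"
        elif kind == 2:  # deletion
            cigar = f"50M{int(rng.integers(1, 20))}D50M"
        elif kind == 3:  # insertion (no reference consumption)
            cigar = f"60M{int(rng.integers(1, 15))}I40M"
        else:  # soft-clipped ends
            cigar = "15S70M15S"
        placements.append((start, 100, cigar))
    return placements
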