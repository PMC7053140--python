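# Methods

## Problem and model

`cellpile` visualizes read coverage — the per-base count of aligned reads
along genomic coordinates — for every cell of a full-length scRNA-seq
experiment simultaneously, as a heat map whose rows are cells and whose
columns are genomic bins within one focal region. The central modeling step
is the *ordering* of the rows: cells are sorted by a one-dimensional "local
pseudo-time" computed from the coverage matrix of the focal region itself,
so that cells with similar local coverage shapes become neighbors and
structure (on/off expression, isoform switches, UTR-length heterogeneity)
appears as coherent blocks rather than salt-and-pepper noise.

## Coverage extraction

**Binning.** A region of width `w` is split into `n` contiguous bins whose
widths differ by at most 1 bp; when `w mod n ≠ 0` the remainder goes to the
leftmost bins. The per-bin statistic is the **mean per-base depth**, chosen
so that (a) 1-bp bins reproduce the raw pileup exactly, (b) the one-bin
value is the width-weighted mean of any finer binning, and (c) BAM- and
BigWig-backed tracks are directly comparable (BigWig summaries are means).
The default of 1000 bins (clamped to the region width) is a
screen-resolution scale.

**BAM pileup.** A read contributes depth at base `p` when its alignment
covers `p` via a CIGAR operation that consumes the reference and aligns the
read across it (`M`, `=`, `X`, `D`); skipped introns (`N`) consume reference
but add no depth, and insertions/soft-clips add none. Reads below
`min_mapq` (default 0) and secondary/supplementary/duplicate-flagged reads
are excluded by default; both filters are overridable. Coverage is
unstranded. A chromosome missing from a file's header yields a zero row
plus a warning rather than an error, so one mis-named reference does not
destroy an otherwise complete heat map.

**Normalization** is multiplicative: row `i` is the binned coverage of cell
`i` times its user-supplied factor (default 1.0), so a CPM-style factor
`10⁶/total mapped reads` plugs in directly. Linearity is exact by
construction and tested as such.

## Diffusion-map ordering

The classical density-normalized construction, fixed for reproducibility:

1. Gaussian kernel on Euclidean row distances,
   `W_ij = exp(−‖x_i − x_j‖²/2σ²)`, diagonal zeroed.
2. Anisotropic α = 1 normalization `W̃ = D⁻¹WD⁻¹`, `D = diag(W·1)`,
   removing the influence of sampling density.
3. The transition operator `P = D̃⁻¹W̃` is eigendecomposed through its
   symmetric conjugate `S = D̃^{-1/2} W̃ D̃^{-1/2}` (symmetric solve,
   `scipy.linalg.eigh`); eigenvectors are mapped back by `ψ = D̃^{-1/2}v`,
   unit-normalized, and scaled by their eigenvalue. The trivial
   constant eigenvector (eigenvalue 1) is discarded; DC1 is the next one.

Choices where the design was open:

- **Bandwidth** `σ = "auto"` is the median pairwise nonzero distance divided
  by √2 — deterministic, scale-free, and adequate for the tens-to-hundreds
  of cells in one plot. Locally adaptive bandwidths were deliberately not
  implemented.
- **No kNN sparsification**: matrices hold the cells of one plot; dense
  kernels are exact and fast at this size.
- **Sign convention**: each component is oriented so that its value for the
  lowest-input-index cell with a nonzero entry is positive, making repeated
  runs bit-identical. Whether ascending DC1 is "early" or "late" pseudo-time
  is arbitrary; ascending order is used.
- **Input scale**: the normalized coverage matrix is embedded as-is; a
  `log1p` switch exists but is off by default.
- **Ties** in scores are broken by input order (stable sort).

PCA ordering projects column-mean-centered rows onto the first right
singular direction, with the same sign convention.

**Scopes.** `all_cells` sorts every row jointly by ascending score;
`group_wise` computes scores independently per user-defined group from that
group's rows only, keeps each group a contiguous block, and preserves
first-appearance group order. Degenerate geometry (identical rows, zero
bandwidth) or groups of fewer than 3 cells (a 3-point kernel is the minimum
meaningful diffusion geometry) fall back to input order with a warning
rather than failing the plot.

## Rendering and the adjustment cache

Tracks are stacked top-to-bottom in user order on a shared genomic x-axis;
every panel spans exactly the focal region. Defaults: relative heights
heat map 6, mean 1 per group, bulk 1, BED 0.5, gene 1.5; DPI 150; output
format chosen by file extension (png/svg/pdf). Gene models are drawn as
exon boxes joined by intron lines with strand arrows, packed onto lanes by
greedy first-fit in input order. When cells outnumber available raster
rows (default cap 4000), adjacent rows *in permuted order* are averaged for
display only; the cache is untouched.

**Color scale.** Values map linearly onto the colormap over `[0, vmax]`
with clamping above. `vmax="auto"` uses the 0.99 upper quantile of positive
values (falling back to 1.0 when the matrix is all zero) — a robust default
so single bins of exceptionally high coverage saturate instead of washing
out the rest; the quantile and an explicit `vmax` are both exposed.

**Adjustment.** `render()` performs all file I/O in one load phase and
stores every coverage matrix (in input row order, permutation kept
separately) in a `PlotState`. `adjust()` accepts style-only overrides
(vmax, colormap, heights, group colors, DPI, reorder scope/method — the
ordering is then recomputed from the cached matrix alone) and redraws
without opening any source file; changing region or sources raises
`RequiresFullRender`. The state pickles to disk, which is how the CLI's
`adjust` subcommand restyles a previous `plot` run.

## Synthetic scenarios

The generator writes sorted indexed BAMs (single-end 100-bp reads, one file
per cell), BigWig, GTF, BED, a manifest and a ground-truth table; a seed
fixes everything byte-for-byte. Reads are tiled evenly over the planted
interval with ±25 bp jitter, giving near-uniform depth with realistic local
fluctuation. Planted structures: `uniform`; `bimodal_expression` (a subset
of cells expresses the locus, the rest carry zero reads — an idealized
on/off pattern); `monotone_gradient` (a coverage step whose breakpoint
increases strictly with a hidden rank; the cells are shuffled on disk);
`isoform_switch` (three-exon vs first-exon-only cells);
`utr_shortening` (only "long" cells cover the distal 3′ UTR window).
Defaults are 10 cells at 200 reads per expressing cell over a 10-kbp
region — desk-scale versions of the phenomena the tool is meant to expose.

What the generator does **not** emulate: sequencing error and base
qualities, UMIs, paired ends, amplification bias, GC effects, or ambient
background reads. Passing tests therefore demonstrate correctness of the
pileup arithmetic, the embedding, the ordering contract and the cache
semantics — not robustness to every artifact of real libraries. In real
data the separation between cell states is softer and the recovered
pseudo-time correspondingly noisier.

## Numerical notes and limitations

- Binned BAM coverage is exact (integer counts averaged over integer
  widths); BigWig round-trips through float32 storage, so agreement with
  per-base oracles is asserted at ~1e-6, not machine epsilon.
- Eigenvector comparisons are made up to global sign; with exactly
  symmetric configurations (e.g. three equidistant cells) the leading
  nontrivial eigenvalue is degenerate and individual components are only
  defined up to rotation within the eigenspace — orderings derived from
  them are then arbitrary, which is inherent to the method.
- All-zero or identical-row matrices have no defined embedding; the plot
  falls back to input order instead of failing.
- The per-bin statistic, default bin count, auto-vmax quantile and track
  heights are this package's own defaults, not claims about any other
  implementation's internals.
- Enhancer rule "not included in the gene bodies" is implemented as full
  containment in a transcript span (partial overlap does not exclude);
  `gene_body_rule="overlap"` switches to any-overlap exclusion. TSS
  distance is unsigned, measured from the TSS point to the nearest peak
  base (0 if the peak covers the TSS).

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run on synthetic inputs sized
for a laptop-class single core: regions of 0.5–10 kbp, 100 random BAMs of
up to 200 mixed-CIGAR reads, 100 random BigWig fixtures, 200 random
matrices up to 50 × 100 for the DC1 oracle, and 50 simulation seeds each
for the gradient-recovery and bimodal-partition rates. These sizes were
chosen as the smallest at which the properties are non-trivial; all
measurements are deterministic given the seed.
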